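"""Predictive-value metrics, group-comparison tests and sedation GLMs.

Proportion confidence intervals are exact Clopper-Pearson throughout: the
lower bound inverts the binomial upper tail, the upper bound the lower
tail, via beta quantiles.  Each predictive metric gets its CI on its own
numerator/denominator pair, so a PPV of 18/18 is reported as
1.00 (0.81-1.00).

The sedation analysis fits four binomial logit models of
P(favourable outcome) on the Day-1 band-power score (PS) and the three
sedative infusion rates (P, M, F): the full model carries all three
PS x rate interactions and each reduced model drops exactly one.  Models
are ranked by AIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import InputError, SeparationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InputError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    value: float | None  # None when the denominator is zero
    lo: float | None
    hi: float | None
    successes: int
    n: int

    def __str__(self):
        if self.value is None:
            return "undefined"
        return f"{round2(self.value):.2f} ({round2(self.lo):.2f}-{round2(self.hi):.2f})"


@dataclass(frozen=True)
class PredictiveMetrics:
    ppv: MetricWithCI
    npv: MetricWithCI
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    accuracy: MetricWithCI
    counts: ConfusionCounts

    @property
    def n_evaluable(self) -> int:
        return self.counts.total


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (report presentation)."""
    return math.floor(x * 100 + 0.5) / 100


def clopper_pearson(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI; (0, ...) at zero successes, (..., 1) at n."""
    if n < 1:
        raise InputError("clopper_pearson needs n >= 1")
    if not 0 <= successes <= n:
        raise InputError(f"successes {successes} outside [0, {n}]")
    alpha = 1 - conf
    lo = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    hi = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lo, hi


def _metric(successes: int, n: int, conf: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(None, None, None, successes, 0)
    lo, hi = clopper_pearson(successes, n, conf)
    return MetricWithCI(successes / n, lo, hi, successes, n)


def confusion_metrics(c: ConfusionCounts, conf: float = 0.95) -> PredictiveMetrics:
    """PPV/NPV/sensitivity/specificity/accuracy with exact CIs.

    A metric whose denominator is zero is reported as undefined
    (``value=None``), never as 0.
    """
    if c.total < 1:
        raise InputError("all-zero confusion counts")
    return PredictiveMetrics(
        ppv=_metric(c.tp, c.tp + c.fp, conf),
        npv=_metric(c.tn, c.tn + c.fn, conf),
        sensitivity=_metric(c.tp, c.tp + c.fn, conf),
        specificity=_metric(c.tn, c.tn + c.fp, conf),
        accuracy=_metric(c.tp + c.tn, c.total, conf),
        counts=c,
    )


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p (df = #groups - 1).

    Identical samples give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise InputError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (minimum-likelihood convention).

    Zero-margin tables are degenerate (only one table is possible given
    the margins) and return p = 1 with a logged notice.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InputError("table must be a non-negative 2x2 integer matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        logger.info("fisher_exact_2x2: zero margin, p = 1")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class GlmFit:
    """A fitted binomial logit model."""

    model_id: str
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    test_statistics: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    aic: float
    n_obs: int
    obs_index: tuple

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "t": self.test_statistics,
                "p": self.p_values,
            }
        )


#: interaction sets of the four candidate models
GLM_MODELS = {
    "full": ("PS:P", "PS:M", "PS:F"),
    "dropPSxF": ("PS:P", "PS:M"),
    "dropPSxM": ("PS:P", "PS:F"),
    "dropPSxP": ("PS:M", "PS:F"),
}


def fit_sedation_glm(data: pd.DataFrame, model_id: str = "full") -> GlmFit:
    """Binomial logit of P(outcome = FO) on band power and sedation rates.

    ``data`` needs columns ``outcome`` (FO/UO), ``power`` (the Day-1
    band-average score) and ``propofol_rate``/``midazolam_rate``/
    ``fentanyl_rate``.  Main effects PS, P, M, F are always included;
    ``model_id`` selects which PS x rate interactions enter (see
    ``GLM_MODELS``).  Rows with any missing covariate are excluded with a
    logged count.  Perfect separation raises :class:`SeparationError`.
    """
    if model_id not in GLM_MODELS:
        raise InputError(f"unknown model_id {model_id!r}; choose from {list(GLM_MODELS)}")
    needed = ["outcome", "power", "propofol_rate", "midazolam_rate", "fentanyl_rate"]
    missing_cols = [c for c in needed if c not in data.columns]
    if missing_cols:
        raise InputError(f"missing columns: {missing_cols}")
    df = data[needed].copy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("fit_sedation_glm: excluded %d patients with missing rates",
                    n0 - len(df))
    y = (df["outcome"] == "FO").astype(float)
    if y.nunique() < 2:
        raise InputError("need at least one patient per outcome")
    base = pd.DataFrame(
        {
            "PS": df["power"].astype(float),
            "P": df["propofol_rate"].astype(float),
            "M": df["midazolam_rate"].astype(float),
            "F": df["fentanyl_rate"].astype(float),
        },
        index=df.index,
    )
    X = base.copy()
    for inter in GLM_MODELS[model_id]:
        _, rate = inter.split(":")
        X[inter] = base["PS"] * base[rate]
    X = sm.add_constant(X, prepend=True)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            fit = model.fit(maxiter=200)
    except (Exception, PerfectSeparationWarning) as exc:
        raise SeparationError(f"GLM fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 1e3):
        raise SeparationError(
            "perfect or quasi-perfect separation: unbounded coefficients"
        )
    return GlmFit(
        model_id=model_id,
        terms=list(X.columns),
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        test_statistics=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        log_likelihood=float(fit.llf),
        aic=float(2 * len(X.columns) - 2 * fit.llf),
        n_obs=len(df),
        obs_index=tuple(df.index),
    )


def fit_all_sedation_glms(data: pd.DataFrame) -> list[GlmFit]:
    return [fit_sedation_glm(data, mid) for mid in GLM_MODELS]


def select_by_aic(fits: list[GlmFit]) -> list[GlmFit]:
    """Rank fits by ascending AIC; ties broken by fewer parameters.

    All fits must be on the identical observation set.
    """
    if len(fits) < 2:
        raise InputError("need >= 2 fits to rank")
    ref = fits[0].obs_index
    for f in fits[1:]:
        if f.obs_index != ref:
            raise InputError("fits were computed on different observation sets")
    ranked = sorted(fits, key=lambda f: (f.aic, len(f.terms)))
    aics = [round(f.aic, 10) for f in ranked]
    if len(set(aics)) < len(aics):
        logger.info("select_by_aic: identical AICs present, order by parameter count")
    return ranked
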