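"""Exact CIs, confusion metrics, nonparametric tests, and the sedation GLMs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from comaspectra.errors import InputError, SeparationError
from comaspectra.stats import (
    GLM_MODELS,
    ConfusionCounts,
    GlmFit,
    clopper_pearson,
    confusion_metrics,
    fisher_exact_2x2,
    fit_all_sedation_glms,
    fit_sedation_glm,
    kruskal_wallis,
    round2,
    select_by_aic,
)


class TestClopperPearson:
    def test_all_successes_lower_bound_closed_form(self):
        lo, hi = clopper_pearson(18, 18)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 18), rel=1e-10)
        assert round2(lo) == 0.81

    def test_zero_successes_upper_bound_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), rel=1e-10)

    def test_printed_sensitivity_interval(self):
        lo, hi = clopper_pearson(18, 45)
        assert (round2(lo), round2(hi)) == (0.26, 0.56)

    def test_interval_contains_point_and_widens_with_confidence(self):
        for k, n in [(0, 5), (3, 7), (10, 10), (45, 91)]:
            lo, hi = clopper_pearson(k, n, 0.95)
            assert lo <= k / n <= hi
            lo99, hi99 = clopper_pearson(k, n, 0.99)
            assert lo99 <= lo and hi99 >= hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            clopper_pearson(5, 0)
        with pytest.raises(InputError):
            clopper_pearson(6, 5)


# Tables-1/2 rows: counts -> (ppv, npv, sensitivity, specificity, accuracy) at 2 dp
PRINTED_ROWS = [
    ((18, 0, 27, 46), (1.00, 0.63, 0.40, 1.00, 0.70)),
    ((30, 7, 14, 33), (0.81, 0.70, 0.68, 0.83, 0.75)),
    ((33, 7, 12, 39), (0.83, 0.76, 0.73, 0.85, 0.79)),
    ((37, 5, 8, 41), (0.88, 0.84, 0.82, 0.89, 0.86)),
    ((6, 7, 39, 39), (0.46, 0.50, 0.13, 0.85, 0.49)),
    ((38, 20, 2, 16), (0.66, 0.89, 0.95, 0.44, 0.71)),
    ((39, 22, 6, 24), (0.64, 0.80, 0.87, 0.52, 0.69)),
    ((35, 11, 3, 25), (0.76, 0.89, 0.92, 0.69, 0.81)),
    ((36, 14, 9, 32), (0.72, 0.78, 0.80, 0.70, 0.75)),
]


class TestConfusionMetrics:
    @pytest.mark.parametrize("counts,expected", PRINTED_ROWS)
    def test_reported_point_metrics_at_two_decimals(self, counts, expected):
        m = confusion_metrics(ConfusionCounts(*counts))
        got = tuple(
            round2(getattr(m, name).value)
            for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy")
        )
        assert got == expected

    def test_zero_denominator_metric_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionCounts(0, 0, 5, 5))
        assert m.ppv.value is None
        assert m.npv.value == pytest.approx(0.5)

    def test_points_scale_free_cis_shrink(self):
        base = ConfusionCounts(6, 7, 39, 39)
        m1 = confusion_metrics(base)
        m4 = confusion_metrics(ConfusionCounts(24, 28, 156, 156))
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy"):
            a, b = getattr(m1, name), getattr(m4, name)
            assert a.value == pytest.approx(b.value)
            assert (b.hi - b.lo) < (a.hi - a.lo)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InputError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))


def _kw_oracle(groups):
    """Hand implementation: tie-corrected rank statistic."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    start, rbar = 0, []
    for g in groups:
        rbar.append(ranks[start:start + len(g)].mean())
        start += len(g)
    h = 12 / (n * (n + 1)) * sum(
        len(g) * m**2 for g, m in zip(groups, rbar)
    ) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_identical_samples_give_zero(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_h(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4, rel=1e-12)

    def test_ties_match_bruteforce_oracle(self, rng):
        for _ in range(20):
            sizes = rng.integers(2, 5, size=rng.integers(2, 4))
            groups = [rng.integers(0, 4, size=s).astype(float) for s in sizes]
            if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
                continue
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(_kw_oracle(groups), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            kruskal_wallis([[1.0], []])


def _fisher_oracle(table):
    """Two-sided p by hypergeometric enumeration (minimum-likelihood rule)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_gives_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3, rel=1e-12)

    def test_zero_margin_returns_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_exhaustive_agreement_with_enumeration_up_to_n12(self):
        count = 0
        for n in range(2, 13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                t = [[a, b], [c, d]]
                if min(a + b, c + d, a + c, b + d) == 0:
                    continue
                assert fisher_exact_2x2(t) == pytest.approx(
                    _fisher_oracle(t), abs=1e-10
                ), t
                count += 1
        assert count > 300


def _glm_frame(rng, n=120, slope_ps=0.0, seps=None):
    ps = rng.normal(size=n)
    rates = {a: np.abs(rng.normal(1.0, 0.5, size=n)) for a in
             ("propofol_rate", "midazolam_rate", "fentanyl_rate")}
    logit = -0.1 + slope_ps * ps
    p = 1 / (1 + np.exp(-logit))
    y = rng.random(n) < p
    return pd.DataFrame(
        {"outcome": np.where(y, "FO", "UO"), "power": ps, **rates}
    )


class TestSedationGlm:
    def test_full_model_has_all_interactions(self, rng):
        fit = fit_sedation_glm(_glm_frame(rng), "full")
        assert set(fit.terms) >= {"PS", "P", "M", "F", "PS:P", "PS:M", "PS:F"}
        assert fit.aic == pytest.approx(2 * len(fit.terms) - 2 * fit.log_likelihood)

    def test_reduced_models_drop_exactly_one_interaction(self, rng):
        df = _glm_frame(rng)
        for mid, expected in GLM_MODELS.items():
            fit = fit_sedation_glm(df, mid)
            assert [t for t in fit.terms if ":" in t] == list(expected)

    def test_missing_rates_exclude_patients(self, rng):
        df = _glm_frame(rng, n=80)
        df.loc[:9, "propofol_rate"] = np.nan
        fit = fit_sedation_glm(df, "full")
        assert fit.n_obs == 70

    def test_loglik_bounded_below_by_intercept_only_closed_form(self, rng):
        df = _glm_frame(rng, n=91)
        k = int((df["outcome"] == "FO").sum())
        n = len(df)
        ll0 = k * math.log(k / n) + (n - k) * math.log(1 - k / n)
        fit = fit_sedation_glm(df, "full")
        assert fit.log_likelihood >= ll0 - 1e-9

    def test_perfect_separation_raises(self, rng):
        df = _glm_frame(rng, n=40)
        df["power"] = np.where(df["outcome"] == "FO", 1.0, -1.0) * (
            1 + np.arange(40) * 0.01
        )
        with pytest.raises(SeparationError):
            fit_sedation_glm(df, "full")


def _fit(model_id, aic, n_terms=3, obs=(0, 1, 2)):
    return GlmFit(
        model_id=model_id, terms=[f"t{i}" for i in range(n_terms)],
        coefficients=np.zeros(n_terms), standard_errors=np.ones(n_terms),
        test_statistics=np.zeros(n_terms), p_values=np.ones(n_terms),
        log_likelihood=(2 * n_terms - aic) / 2, aic=aic, n_obs=len(obs),
        obs_index=tuple(obs),
    )


class TestSelectByAic:
    def test_ascending_aic_order(self):
        ranked = select_by_aic([_fit("a", 99.55), _fit("b", 97.57), _fit("c", 97.98)])
        assert [f.model_id for f in ranked] == ["b", "c", "a"]

    def test_ties_broken_by_fewer_parameters(self):
        ranked = select_by_aic([_fit("big", 100.0, n_terms=5), _fit("small", 100.0, n_terms=3)])
        assert ranked[0].model_id == "small"

    def test_constant_loglik_shift_preserves_ranking(self):
        fits = [_fit("a", 103.0), _fit("b", 101.0)]
        shifted = [_fit(f.model_id, f.aic + 7.0) for f in fits]
        assert [f.model_id for f in select_by_aic(fits)] == [
            f.model_id for f in select_by_aic(shifted)
        ]

    def test_different_observation_sets_rejected(self):
        with pytest.raises(InputError):
            select_by_aic([_fit("a", 1.0, obs=(0, 1)), _fit("b", 2.0, obs=(0, 2))])
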