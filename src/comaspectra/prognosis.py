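"""Outcome prediction from band-averaged normalized power.

The procedure is a stratified 5-fold cross-validation.  In each fold the
training patients alone drive (i) discovery of the discriminative
frequency band via the cluster-permutation test and (ii) selection of a
scalar threshold.  The threshold is the maximum band-power score among
training UO patients, so the rule ``score > threshold => predict FO``
classifies every training UO patient correctly — zero training false
positives, hence maximal (unit) training PPV whenever any FO patient
clears it.  A patient scoring exactly the threshold is predicted UO (the
inequality is strict).  The held-out fold is scored once with the frozen
band and threshold; test folds partition the cohort, so each patient is
tested exactly once.

``apply_fixed_model`` re-applies one fold's frozen band and threshold to
a different recording day.  ``combine_predictions`` merges the power-based
prediction with a binary clinical marker by a monotone OR: predict FO
when either source is favourable, falling back to whichever source is
available when the other is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusterstat import AdjacencyGraph, cluster_permutation_test, extract_band
from .errors import InputError
from .spectral import FrequencyBand, PatientSpectrum, SpectrumGrid, band_average
from .stats import ConfusionCounts, PredictiveMetrics, confusion_metrics

logger = logging.getLogger(__name__)

FO, UO = "FO", "UO"

DEFAULT_BAND = FrequencyBand(4.6, 15.2)


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict[str, int]  # patient id -> fold index
    seed: int | None = None

    def train_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of.items() if f != fold]

    def test_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of.items() if f == fold]


@dataclass
class TrainedFoldModel:
    band: FrequencyBand
    threshold: float
    fold: int
    training_ids: list[str]
    band_from_cluster: bool = True  # False when the fallback band was used


@dataclass
class PredictionRecord:
    patient_id: str
    score: float | None
    predicted: str  # FO or UO
    true: str
    source: str  # power / marker / combined


@dataclass
class CVResult:
    models: list[TrainedFoldModel]
    records: list[PredictionRecord]  # pooled held-out predictions
    fold_metrics: pd.DataFrame  # one row per fold
    pooled: PredictiveMetrics
    folds: FoldAssignment | None = None

    def metric_mean_sd(self, name: str) -> tuple[float, float]:
        vals = self.fold_metrics[name].to_numpy(dtype=float)
        return float(np.nanmean(vals)), float(np.nanstd(vals, ddof=0))


def stratified_kfold(labels: dict[str, str], k: int = 5, seed=None) -> FoldAssignment:
    """Outcome-stratified k-fold partition with matched group counts.

    Each class is shuffled and dealt round-robin; the leftover patients of
    the two classes are placed in disjoint folds so that every train and
    test set has FO and UO counts differing by at most one.
    """
    ids_fo = sorted(p for p, o in labels.items() if o == FO)
    ids_uo = sorted(p for p, o in labels.items() if o == UO)
    if len(ids_fo) < k or len(ids_uo) < k:
        raise InputError(
            f"each class needs >= k={k} patients "
            f"(got {len(ids_fo)} FO, {len(ids_uo)} UO)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else seed
    fold_of: dict[str, int] = {}
    for offset, ids in ((0, ids_fo), (k - 1, ids_uo)):
        ids = list(ids)
        rng.shuffle(ids)
        # offsetting the deal start makes the two classes' leftover folds
        # disjoint, keeping per-fold counts matched
        for j, pid in enumerate(ids):
            fold_of[pid] = (offset + j) % k
    fa = FoldAssignment(k=k, fold_of=fold_of, seed=seed_val)
    for f in range(k):
        for subset in (fa.train_ids(f), fa.test_ids(f)):
            nf = sum(labels[p] == FO for p in subset)
            nu = len(subset) - nf
            if abs(nf - nu) > 1:
                raise InputError(
                    f"cohort too unbalanced for matched folds "
                    f"(fold {f}: {nf} FO vs {nu} UO)"
                )
    return fa


def select_threshold(train_scores, train_labels) -> float:
    """Maximum training-UO score: zero training false positives by construction."""
    scores = np.asarray(train_scores, dtype=float)
    labels = np.asarray(train_labels)
    uo_scores = scores[labels == UO]
    if len(uo_scores) == 0:
        raise InputError("no UO patients in training set")
    return float(uo_scores.max())


def _predict(score: float, threshold: float) -> str:
    return FO if score > threshold else UO


def _stack(spectra: dict[str, PatientSpectrum], ids: list[str]) -> np.ndarray:
    return np.stack([spectra[p].values for p in ids])


def _records_frame_metrics(records: list[PredictionRecord]):
    counts = records_to_counts(records)
    return confusion_metrics(counts)


def records_to_counts(records: list[PredictionRecord]) -> ConfusionCounts:
    """Confusion counts with predicted/true FO as the positive class."""
    tp = sum(r.predicted == FO and r.true == FO for r in records)
    fp = sum(r.predicted == FO and r.true == UO for r in records)
    fn = sum(r.predicted == UO and r.true == FO for r in records)
    tn = sum(r.predicted == UO and r.true == UO for r in records)
    return ConfusionCounts(tp, fp, fn, tn)


def _fold_metric_row(fold: int, records: list[PredictionRecord]) -> dict:
    c = records_to_counts(records)
    m = confusion_metrics(c)
    row = {"fold": fold, "n_test": c.total}
    for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy"):
        v = getattr(m, name).value
        row[name] = np.nan if v is None else v
    return row


def crossvalidate(
    spectra: dict[str, PatientSpectrum],
    labels: dict[str, str],
    folds: FoldAssignment,
    adjacency: AdjacencyGraph,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    default_band: FrequencyBand = DEFAULT_BAND,
    seed=None,
    grid: SpectrumGrid | None = None,
) -> CVResult:
    """Per-fold band discovery + threshold selection, held-out evaluation.

    The cluster test and threshold see only training patients; when a
    training fold yields no significant cluster the configured
    ``default_band`` is used with a logged notice.
    """
    missing = set(folds.fold_of) - set(spectra)
    if missing:
        raise InputError(f"no spectra for patients: {sorted(missing)[:5]}")
    grid = grid or next(iter(spectra.values())).grid
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models: list[TrainedFoldModel] = []
    records: list[PredictionRecord] = []
    fold_rows = []
    for f in range(folds.k):
        train = folds.train_ids(f)
        test = folds.test_ids(f)
        train_fo = [p for p in train if labels[p] == FO]
        train_uo = [p for p in train if labels[p] == UO]
        result = cluster_permutation_test(
            _stack(spectra, train_fo),
            _stack(spectra, train_uo),
            adjacency,
            n_perm=n_perm,
            alpha=alpha,
            cluster_alpha=cluster_alpha,
            seed=rng,
            grid=grid,
        )
        band = extract_band(result, grid)
        from_cluster = band is not None
        if band is None:
            logger.warning(
                "fold %d: no significant cluster; falling back to band %.1f-%.1f Hz",
                f, default_band.fmin, default_band.fmax,
            )
            band = default_band
        train_scores = [band_average(spectra[p], band) for p in train]
        threshold = select_threshold(train_scores, [labels[p] for p in train])
        model = TrainedFoldModel(
            band=band, threshold=threshold, fold=f, training_ids=train,
            band_from_cluster=from_cluster,
        )
        models.append(model)
        fold_records = []
        for p in test:
            score = band_average(spectra[p], band)
            fold_records.append(
                PredictionRecord(p, score, _predict(score, threshold), labels[p], "power")
            )
        records.extend(fold_records)
        fold_rows.append(_fold_metric_row(f, fold_records))
    pooled = confusion_metrics(records_to_counts(records))
    return CVResult(
        models=models,
        records=records,
        fold_metrics=pd.DataFrame(fold_rows),
        pooled=pooled,
        folds=folds,
    )


def representative_fold(models: list[TrainedFoldModel], grid: SpectrumGrid | None = None) -> TrainedFoldModel:
    """The fold whose extracted band spans the most grid bins (ties: lowest fold)."""
    grid = grid or SpectrumGrid()

    def n_bins(m: TrainedFoldModel) -> int:
        return int(m.band.bin_mask(grid).sum())

    return max(models, key=lambda m: (n_bins(m), -m.fold))


def apply_fixed_model(
    model: TrainedFoldModel,
    spectra: dict[str, PatientSpectrum],
    labels: dict[str, str],
) -> list[PredictionRecord]:
    """Score patients with a frozen band and threshold (e.g. Day-2 spectra)."""
    records = []
    for p in sorted(spectra):
        spec = spectra[p]
        if spec.grid.n_bins != next(iter(spectra.values())).grid.n_bins:
            raise InputError("spectra are on mixed grids")
        score = band_average(spec, model.band)
        records.append(
            PredictionRecord(p, score, _predict(score, model.threshold), labels[p], "power")
        )
    return records


def combine_predictions(
    power: list[PredictionRecord],
    marker: dict[str, str],
    labels: dict[str, str] | None = None,
) -> list[PredictionRecord]:
    """OR-combine power predictions with a clinical marker.

    ``marker`` maps patient id -> favourable / unfavourable / missing.
    Predict FO when the power rule or the marker is favourable; a missing
    marker defers to power, a missing power score defers to the marker,
    and a patient missing both is excluded with a logged notice.
    """
    power_by_id = {r.patient_id: r for r in power}
    ids = sorted(set(power_by_id) | set(marker))
    out = []
    for pid in ids:
        p_rec = power_by_id.get(pid)
        m_val = marker.get(pid, "missing")
        has_power = p_rec is not None and p_rec.score is not None
        has_marker = m_val in ("favourable", "unfavourable")
        if not has_power and not has_marker:
            logger.warning("combine: patient %s has neither power nor marker", pid)
            continue
        if has_power and has_marker:
            pred = FO if (p_rec.predicted == FO or m_val == "favourable") else UO
        elif has_power:
            pred = p_rec.predicted
        else:
            pred = FO if m_val == "favourable" else UO
        true = p_rec.true if p_rec is not None else (labels or {}).get(pid)
        if true is None:
            raise InputError(f"no true outcome for patient {pid}")
        out.append(
            PredictionRecord(
                pid, p_rec.score if p_rec else None, pred, true, "combined"
            )
        )
    return out


def marker_indication(meta, which: str) -> str:
    """Map a :class:`PatientMeta` marker field to favourable/unfavourable/missing."""
    if which == "reactivity":
        return {"present": "favourable", "absent": "unfavourable"}.get(
            meta.reactivity, "missing"
        )
    if which == "discontinuity":
        return {"yes": "favourable", "no": "unfavourable"}.get(
            meta.discontinuity_favourable, "missing"
        )
    if which == "epileptiform":
        return {"absent": "favourable", "present": "unfavourable"}.get(
            meta.epileptiform, "missing"
        )
    raise InputError(f"unknown marker {which!r}")
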