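"""End-to-end orchestration on a synthetic cohort.

``run_all`` chains every stage: simulate -> condition epochs -> spectra
-> Day-1 cluster test -> cross-validated prediction -> representative
fold -> fixed-model application to Day 2 -> marker combination ->
metrics tables -> sedation group statistics -> interaction GLMs.  The
run is deterministic given the seed; the resolved configuration and seed
are written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .clusterstat import build_adjacency, cluster_permutation_test
from .errors import ComaSpectraError, SeparationError
from .preprocess import average_reference
from .prognosis import (
    apply_fixed_model,
    combine_predictions,
    crossvalidate,
    marker_indication,
    records_to_counts,
    representative_fold,
    stratified_kfold,
)
from .spectral import FrequencyBand, SpectrumGrid, band_average, epochs_psd, patient_spectrum
from .stats import (
    GLM_MODELS,
    confusion_metrics,
    fisher_exact_2x2,
    fit_sedation_glm,
    kruskal_wallis,
    select_by_aic,
)
from .synthetic import AGENTS, CohortConfig, MarkerParams, SedationAgentParams, generate_cohort

logger = logging.getLogger(__name__)

#: artifacts every successful run leaves behind
MANIFEST = (
    "cohort_meta.tsv",
    "spectra_day1.tsv",
    "clusters.json",
    "cv_models.json",
    "predictions.tsv",
    "metrics.tsv",
)


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    normalization: str = "per_electrode"
    n_perm: int = 5000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    adjacency_method: str = "delaunay"
    adjacency_param: float = 0.5
    k: int = 5
    default_band: tuple[float, float] = (4.6, 15.2)
    seed: int = 0


def cohort_config_to_dict(c: CohortConfig) -> dict:
    d = dataclasses.asdict(c)
    d["sedation_params"] = {
        f"{o}:{day}": {a: dataclasses.asdict(p) for a, p in agents.items()}
        for (o, day), agents in c.sedation_params.items()
    }
    d["marker_params"] = {
        m: dataclasses.asdict(p) for m, p in c.marker_params.items()
    }
    d["bump_band"] = list(c.bump_band)
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "sedation_params" in d:
        d["sedation_params"] = {
            (k.split(":")[0], int(k.split(":")[1])): {
                a: SedationAgentParams(**p) for a, p in agents.items()
            }
            for k, agents in d["sedation_params"].items()
        }
    if "marker_params" in d:
        d["marker_params"] = {
            m: MarkerParams(**p) for m, p in d["marker_params"].items()
        }
    if "bump_band" in d:
        d["bump_band"] = tuple(d["bump_band"])
    return CohortConfig(**d)


def run_config_to_yaml(config: RunConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["cohort"] = cohort_config_to_dict(config.cohort)
    d["default_band"] = list(config.default_band)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def run_config_from_yaml(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "cohort" in d:
        d["cohort"] = cohort_config_from_dict(d["cohort"])
    if "default_band" in d:
        d["default_band"] = tuple(d["default_band"])
    return RunConfig(**d)


def _stage(name):
    logger.info("stage: %s", name)
    return name


def compute_spectra(records, day: int, normalization: str, grid: SpectrumGrid):
    """Average-reference each recording and estimate its normalized spectrum."""
    spectra = {}
    for rec in records:
        ep = average_reference(rec.eeg[day])
        psds = epochs_psd(ep, grid)
        spectra[rec.patient_id] = patient_spectrum(
            psds,
            grid,
            mode=normalization,
            patient_id=rec.patient_id,
            day=day,
            channel_labels=list(ep.channel_labels),
        )
    return spectra


def _group_stats_frame(meta: pd.DataFrame) -> pd.DataFrame:
    """Day-1 vs Day-2 sedation comparisons per outcome scope."""
    rows = []
    for scope in ("FO", "UO", "ALL"):
        sub = meta if scope == "ALL" else meta[meta["outcome"] == scope]
        for agent in AGENTS:
            col = f"{agent}_rate"
            d1 = sub[sub["day"] == 1][col]
            d2 = sub[sub["day"] == 2][col]
            r1 = d1.dropna()[lambda s: s > 0]
            r2 = d2.dropna()[lambda s: s > 0]
            if len(r1) and len(r2):
                h, p_kw = kruskal_wallis([r1.to_numpy(), r2.to_numpy()])
            else:
                h, p_kw = np.nan, np.nan
            tab = [
                [int((d1.dropna() > 0).sum()), int((d1.dropna() == 0).sum())],
                [int((d2.dropna() > 0).sum()), int((d2.dropna() == 0).sum())],
            ]
            p_f = fisher_exact_2x2(tab)
            rows.append(
                {
                    "scope": scope,
                    "agent": agent,
                    "day1_mean": r1.mean() if len(r1) else np.nan,
                    "day1_sd": r1.std(ddof=1) if len(r1) > 1 else np.nan,
                    "day2_mean": r2.mean() if len(r2) else np.nan,
                    "day2_sd": r2.std(ddof=1) if len(r2) > 1 else np.nan,
                    "n_sedated_day1": tab[0][0],
                    "n_sedated_day2": tab[1][0],
                    "kruskal_H": h,
                    "kruskal_p": p_kw,
                    "fisher_p": p_f,
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir) -> Path:
    """Run the whole analysis; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        run_config_to_yaml(
            dataclasses.replace(config, cohort=cohort_cfg), out / "config.yaml"
        )
        grid = SpectrumGrid()
        default_band = FrequencyBand(*config.default_band)

        stage = _stage("simulate")
        records = generate_cohort(cohort_cfg)
        labels = {r.patient_id: r.outcome for r in records}
        meta = cio.metadata_frame(records)
        cio.write_metadata_tsv(meta, out / "cohort_meta.tsv", seed=config.seed)

        stage = _stage("spectra")
        spectra = {
            day: compute_spectra(records, day, config.normalization, grid)
            for day in (1, 2)
        }
        for day in (1, 2):
            cio.write_tsv(
                cio.spectra_frame(spectra[day]),
                out / f"spectra_day{day}.tsv",
                seed=config.seed,
            )

        stage = _stage("cluster-test-day1")
        ch_labels = list(records[0].eeg[1].channel_labels)
        adjacency = build_adjacency(
            records[0].eeg[1].channel_positions,
            ch_labels,
            method=config.adjacency_method,
            param=config.adjacency_param,
        )
        fo_ids = sorted(p for p, o in labels.items() if o == "FO")
        uo_ids = sorted(p for p, o in labels.items() if o == "UO")
        day1 = spectra[1]
        result = cluster_permutation_test(
            np.stack([day1[p].values for p in fo_ids]),
            np.stack([day1[p].values for p in uo_ids]),
            adjacency,
            n_perm=config.n_perm,
            alpha=config.alpha,
            cluster_alpha=config.cluster_alpha,
            seed=config.seed + 2,
            grid=grid,
        )
        with open(out / "clusters.json", "w") as fh:
            json.dump(cio.cluster_result_to_json(result), fh, indent=1)
        if not result.significant_clusters:
            logger.warning("no significant Day-1 cluster on the full cohort")

        stage = _stage("cross-validate")
        folds = stratified_kfold(labels, k=config.k, seed=config.seed + 1)
        cv = crossvalidate(
            day1,
            labels,
            folds,
            adjacency,
            n_perm=config.n_perm,
            alpha=config.alpha,
            cluster_alpha=config.cluster_alpha,
            default_band=default_band,
            seed=config.seed + 2,
            grid=grid,
        )
        with open(out / "cv_models.json", "w") as fh:
            json.dump(
                [
                    {
                        "fold": m.fold,
                        "band": [m.band.fmin, m.band.fmax],
                        "threshold": m.threshold,
                        "band_from_cluster": m.band_from_cluster,
                        "training_ids": m.training_ids,
                    }
                    for m in cv.models
                ],
                fh,
                indent=1,
            )
        cio.write_tsv(cv.fold_metrics, out / "fold_metrics.tsv", seed=config.seed)

        stage = _stage("day2-fixed-model")
        rep = representative_fold(cv.models, grid)
        day2_records = apply_fixed_model(rep, spectra[2], labels)

        stage = _stage("combine-markers")
        markers = {
            which: {
                r.patient_id: marker_indication(r.meta[1], which) for r in records
            }
            for which in ("reactivity", "discontinuity")
        }
        metric_rows = []
        pred_frames = []
        for day, recs in ((1, cv.records), (2, day2_records)):
            metric_rows.append(
                cio.metrics_row(
                    f"Power spectra day {day}",
                    confusion_metrics(records_to_counts(recs)),
                )
            )
            df = cio.predictions_frame(recs)
            df.insert(1, "day", day)
            pred_frames.append(df)
            for which in ("reactivity", "discontinuity"):
                combined = combine_predictions(recs, markers[which], labels)
                metric_rows.append(
                    cio.metrics_row(
                        f"Power + {which} day {day}",
                        confusion_metrics(records_to_counts(combined)),
                    )
                )
                dfc = cio.predictions_frame(combined)
                dfc.insert(1, "day", day)
                dfc["source"] = f"combined_{which}"
                pred_frames.append(dfc)
        cio.write_tsv(
            pd.concat(pred_frames, ignore_index=True),
            out / "predictions.tsv",
            seed=config.seed,
        )
        cio.write_tsv(pd.DataFrame(metric_rows), out / "metrics.tsv", seed=config.seed)

        stage = _stage("group-stats")
        cio.write_tsv(_group_stats_frame(meta), out / "group_stats.tsv", seed=config.seed)

        stage = _stage("sedation-glm")
        day1_meta = meta[meta["day"] == 1].set_index("patient_id")
        glm_data = pd.DataFrame(
            {
                "outcome": day1_meta["outcome"],
                "power": [
                    band_average(day1[p], rep.band) for p in day1_meta.index
                ],
                "propofol_rate": day1_meta["propofol_rate"],
                "midazolam_rate": day1_meta["midazolam_rate"],
                "fentanyl_rate": day1_meta["fentanyl_rate"],
            }
        )
        fits, failed = [], []
        for model_id in GLM_MODELS:
            try:
                fits.append(fit_sedation_glm(glm_data, model_id))
            except SeparationError as exc:
                logger.warning("GLM %s not identifiable: %s", model_id, exc)
                failed.append(model_id)
        ranked = select_by_aic(fits) if len(fits) >= 2 else fits
        glm_rows = [
            {"model": mid, "rank": np.nan, "aic": np.nan, "loglik": np.nan,
             "n": np.nan, "term": "separation", "coef": np.nan, "se": np.nan,
             "t": np.nan, "p": np.nan}
            for mid in failed
        ]
        for rank, f in enumerate(ranked, start=1):
            for term, coef, se, t, p in zip(
                f.terms, f.coefficients, f.standard_errors,
                f.test_statistics, f.p_values,
            ):
                glm_rows.append(
                    {
                        "model": f.model_id,
                        "rank": rank,
                        "aic": f.aic,
                        "loglik": f.log_likelihood,
                        "n": f.n_obs,
                        "term": term,
                        "coef": coef,
                        "se": se,
                        "t": t,
                        "p": p,
                    }
                )
        cio.write_tsv(pd.DataFrame(glm_rows), out / "glm.tsv", seed=config.seed)
    except ComaSpectraError as exc:
        raise ComaSpectraError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("run complete: %s", out)
    return out
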