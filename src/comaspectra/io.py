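"""Table and container I/O.

All tables are TSV, UTF-8, '.' decimal separator, with '#'-prefixed
header comments carrying the package version and RNG seed.  Missing
values are written as ``NA`` and parsed back as missing, never as zero.
EEG epochs are stored as raw float32 binary with a JSON sidecar (shape,
dtype, sampling rate, labels, positions); EDF reading for real
recordings is available when :mod:`mne` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ContinuousRecording, EpochArray
from .errors import InputError

META_COLUMNS = [
    "patient_id",
    "outcome",
    "day",
    "propofol_rate",
    "midazolam_rate",
    "fentanyl_rate",
    "reactivity",
    "discontinuity_favourable",
    "epileptiform",
]

_RATE_COLUMNS = ["propofol_rate", "midazolam_rate", "fentanyl_rate"]


def write_tsv(df: pd.DataFrame, path, seed=None, comments: list[str] | None = None):
    """Write a TSV with version/seed header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# comaspectra {__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"], keep_default_na=True
    )


def metadata_frame(records) -> pd.DataFrame:
    """One row per patient-day from a list of :class:`PatientRecord`."""
    rows = []
    for rec in records:
        for day in sorted(rec.meta):
            m = rec.meta[day]
            rows.append({c: getattr(m, c) for c in META_COLUMNS})
    return pd.DataFrame(rows, columns=META_COLUMNS)


def write_metadata_tsv(records_or_frame, path, seed=None) -> None:
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else metadata_frame(records_or_frame)
    )
    write_tsv(df, path, seed=seed)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read patient metadata, validating schema and value domains."""
    df = read_tsv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"metadata file missing mandatory columns: {missing}")
    bad = set(df["outcome"].dropna()) - {"FO", "UO"}
    if bad:
        raise InputError(f"malformed outcome values: {sorted(bad)}")
    if not set(df["day"].dropna()).issubset({1, 2}):
        raise InputError("day must be 1 or 2")
    for c in _RATE_COLUMNS:
        vals = df[c].dropna()
        if len(vals) and (vals < 0).any():
            raise InputError(f"negative rates in column {c}")
    return df


def spectra_frame(spectra: dict) -> pd.DataFrame:
    """Long-format table (patient_id, day, electrode, frequency, value)."""
    rows = []
    for pid in sorted(spectra):
        spec = spectra[pid]
        labels = spec.channel_labels or [f"E{i}" for i in range(spec.values.shape[0])]
        f = spec.grid.frequencies
        for ei, ch in enumerate(labels):
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "day": spec.day,
                        "electrode": ch,
                        "frequency": f,
                        "value": spec.values[ei],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def frame_to_spectra(df: pd.DataFrame, grid) -> dict:
    """Inverse of :func:`spectra_frame` for one recording day."""
    from .spectral import PatientSpectrum

    out = {}
    for (pid, day), sub in df.groupby(["patient_id", "day"], sort=True):
        electrodes = list(dict.fromkeys(sub["electrode"]))
        mat = (
            sub.pivot_table(index="electrode", columns="frequency", values="value")
            .reindex(electrodes)
            .to_numpy()
        )
        out[str(pid)] = PatientSpectrum(
            mat, grid, patient_id=str(pid), day=int(day), channel_labels=electrodes
        )
    return out


def write_epochs(ep: EpochArray, path) -> None:
    """Raw float32 binary + JSON sidecar (documented container format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ep.data.astype("<f4").tofile(path)
    sidecar = {
        "shape": list(ep.data.shape),
        "dtype": "<f4",
        "order": "C",
        "fs": ep.fs,
        "channel_labels": list(ep.channel_labels),
        "channel_positions": (
            ep.channel_positions.tolist() if ep.channel_positions is not None else None
        ),
        "version": __version__,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_epochs(path) -> EpochArray:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sc = json.load(fh)
    data = np.fromfile(path, dtype=sc["dtype"]).reshape(sc["shape"]).astype(float)
    pos = sc.get("channel_positions")
    return EpochArray(
        data,
        sc["fs"],
        list(sc["channel_labels"]),
        np.asarray(pos) if pos is not None else None,
    )


def read_edf(path) -> ContinuousRecording:
    """Read a real EDF/EDF+ recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise InputError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return ContinuousRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), None)


def cluster_result_to_json(result) -> dict:
    return {
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "alpha": result.alpha,
        "cluster_alpha": result.cluster_alpha,
        "clusters": [
            {
                "mass": c.mass,
                "sign": "+" if c.sign > 0 else "-",
                "p": c.p,
                "significant": bool(c.significant),
                "bins": sorted([int(e), int(f)] for e, f in c.bins),
            }
            for c in result.clusters
        ],
    }


def predictions_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "score": r.score,
                "predicted": r.predicted,
                "true": r.true,
                "source": r.source,
            }
            for r in records
        ]
    )


def metrics_row(predictor: str, metrics) -> dict:
    """A Tables-1/2-shaped report row for one predictor."""
    c = metrics.counts
    row = {"predictor": predictor, "TP/FP/FN/TN": f"{c.tp}/{c.fp}/{c.fn}/{c.tn}"}
    for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy"):
        row[name.upper() if name in ("ppv", "npv") else name] = str(getattr(metrics, name))
    return row
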