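"""Seeded synthetic cohorts of comatose-patient EEG and metadata.

The generator emulates the statistical structure of a two-day post-arrest
EEG cohort: every patient carries a favourable (FO) or unfavourable (UO)
outcome label and two recordings (Day 1 and Day 2).  Each channel is
1/f^beta Gaussian background activity plus a band-limited oscillation
whose amplitude depends on outcome and day: FO patients on Day 1 carry an
oscillatory power elevation inside ``bump_band`` (default 4.6-15.2 Hz)
that attenuates on Day 2, while the UO spectrum defaults to pure 1/f
background.  The oscillation is band-filtered Gaussian noise with a
patient-specific spectral peak (peak ~ Normal(10 Hz, 1.5 Hz)) on a flat
in-band pedestal, shared across channels through a common source with
per-channel loadings so that neighbouring electrodes covary.  Two
per-patient traits create realistic between-patient score spread: a
lognormal jitter on the oscillation gain, and a lognormal multiplier on
sub-band (delta-range) background power emulating the varying delta
dominance of comatose EEG, which moves the normalized band score through
the normalization denominator.

Sedation infusion rates (propofol, midazolam, fentanyl) are drawn from
truncated-at-zero normals with per-outcome, per-day means/SDs and
administration probabilities matching the marginal structure of the study
population this generator stands in for; clinical EEG markers
(reactivity, discontinuity, epileptiform activity) are Bernoulli draws
with configurable sensitivity for FO, specificity for UO and missingness.
Missing metadata is always encoded explicitly as missing, never as zero.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .containers import ContinuousRecording, EpochArray
from .errors import ConfigError
from .montage import get_montage
from .preprocess import bandpass_filter, resample, segment_epochs

FO, UO = "FO", "UO"
AGENTS = ("propofol", "midazolam", "fentanyl")
MARKERS = ("reactivity", "discontinuity", "epileptiform")


@dataclass(frozen=True)
class SedationAgentParams:
    """Truncated-normal infusion-rate model for one agent/outcome/day."""

    mean: float
    sd: float
    p_administered: float


@dataclass(frozen=True)
class MarkerParams:
    """Binary clinical marker: P(favourable indication | FO), P(unfavourable
    indication | UO), and missingness probability."""

    sensitivity_fo: float
    specificity_uo: float
    p_missing: float


def default_sedation_params() -> dict:
    """Per-(outcome, day) agent rate models.

    Means/SDs (mg/kg/h; fentanyl in ug/kg/h) and administration
    probabilities follow the marginal distribution of a 91-patient
    two-day post-arrest cohort.
    """
    return {
        (FO, 1): {
            "propofol": SedationAgentParams(2.46, 1.23, 34 / 43),
            "midazolam": SedationAgentParams(0.13, 0.10, 20 / 43),
            "fentanyl": SedationAgentParams(0.60, 0.67, 37 / 43),
        },
        (FO, 2): {
            "propofol": SedationAgentParams(2.17, 1.40, 27 / 43),
            "midazolam": SedationAgentParams(0.09, 0.05, 4 / 43),
            "fentanyl": SedationAgentParams(1.31, 1.60, 19 / 43),
        },
        (UO, 1): {
            "propofol": SedationAgentParams(2.32, 1.24, 28 / 46),
            "midazolam": SedationAgentParams(0.12, 0.12, 18 / 46),
            "fentanyl": SedationAgentParams(0.81, 0.64, 28 / 46),
        },
        (UO, 2): {
            "propofol": SedationAgentParams(2.19, 1.46, 16 / 46),
            "midazolam": SedationAgentParams(0.20, 0.24, 5 / 46),
            "fentanyl": SedationAgentParams(0.95, 0.75, 9 / 46),
        },
    }


def default_marker_params() -> dict[str, MarkerParams]:
    return {
        "reactivity": MarkerParams(31 / 39, 31 / 36, 16 / 91),
        "discontinuity": MarkerParams(30 / 44, 33 / 40, 7 / 91),
        "epileptiform": MarkerParams(0.90, 0.50, 0.05),
    }


@dataclass
class CohortConfig:
    """Everything the cohort generator needs; see module docstring."""

    n_fo: int = 45
    n_uo: int = 46
    n_channels: int = 19
    fs_raw: float = 1200.0
    fs_out: float = 500.0
    epoch_len: float = 5.0
    n_epochs_per_recording: int = 120
    bump_band: tuple[float, float] = (4.6, 15.2)
    bump_gain_fo_day1: float = 1.0
    bump_gain_fo_day2: float = 0.2
    bump_gain_uo: float = 0.0
    gain_jitter_sd: float = 0.3  # lognormal sigma of per-patient gain jitter
    osc_peak_mean: float = 10.0
    osc_peak_sd: float = 1.5
    osc_peak_width: float = 2.0  # Hz, Gaussian width of the spectral peak
    osc_floor: float = 1.0  # in-band pedestal relative to peak height
    # the raw support extends this far (Hz) beyond bump_band on each side,
    # compensating the +/-1 Hz spectral smoothing of the analysis so the
    # full-strength smoothed elevation spans exactly bump_band
    edge_widen: float = 1.0
    mixing: float = 0.3  # fraction of oscillatory power from the common source
    background_rms: float = 10.0  # microvolts
    noise_exponent: float = 1.0  # 1/f^beta slope
    # lognormal sigma of the per-patient multiplier on sub-band (< bump_band
    # low edge) background power: emulates varying delta dominance across
    # comatose patients, the main source of between-patient band-score spread
    delta_mod_sd: float = 0.5
    sedation_params: dict = field(default_factory=default_sedation_params)
    sedation_missing_prob: dict = field(
        default_factory=lambda: {FO: 2 / 45, UO: 0.0}
    )
    marker_params: dict = field(default_factory=default_marker_params)
    seed: int = 0

    def validate(self) -> None:
        if self.n_fo < 1:
            raise ConfigError("n_fo", f"must be >= 1, got {self.n_fo}")
        if self.n_uo < 1:
            raise ConfigError("n_uo", f"must be >= 1, got {self.n_uo}")
        if self.fs_out <= 0 or self.fs_raw < self.fs_out:
            raise ConfigError("fs_out", "need 0 < fs_out <= fs_raw")
        n_samp = self.epoch_len * self.fs_out
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ConfigError(
                "epoch_len", "epoch_len * fs_out must be an integer sample count"
            )
        lo, hi = self.bump_band
        if not (2.0 <= lo <= hi <= 40.0):
            raise ConfigError("bump_band", f"must lie within [2, 40], got {self.bump_band}")
        for name in ("bump_gain_fo_day1", "bump_gain_fo_day2", "bump_gain_uo"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "gain must be non-negative")
        if not 0 <= self.mixing <= 1:
            raise ConfigError("mixing", f"must be in [0, 1], got {self.mixing}")
        if self.n_epochs_per_recording < 1:
            raise ConfigError("n_epochs_per_recording", "must be >= 1")
        for key, agents in self.sedation_params.items():
            for agent, p in agents.items():
                if not 0 <= p.p_administered <= 1:
                    raise ConfigError(
                        "sedation_params", f"{key}/{agent}: probability outside [0, 1]"
                    )
                if p.sd < 0:
                    raise ConfigError("sedation_params", f"{key}/{agent}: sd < 0")
        for name in ("gain_jitter_sd", "delta_mod_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "spread parameter must be non-negative")
        for name, m in self.marker_params.items():
            for v in (m.sensitivity_fo, m.specificity_uo, m.p_missing):
                if not 0 <= v <= 1:
                    raise ConfigError(
                        "marker_params", f"{name}: probability outside [0, 1]"
                    )


@dataclass
class PatientMeta:
    """One patient-day of metadata; None encodes missing."""

    patient_id: str
    outcome: str  # FO or UO
    day: int  # 1 or 2
    propofol_rate: float | None = None
    midazolam_rate: float | None = None
    fentanyl_rate: float | None = None
    reactivity: str = "missing"  # present / absent / missing
    discontinuity_favourable: str = "missing"  # yes / no / missing
    epileptiform: str = "missing"  # present / absent / missing


@dataclass
class PatientRecord:
    """A patient with two recordings and per-day metadata."""

    patient_id: str
    outcome: str
    meta: dict[int, PatientMeta]
    eeg: dict[int, EpochArray]


def _gain_for(outcome: str, day: int, config: CohortConfig) -> float:
    if outcome == UO:
        return config.bump_gain_uo
    return config.bump_gain_fo_day1 if day == 1 else config.bump_gain_fo_day2


def _shaped_noise(rng, n: int, envelope: np.ndarray) -> np.ndarray:
    """Gaussian noise with rfft amplitude envelope, unit variance target."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * envelope
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_patient_eeg(
    outcome: str,
    day: int,
    config: CohortConfig,
    rng: np.random.Generator,
    gain: float | None = None,
    delta_mod: float | None = None,
) -> EpochArray:
    """Synthesize one recording and condition it to analysis-ready epochs.

    A continuous multichannel signal is generated at ``fs_raw`` (1/f
    background + outcome/day-scaled oscillation), band-pass filtered
    1-40 Hz, resampled to ``fs_out`` and cut into ``epoch_len``-second
    epochs.  ``gain`` overrides the outcome/day gain and ``delta_mod``
    the patient's low-frequency dominance multiplier (used internally to
    apply per-patient traits).
    """
    config.validate()
    labels, positions = get_montage(config.n_channels)
    n_ch = config.n_channels
    duration = config.n_epochs_per_recording * config.epoch_len
    n = int(round(duration * config.fs_raw))
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs_raw)

    # background: 1/f^beta amplitude envelope (flat below 1 Hz, zero DC),
    # with the patient's delta-dominance multiplier below the analysis band
    env_bg = np.zeros_like(freqs)
    nz = freqs > 0
    env_bg[nz] = np.maximum(freqs[nz], 1.0) ** (-config.noise_exponent / 2)
    if delta_mod is None:
        delta_mod = float(np.exp(rng.normal(0.0, config.delta_mod_sd)))
    env_bg_mod = np.where(freqs < config.bump_band[0], env_bg * np.sqrt(delta_mod), env_bg)
    bg = np.stack([_shaped_noise(rng, n, env_bg_mod) for _ in range(n_ch)])
    bg *= config.background_rms

    if gain is None:
        gain = _gain_for(outcome, day, config)
    if gain > 0:
        lo, hi = config.bump_band
        peak = float(
            np.clip(rng.normal(config.osc_peak_mean, config.osc_peak_sd), lo, hi)
        )
        in_band = (freqs >= lo - config.edge_widen) & (freqs <= hi + config.edge_widen)
        # amplitude relative to the local 1/f background, so the relative
        # in-band power elevation is a pedestal spanning the whole band
        # plus the patient-specific peak
        env_osc = np.where(
            in_band,
            env_bg
            * (
                config.osc_floor
                + np.exp(-0.5 * ((freqs - peak) / config.osc_peak_width) ** 2)
            ),
            0.0,
        )
        # oscillation RMS is set relative to the background's in-band RMS
        band_fraction = (env_bg[in_band] ** 2).sum() / (env_bg**2).sum()
        bg_band_rms = config.background_rms * np.sqrt(band_fraction)
        common = _shaped_noise(rng, n, env_osc)
        loadings = rng.uniform(0.5, 1.5, size=n_ch)
        amp = gain * bg_band_rms
        for c in range(n_ch):
            indep = _shaped_noise(rng, n, env_osc)
            bg[c] += amp * (
                np.sqrt(config.mixing) * loadings[c] * common
                + np.sqrt(1 - config.mixing) * indep
            )

    rec = ContinuousRecording(bg, config.fs_raw, labels, positions)
    rec = bandpass_filter(rec, 1.0, 40.0)
    if config.fs_out != config.fs_raw:
        rec = resample(rec, config.fs_out)
    return segment_epochs(rec, config.epoch_len)


def _draw_sedation(
    meta: PatientMeta, outcome: str, day: int, config: CohortConfig, rng
) -> None:
    if rng.random() < config.sedation_missing_prob.get(outcome, 0.0):
        return  # whole sedation record missing (rates stay None)
    for agent in AGENTS:
        p = config.sedation_params[(outcome, day)][agent]
        if rng.random() < p.p_administered:
            if p.sd == 0:
                rate = p.mean
            else:
                a = (0.0 - p.mean) / p.sd
                rate = float(
                    sps.truncnorm.rvs(a, np.inf, loc=p.mean, scale=p.sd, random_state=rng)
                )
            setattr(meta, f"{agent}_rate", rate)
        else:
            setattr(meta, f"{agent}_rate", 0.0)


def _draw_markers(meta: PatientMeta, outcome: str, config: CohortConfig, rng) -> None:
    drawn = {}
    for name in MARKERS:
        m = config.marker_params[name]
        if rng.random() < m.p_missing:
            drawn[name] = "missing"
            continue
        if outcome == FO:
            favourable = rng.random() < m.sensitivity_fo
        else:
            favourable = not (rng.random() < m.specificity_uo)
        drawn[name] = "favourable" if favourable else "unfavourable"
    table = {"favourable": "present", "unfavourable": "absent", "missing": "missing"}
    meta.reactivity = table[drawn["reactivity"]]
    meta.discontinuity_favourable = {
        "favourable": "yes", "unfavourable": "no", "missing": "missing"
    }[drawn["discontinuity"]]
    # epileptiform activity present is the unfavourable indication
    meta.epileptiform = {
        "favourable": "absent", "unfavourable": "present", "missing": "missing"
    }[drawn["epileptiform"]]


def generate_cohort(
    config: CohortConfig, days: tuple[int, ...] = (1, 2)
) -> list[PatientRecord]:
    """Generate the full cohort: ``n_fo + n_uo`` patients x two recordings.

    Deterministic given ``config.seed``; per-patient random streams are
    spawned from one seed sequence so cohorts of different sizes share no
    state ordering ambiguity.  ``days`` restricts which recordings are
    synthesized (metadata is always produced for both days); day-1 draws
    are identical whether or not day 2 is generated.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    outcomes = [FO] * config.n_fo + [UO] * config.n_uo
    records: list[PatientRecord] = []
    for i, outcome in enumerate(outcomes):
        pid = f"P{i + 1:03d}"
        # one stable triple of independent streams per patient
        children = root.spawn(1)[0].spawn(3)
        rng_meta = np.random.default_rng(children[0])
        rng_day = {1: np.random.default_rng(children[1]),
                   2: np.random.default_rng(children[2])}
        jitter = float(np.exp(rng_meta.normal(0.0, config.gain_jitter_sd)))
        delta_mod = float(np.exp(rng_meta.normal(0.0, config.delta_mod_sd)))
        meta: dict[int, PatientMeta] = {}
        eeg: dict[int, EpochArray] = {}
        markers_drawn = None
        for day in (1, 2):
            m = PatientMeta(patient_id=pid, outcome=outcome, day=day)
            _draw_sedation(m, outcome, day, config, rng_meta)
            if markers_drawn is None:
                _draw_markers(m, outcome, config, rng_meta)
                markers_drawn = (m.reactivity, m.discontinuity_favourable, m.epileptiform)
            else:
                m.reactivity, m.discontinuity_favourable, m.epileptiform = markers_drawn
            if day in days:
                gain = _gain_for(outcome, day, config) * jitter
                eeg[day] = generate_patient_eeg(
                    outcome, day, config, rng_day[day], gain=gain,
                    delta_mod=delta_mod,
                )
            meta[day] = m
        records.append(PatientRecord(pid, outcome, meta, eeg))
    return records


def null_config(config: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A copy of ``config`` with all oscillation gains equal (group-null)."""
    config = config or CohortConfig()
    gain = config.bump_gain_uo
    return replace(
        config,
        bump_gain_fo_day1=gain,
        bump_gain_fo_day2=gain,
        **overrides,
    )
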