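"""Multitaper power spectral estimation on a fixed frequency grid.

Spectra are estimated per epoch and electrode with Slepian (DPSS) tapers:
for a 5 s epoch and a +/-1 Hz half-bandwidth the time-bandwidth product is
NW = 5, giving K = 2*NW - 1 = 9 well-concentrated tapers.  Power at each
grid frequency is the uniform average over tapers of the squared magnitude
of the tapered DFT.  Epochs are averaged and the result normalized so each
electrode's spectrum sums to one over the grid (``per_electrode`` mode) or
so the grand sum over all electrodes and frequencies is one (``global``);
the normalized, unit-free spectrum is what the downstream classifier sees.

The grid is native to the epoch length: a 5 s window yields exactly the
0.2 Hz resolution of the default 2-40 Hz grid, so no zero-padding or
interpolation is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

from .containers import EpochArray
from .errors import ConfigError, InputError


@dataclass(frozen=True)
class SpectrumGrid:
    """Uniform analysis grid, 2.0-40.0 Hz in 0.2 Hz steps by default."""

    fmin: float = 2.0
    fmax: float = 40.0
    step: float = 0.2

    def __post_init__(self):
        if self.step <= 0 or self.fmax < self.fmin:
            raise ConfigError("grid", f"invalid grid {self.fmin}-{self.fmax}/{self.step}")

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.fmax - self.fmin) / self.step)) + 1
        return np.round(self.fmin + self.step * np.arange(n), 10)

    @property
    def n_bins(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class FrequencyBand:
    """A closed frequency interval [fmin, fmax] on the analysis grid."""

    fmin: float
    fmax: float

    def __post_init__(self):
        if self.fmax < self.fmin:
            raise ConfigError("band", f"fmax {self.fmax} < fmin {self.fmin}")

    def bin_mask(self, grid: SpectrumGrid) -> np.ndarray:
        f = grid.frequencies
        mask = (f >= self.fmin - 1e-9) & (f <= self.fmax + 1e-9)
        if not mask.any():
            raise ConfigError("band", f"({self.fmin}, {self.fmax}) selects no grid bin")
        return mask


@dataclass
class PatientSpectrum:
    """Normalized power, electrodes x frequencies, for one patient-recording."""

    values: np.ndarray
    grid: SpectrumGrid
    patient_id: str = ""
    day: int = 1
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_bins:
            raise InputError(
                f"spectrum shape {self.values.shape} does not match "
                f"{self.grid.n_bins}-bin grid"
            )
        if np.any(self.values < 0):
            raise InputError("negative power values")


def dpss_tapers(n_samples: int, half_bandwidth: float, fs: float) -> np.ndarray:
    """Orthonormal Slepian tapers, K = 2*NW - 1, as a (K, n_samples) matrix.

    ``NW = (n_samples / fs) * half_bandwidth`` is the time-(half-)bandwidth
    product; ``half_bandwidth`` is the one-sided smoothing width in Hz.
    """
    nw = (n_samples / fs) * half_bandwidth
    if nw < 1:
        raise ConfigError(
            "half_bandwidth",
            f"time-bandwidth product {nw:.3f} < 1; widen the smoothing "
            "or lengthen the window",
        )
    k = int(round(2 * nw)) - 1
    tapers = windows.dpss(n_samples, nw, Kmax=k, norm=2)
    return np.atleast_2d(tapers)


def multitaper_psd(
    epoch: np.ndarray,
    fs: float,
    grid: SpectrumGrid | None = None,
    half_bandwidth: float = 1.0,
    tapers: np.ndarray | None = None,
) -> np.ndarray:
    """Multitaper PSD of one epoch (channels x samples) on the grid bins.

    Power at grid frequency f is ``mean_k |DFT(taper_k * x)[f]|^2``.  The
    epoch duration must be an exact multiple of the grid step's reciprocal
    (no zero padding); precomputed ``tapers`` may be passed to amortize the
    DPSS solve across epochs.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    grid = grid or SpectrumGrid()
    n = epoch.shape[-1]
    df = fs / n
    if abs(grid.step / df - round(grid.step / df)) > 1e-9 or grid.step < df - 1e-12:
        raise ConfigError(
            "grid",
            f"grid step {grid.step} Hz incompatible with window resolution "
            f"{df:.6g} Hz (no zero padding)",
        )
    if tapers is None:
        tapers = dpss_tapers(n, half_bandwidth, fs)
    bins = np.round(grid.frequencies / df).astype(int)
    if bins[-1] > n // 2:
        raise ConfigError("grid", "grid extends beyond Nyquist")
    # (channels, K, n) tapered copies -> rfft -> power averaged over K
    tapered = epoch[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)[..., bins]
    return (spec.real**2 + spec.imag**2).mean(axis=1)


def epochs_psd(
    ep: EpochArray,
    grid: SpectrumGrid | None = None,
    half_bandwidth: float = 1.0,
) -> np.ndarray:
    """PSD of every epoch of an :class:`EpochArray` (epochs x channels x freqs)."""
    grid = grid or SpectrumGrid()
    tapers = dpss_tapers(ep.n_samples, half_bandwidth, ep.fs)
    bins = np.round(grid.frequencies / (ep.fs / ep.n_samples)).astype(int)
    if bins[-1] > ep.n_samples // 2:
        raise ConfigError("grid", "grid extends beyond Nyquist")
    df = ep.fs / ep.n_samples
    if abs(grid.step / df - round(grid.step / df)) > 1e-9 or grid.step < df - 1e-12:
        raise ConfigError(
            "grid",
            f"grid step {grid.step} Hz incompatible with window resolution "
            f"{df:.6g} Hz",
        )
    tapered = ep.data[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)[..., bins]
    return (spec.real**2 + spec.imag**2).mean(axis=2)


def patient_spectrum(
    epoch_psds: np.ndarray,
    grid: SpectrumGrid | None = None,
    mode: str = "per_electrode",
    patient_id: str = "",
    day: int = 1,
    channel_labels: list[str] | None = None,
) -> PatientSpectrum:
    """Average epoch PSDs and normalize by the sum of spectral values.

    ``per_electrode`` divides each electrode's mean spectrum by its own sum
    over the grid (each row then sums to 1); ``global`` divides everything
    by the grand sum.
    """
    epoch_psds = np.asarray(epoch_psds, dtype=float)
    if epoch_psds.ndim != 3 or epoch_psds.shape[0] < 1:
        raise InputError("epoch_psds must be epochs x channels x freqs, >=1 epoch")
    mean = epoch_psds.mean(axis=0)
    if mode == "per_electrode":
        denom = mean.sum(axis=1, keepdims=True)
    elif mode == "global":
        denom = np.full((mean.shape[0], 1), mean.sum())
    else:
        raise ConfigError("mode", f"unknown normalization mode {mode!r}")
    if np.any(denom <= 0):
        raise InputError("all-zero spectrum cannot be normalized")
    return PatientSpectrum(
        mean / denom,
        grid or SpectrumGrid(),
        patient_id=patient_id,
        day=day,
        channel_labels=channel_labels or [],
    )


def band_average(spec: PatientSpectrum, band: FrequencyBand) -> float:
    """Unweighted mean of normalized power over all electrodes and band bins."""
    mask = band.bin_mask(spec.grid)
    return float(spec.values[:, mask].mean())
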