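"""In-memory containers for EEG recordings and epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


def _check_channels(data_channels: int, labels, positions) -> None:
    if len(labels) != data_channels:
        raise InputError(
            f"{len(labels)} channel labels for {data_channels} data channels"
        )
    if len(set(labels)) != len(labels):
        raise InputError("channel labels are not unique")
    if positions.shape[0] != data_channels:
        raise InputError(
            f"{positions.shape[0]} channel positions for "
            f"{data_channels} data channels"
        )


@dataclass
class ContinuousRecording:
    """A continuous multichannel EEG recording.

    ``data`` is channels x samples in microvolts; ``positions`` are 2-D
    (or 3-D) template-montage coordinates, one row per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError(f"recording data must be 2-D, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise InputError("recording contains non-finite values")
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            _check_channels(
                self.data.shape[0], self.channel_labels, self.channel_positions
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochArray:
    """Segmented EEG: epochs x channels x samples at a fixed rate."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InputError(f"epoch data must be 3-D, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise InputError("epochs contain non-finite values")
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            _check_channels(
                self.data.shape[1], self.channel_labels, self.channel_positions
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
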