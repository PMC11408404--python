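"""Shared domain containers.

``Recording`` is the in-memory form of a multi-channel EEG recording and
``SpindleEvent`` a single annotated (or simulated) sleep spindle.  They live
here so that the simulator and the I/O layer can both use them without a
circular import; the public homes are :mod:`spindilometer.eeg_io` and
:mod:`spindilometer.simkit`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six referential EEG derivations of a standard PSG montage.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F4-M1", "C4-M1", "O2-M1", "F3-M2", "C3-M2", "O1-M2",
)

SIGMA_BAND = (11.0, 16.0)


@dataclass
class Recording:
    """Multi-channel EEG samples in microvolts.

    Parameters
    ----------
    channel_labels : list of str
        Unique channel names, one per row of ``samples``.
    fs : float
        Sampling rate in Hz, shared by all channels.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    start_time : float
        Recording start, seconds since the epoch (informational).
    missing_mask : ndarray of bool or None
        ``True`` marks a missing/invalid sample; same shape as ``samples``.
    """

    channel_labels: list[str]
    fs: float
    samples: np.ndarray
    start_time: float = 0.0
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.samples.shape:
                raise ValueError("missing_mask shape must match samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present; available: {self.channel_labels}"
            ) from None
        return self.samples[idx]


@dataclass(frozen=True)
class SpindleEvent:
    """One sleep spindle: a sigma-band (11-16 Hz) burst of 0.5-3 s."""

    channel: str
    onset_s: float
    duration_s: float
    freq_hz: float
    amp_uv: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if not 0.5 <= self.duration_s <= 3.0:
            raise ValueError("spindle duration must lie in [0.5, 3] s")
        if not 11.0 <= self.freq_hz <= 16.0:
            raise ValueError("spindle frequency must lie in the sigma band [11, 16] Hz")
        if self.amp_uv < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s
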