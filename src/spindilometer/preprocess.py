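"""Data preparation: imputation, min-max normalization, epoching, splitting.

The pipeline convention is 30-s scoring epochs, each divided into three
10-s frames -- the frame is the unit on which features are computed and
spindle presence is labeled.  Normalization is min-max to [0, 1], applied
per channel per recording (not per frame), so relative amplitude contrast
between frames survives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from ._types import Recording

__all__ = [
    "Segment",
    "SplitIndices",
    "impute_missing",
    "minmax_normalize",
    "segment_recording",
    "split_dataset",
]


@dataclass
class Segment:
    """One 10-s single-channel window of a recording."""

    channel: str
    epoch_index: int        # 0-based 30-s epoch number
    frame_index: int        # 0..(epoch_s/frame_s - 1) within the epoch
    start_sample: int
    values: np.ndarray

    @property
    def frame_number(self) -> int:
        """Flat frame index within the channel (epoch * frames_per_epoch + frame)."""
        return self.epoch_index * 3 + self.frame_index


@dataclass
class SplitIndices:
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int
    stratified: bool


def impute_missing(signal: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Replace missing samples with the mean of the observed samples.

    ``mask`` marks missing positions (True = missing).  Observed samples are
    untouched.  Raises if every sample is missing (no mean exists).
    """
    x = np.asarray(signal, dtype=float)
    if mask is None:
        return x.copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("mask shape must match signal shape")
    if mask.all():
        raise ValueError("all samples missing: mean imputation undefined")
    out = x.copy()
    out[mask] = x[~mask].mean()
    return out


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map to [0, 1]: minimum -> 0, maximum -> 1; constant input -> all zeros."""
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("minmax_normalize requires finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def segment_recording(
    recording: Recording, epoch_s: float = 30.0, frame_s: float = 10.0
) -> list[Segment]:
    """Slice a recording into contiguous 10-s frames grouped by 30-s epoch.

    A trailing partial epoch is discarded.  Per channel the count is
    ``(epoch_s/frame_s) * floor(duration / epoch_s)`` frames.
    """
    fs = recording.fs
    if abs(frame_s * fs - round(frame_s * fs)) > 1e-9:
        raise ValueError("frame_s * fs must be an integer number of samples")
    ratio = epoch_s / frame_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"frame_s={frame_s} must divide epoch_s={epoch_s}")
    frames_per_epoch = int(round(ratio))
    frame_len = int(round(frame_s * fs))
    epoch_len = frame_len * frames_per_epoch
    n_epochs = recording.n_samples // epoch_len
    if n_epochs == 0:
        raise ValueError(
            f"recording ({recording.duration_s:.1f} s) shorter than one "
            f"{epoch_s:.0f}-s epoch"
        )
    segments = []
    for ch_idx, label in enumerate(recording.channel_labels):
        for e in range(n_epochs):
            for f in range(frames_per_epoch):
                start = e * epoch_len + f * frame_len
                segments.append(
                    Segment(
                        channel=label,
                        epoch_index=e,
                        frame_index=f,
                        start_sample=start,
                        values=recording.samples[ch_idx, start : start + frame_len],
                    )
                )
    return segments


def split_dataset(
    segment_ids: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> SplitIndices:
    """Deterministic 70/30 train/test split of segment ids.

    With ``stratified=True`` (default) the per-class train fraction is within
    one segment of ``train_frac``; this requires both classes present.
    """
    ids = np.asarray(segment_ids)
    y = np.asarray(labels)
    if ids.shape != y.shape:
        raise ValueError("segment_ids and labels must align")
    if ids.size < 2:
        raise ValueError("need at least two segments to split")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if stratified and len(np.unique(y)) < 2:
        raise ValueError("stratified split requires both classes present")
    train_ids, test_ids = train_test_split(
        ids,
        train_size=train_frac,
        random_state=seed,
        shuffle=True,
        stratify=y if stratified else None,
    )
    return SplitIndices(
        train_ids=np.sort(train_ids),
        test_ids=np.sort(test_ids),
        seed=seed,
        stratified=stratified,
    )
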