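"""Read and write EEG recordings (EDF) and spindle annotation tables (CSV).

The recording format is 16-bit continuous EDF/EDF+, the de-facto exchange
format for polysomnography.  The codec here is deliberately minimal: one
data-record per second, linear digital-to-physical scaling from the header
fields, microvolt units.  Digital samples falling outside the declared
digital range are flagged in ``missing_mask`` rather than silently clipped.

Annotations travel as plain CSV with columns
``channel,onset_s,duration_s,freq_hz,amp_uv`` (header required).
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import Recording, SpindleEvent

__all__ = [
    "Recording",
    "EDFFormatError",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
]

_DIG_MIN, _DIG_MAX = -32768, 32767
ANNOTATION_COLUMNS = ["channel", "onset_s", "duration_s", "freq_hz", "amp_uv"]


class EDFFormatError(ValueError):
    """Malformed or unsupported EDF content; the message names the field."""


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _pack(value: str, length: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > length:
        raise EDFFormatError(f"header field {value!r} exceeds {length} bytes")
    return b.ljust(length)


def write_edf(recording: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as 16-bit continuous EDF (1-s data records).

    Per-channel physical min/max are set to the data range padded by 1%, so
    quantization error is at most one step of the 16-bit physical range.
    NaN samples are rejected: impute first.
    """
    if recording.n_channels == 0:
        raise ValueError("cannot write an EDF with no channels")
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError(
            "samples contain NaN/inf; impute missing values before writing EDF"
        )
    fs = recording.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9 or spr <= 0:
        raise EDFFormatError(
            f"sampling rate {fs} Hz is not an integer; cannot use 1-s EDF records"
        )
    ns = recording.n_channels
    n_samples = recording.n_samples
    n_records = int(np.ceil(n_samples / spr))

    phys_min = np.empty(ns)
    phys_max = np.empty(ns)
    digital = np.zeros((ns, n_records * spr), dtype=np.int16)
    for i in range(ns):
        x = recording.samples[i]
        lo, hi = float(x.min()), float(x.max())
        span = hi - lo
        if span == 0:
            pad = max(1.0, abs(hi) * 0.01)
        else:
            pad = 0.01 * span
        phys_min[i], phys_max[i] = lo - pad, hi + pad
        gain = (phys_max[i] - phys_min[i]) / (_DIG_MAX - _DIG_MIN)
        dig = np.round((x - phys_min[i]) / gain + _DIG_MIN)
        padded = np.full(n_records * spr, np.round((0.0 - phys_min[i]) / gain + _DIG_MIN))
        padded[:n_samples] = dig
        digital[i] = np.clip(padded, _DIG_MIN, _DIG_MAX).astype(np.int16)

    header = b"".join([
        _pack("0", 8),
        _pack("X X X X", 80),                       # patient id (anonymous)
        _pack("Startdate X X X X", 80),             # recording id
        _pack("01.01.00", 8),
        _pack("00.00.00", 8),
        _pack(str(256 * (1 + ns)), 8),
        _pack("", 44),
        _pack(str(n_records), 8),
        _pack("1", 8),                               # record duration, seconds
        _pack(str(ns), 4),
    ])
    sig = b"".join(_pack(lbl[:16], 16) for lbl in recording.channel_labels)
    sig += b"".join(_pack("", 80) for _ in range(ns))
    sig += b"".join(_pack("uV", 8) for _ in range(ns))
    sig += b"".join(_pack(f"{phys_min[i]:.8g}"[:8], 8) for i in range(ns))
    sig += b"".join(_pack(f"{phys_max[i]:.8g}"[:8], 8) for i in range(ns))
    sig += b"".join(_pack(str(_DIG_MIN), 8) for _ in range(ns))
    sig += b"".join(_pack(str(_DIG_MAX), 8) for _ in range(ns))
    sig += b"".join(_pack("", 80) for _ in range(ns))
    sig += b"".join(_pack(str(spr), 8) for _ in range(ns))
    sig += b"".join(_pack("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())


def read_edf(
    path: str | os.PathLike, channels: list[str] | None = None
) -> Recording:
    """Read a continuous 16-bit EDF/EDF+ file into microvolts.

    Parameters
    ----------
    path : path-like
        EDF file to read.
    channels : list of str, optional
        Subset of channel labels to load, in the requested order; default
        all signal channels ('EDF Annotations' streams are skipped).

    Digital samples outside the header's digital range are flagged in
    ``missing_mask`` (the physical value is still the linear map of the
    stored integer).
    """
    with open(path, "rb") as fh:
        raw = fh.read(256)
        if len(raw) < 256:
            raise EDFFormatError("file shorter than the 256-byte EDF header")
        if _field(raw, 0, 8) != "0":
            raise EDFFormatError(f"version field is {_field(raw, 0, 8)!r}, expected '0'")
        reserved = _field(raw, 192, 44)
        if reserved.startswith("EDF+D"):
            raise EDFFormatError("reserved field declares discontinuous EDF+D; only continuous files are supported")
        try:
            n_records = int(_field(raw, 236, 8))
            record_dur = float(_field(raw, 244, 8))
            ns = int(_field(raw, 252, 4))
        except ValueError as exc:
            raise EDFFormatError(f"non-numeric header count field: {exc}") from None
        if ns <= 0:
            raise EDFFormatError("number-of-signals field is not positive")
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise EDFFormatError("truncated signal header block")

        def col(offset: int, width: int, j: int) -> str:
            return sig[offset * ns + j * width : offset * ns + (j + 1) * width] \
                .decode("ascii", errors="replace").strip()

        # byte offsets of the per-signal field blocks: label 0, transducer
        # 16, phys dim 96, phys min 104, phys max 112, dig min 120, dig max
        # 128, prefiltering 136, samples/record 216, reserved 224
        labels = [col(0, 16, j) for j in range(ns)]
        try:
            pmin = [float(col(104, 8, j)) for j in range(ns)]
            pmax = [float(col(112, 8, j)) for j in range(ns)]
            dmin = [int(float(col(120, 8, j))) for j in range(ns)]
            dmax = [int(float(col(128, 8, j))) for j in range(ns)]
            spr = [int(col(216, 8, j)) for j in range(ns)]
        except ValueError as exc:
            raise EDFFormatError(f"non-numeric signal scaling field: {exc}") from None
        data = np.frombuffer(fh.read(), dtype="<i2")

    keep = [j for j in range(ns) if labels[j] != "EDF Annotations"]
    if channels is not None:
        available = [labels[j] for j in keep]
        missing = [c for c in channels if c not in available]
        if missing:
            raise KeyError(
                f"channels {missing} not in file; available: {available}"
            )
        keep = [labels.index(c) for c in channels]

    rec_len = sum(spr)
    if data.size < n_records * rec_len:
        raise EDFFormatError("data section shorter than n_records declares")
    data = data[: n_records * rec_len].reshape(n_records, rec_len)
    offsets = np.concatenate([[0], np.cumsum(spr)])

    fs_set = {spr[j] / record_dur for j in keep}
    if len(fs_set) > 1:
        raise EDFFormatError(
            f"channels have differing sampling rates {sorted(fs_set)}"
        )
    fs = fs_set.pop()

    out = []
    masks = []
    for j in keep:
        dig = data[:, offsets[j] : offsets[j + 1]].reshape(-1).astype(float)
        if dmax[j] == dmin[j]:
            raise EDFFormatError(f"signal {labels[j]!r} has zero digital range")
        gain = (pmax[j] - pmin[j]) / (dmax[j] - dmin[j])
        out.append((dig - dmin[j]) * gain + pmin[j])
        masks.append((dig < dmin[j]) | (dig > dmax[j]))
    mask = np.vstack(masks)
    return Recording(
        channel_labels=[labels[j] for j in keep],
        fs=fs,
        samples=np.vstack(out),
        missing_mask=mask if mask.any() else None,
    )


def write_annotations(events: list[SpindleEvent], path: str | os.PathLike) -> None:
    """Write spindle events as CSV, sorted by (channel, onset)."""
    rows = sorted(events, key=lambda e: (e.channel, e.onset_s))
    df = pd.DataFrame(
        [(e.channel, e.onset_s, e.duration_s, e.freq_hz, e.amp_uv) for e in rows],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_annotations(
    path: str | os.PathLike, channels: list[str] | None = None
) -> list[SpindleEvent]:
    """Read spindle events from CSV; validates rows and sorts by (channel, onset).

    ``channels``, when given, is the set of legal channel labels; a row
    naming any other channel raises with its (1-based data) row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation CSV missing columns {missing_cols}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.duration_s <= 0:
            raise ValueError(f"row {i}: non-positive duration {row.duration_s}")
        if channels is not None and row.channel not in channels:
            raise ValueError(
                f"row {i}: unknown channel {row.channel!r}; expected one of {list(channels)}"
            )
        events.append(
            SpindleEvent(
                channel=str(row.channel),
                onset_s=float(row.onset_s),
                duration_s=float(row.duration_s),
                freq_hz=float(row.freq_hz),
                amp_uv=float(row.amp_uv),
            )
        )
    events.sort(key=lambda e: (e.channel, e.onset_s))
    return events
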