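"""Denoising, normalisation and segmentation of raw ECG records.

The pipeline order is fixed: denoise -> normalize -> segment.  Normalisation
is per record (before segmentation) so relative amplitude differences between
segments of one record are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CLASSES, EcgRecord

DEFAULT_DENOISE_WINDOW = 5
DEFAULT_N_SEGMENTS = 6


@dataclass
class Segment:
    """A contiguous sub-signal of one record, inheriting its label."""

    parent_id: str
    label: str
    segment_index: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.segment_index < 0:
            raise ValueError("segment_index must be >= 0")

    def __len__(self) -> int:
        return self.samples.size


def denoise(samples: np.ndarray, window: int = DEFAULT_DENOISE_WINDOW) -> np.ndarray:
    """Centered moving-average smoother with reflected boundary padding.

    Output length equals input length.  ``window`` must be odd, positive and
    no longer than the signal.
    """
    x = np.asarray(samples, dtype=np.float64)
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    if window == 1:
        return x.copy()
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    csum = np.cumsum(np.concatenate(([0.0], padded)))
    return (csum[window:] - csum[:-window]) / window


def normalize(samples: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant signal maps to all 0.5."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot normalize non-finite values")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def segment(record: EcgRecord, n_segments: int = DEFAULT_N_SEGMENTS) -> list[Segment]:
    """Split a record into equal-length contiguous segments.

    Each segment has length ``floor(len(record)/n_segments)``; trailing
    remainder samples are discarded (65,535 samples / 6 -> six segments of
    10,922 samples, 3 discarded).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    n = len(record)
    if n_segments > n:
        raise ValueError(f"n_segments {n_segments} exceeds record length {n}")
    seg_len = n // n_segments
    return [
        Segment(
            parent_id=record.record_id,
            label=record.label,
            segment_index=i,
            samples=record.samples[i * seg_len : (i + 1) * seg_len],
        )
        for i in range(n_segments)
    ]


def preprocess_record(
    record: EcgRecord,
    window: int = DEFAULT_DENOISE_WINDOW,
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> list[Segment]:
    """denoise -> normalize -> segment, returning the record's segments."""
    cleaned = normalize(denoise(record.samples, window))
    return segment(
        EcgRecord(record.record_id, record.label, cleaned, record.sampling_rate),
        n_segments,
    )
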