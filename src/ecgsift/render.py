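"""Rasterisation of 1-D signal segments into RGB images.

Each segment is drawn as a connected black polyline on a white background,
with no axes, ticks or margins beyond a small fixed pad.  The y axis is
autoscaled per segment (the segment's own [min, max] spans the drawable
height), so rendering is invariant to global amplitude scaling of the
segment.  Rasterisation is integer arithmetic with no antialiasing, hence
bit-identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .preprocess import Segment

DEFAULT_SIZE = 200
DEFAULT_LINE_WIDTH = 1
DEFAULT_PAD = 2

WHITE = 255


@dataclass
class SignalImage:
    """An H x W x 3 8-bit raster of one segment."""

    pixels: np.ndarray
    label: str
    source: tuple[str, int]  # (parent_id, segment_index)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path, format="PNG")

    @classmethod
    def load(cls, path, label: str, source: tuple[str, int]) -> "SignalImage":
        with Image.open(path) as img:
            pixels = np.asarray(img.convert("RGB"), dtype=np.uint8)
        return cls(pixels, label, source)

    def filename(self) -> str:
        parent, idx = self.source
        return f"{parent}_s{idx}.png"


def _fill_spans(mask: np.ndarray, cols: np.ndarray, ylo: np.ndarray, yhi: np.ndarray) -> None:
    """Set mask[y, c] = True for ylo[i] <= y <= yhi[i] at column cols[i]."""
    lengths = yhi - ylo + 1
    rows = np.repeat(ylo, lengths) + _ragged_arange(lengths)
    mask[rows, np.repeat(cols, lengths)] = True


def _ragged_arange(lengths: np.ndarray) -> np.ndarray:
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(lengths)[:-1]
    out[ends] = 1 - lengths[:-1]
    return np.cumsum(out)


def polyline_mask(
    xs: np.ndarray, ys: np.ndarray, height: int, width: int
) -> np.ndarray:
    """Boolean mask of a connected polyline through integer points (xs, ys).

    ``xs`` must be non-decreasing (sample index maps monotonically to the x
    axis).  Consecutive points in the same or adjacent columns are joined by
    vertical span fills (the fast, common case when there are many samples
    per pixel column); wider jumps fall back to a per-column linear walk.
    """
    mask = np.zeros((height, width), dtype=bool)
    if xs.size == 1:
        mask[ys[0], xs[0]] = True
        return mask
    c0, c1 = xs[:-1], xs[1:]
    y0, y1 = ys[:-1], ys[1:]
    dx = c1 - c0

    same = dx == 0
    if np.any(same):
        _fill_spans(
            mask,
            c0[same],
            np.minimum(y0[same], y1[same]),
            np.maximum(y0[same], y1[same]),
        )
    adj = dx == 1
    if np.any(adj):
        ym = (y0[adj] + y1[adj]) // 2
        _fill_spans(mask, c0[adj], np.minimum(y0[adj], ym), np.maximum(y0[adj], ym))
        _fill_spans(mask, c1[adj], np.minimum(ym, y1[adj]), np.maximum(ym, y1[adj]))
    for i in np.nonzero(dx > 1)[0]:  # sparse segments: walk the columns
        a, b, ya, yb = int(c0[i]), int(c1[i]), int(y0[i]), int(y1[i])
        bounds = np.rint(ya + (yb - ya) * (np.arange(a, b + 1) - a) / (b - a)).astype(int)
        entry = np.concatenate(([ya], bounds[:-1]))
        lo = np.minimum(entry, bounds)
        hi = np.maximum(entry, bounds)
        _fill_spans(mask, np.arange(a, b + 1), lo, hi)
    return mask


def render_segment(
    seg: Segment,
    width: int = DEFAULT_SIZE,
    height: int = DEFAULT_SIZE,
    line_width: int = DEFAULT_LINE_WIDTH,
    pad: int = DEFAULT_PAD,
    value_range: tuple[float, float] | None = None,
) -> SignalImage:
    """Render one segment as a white-background black-trace RGB raster.

    Sample index maps linearly to [0, width-1]; the segment's own [min, max]
    (or an explicit ``value_range``, for a global y scale shared across
    segments) maps linearly to [height-1-pad, pad] (larger values higher).
    A constant segment draws at mid-height.
    """
    x = seg.samples
    if x.size == 0:
        raise ValueError("cannot render an empty segment")
    if width < 16 or height < 16:
        raise ValueError("width and height must be >= 16")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")

    if value_range is not None:
        lo, hi = float(value_range[0]), float(value_range[1])
        x = np.clip(x, lo, hi)
    else:
        lo, hi = float(np.min(x)), float(np.max(x))
    norm = np.full(x.size, 0.5) if hi == lo else (x - lo) / (hi - lo)
    xs = np.rint(np.arange(x.size) * (width - 1) / max(x.size - 1, 1)).astype(np.int64)
    ys = np.rint(pad + (height - 1 - 2 * pad) * (1.0 - norm)).astype(np.int64)

    mask = polyline_mask(xs, ys, height, width)
    if line_width > 1:
        from scipy.ndimage import binary_dilation

        mask = binary_dilation(mask, structure=np.ones((line_width, line_width), bool))

    pixels = np.full((height, width, 3), WHITE, dtype=np.uint8)
    pixels[mask] = 0
    return SignalImage(pixels, seg.label, (seg.parent_id, seg.segment_index))
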