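"""Scale-invariant keypoint features (SIFT), keypoint overlay, and HOG.

The detector finds extrema of a difference-of-Gaussians (DoG) scale space

    L(a, b, sigma) = G(a, b, sigma) * I(a, b)          (Gaussian blur)
    D_i = L_{i+1} - L_i                                (adjacent-level DoG)

refines them to subpixel position/scale with a second-order Taylor fit,
rejects low-contrast and edge-like points, assigns gradient orientations,
and describes each keypoint with the classic 4 x 4 x 8 = 128-dimensional
gradient-orientation histogram (L2-normalised, clamped at 0.2,
renormalised).  Everything in this module is deterministic.

The keypoint *overlay* is the fusion step feeding the CNN: detected
keypoints are drawn as red circles (radius = keypoint scale) onto the RGB
rendering, so the classifier input remains an H x W x 3 image.

HOG (histogram of oriented gradients) is the comparison descriptor: unsigned
gradient orientations binned per cell, block-normalised over sliding blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import correlate1d

from .render import SignalImage

#: Fixed luma weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_N_OCTAVES = 4
DEFAULT_N_INTERVALS = 3
DEFAULT_BASE_SIGMA = 1.6
DEFAULT_CONTRAST_THRESHOLD = 0.03
DEFAULT_EDGE_RATIO = 10.0

_MIN_OCTAVE_SIZE = 8


def to_grayscale(image) -> np.ndarray:
    """Return a [0, 1] float grayscale array from an image or raw array."""
    pixels = image.pixels if isinstance(image, SignalImage) else np.asarray(image)
    if pixels.ndim == 2:
        gray = pixels.astype(np.float64)
        return gray / 255.0 if pixels.dtype == np.uint8 else gray
    gray = pixels.astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
    if pixels.dtype == np.uint8:
        gray /= 255.0
    return gray


def gaussian_2d(a: float, b: float, sigma: float) -> float:
    """The 2-D Gaussian G(a, b, sigma) = exp(-(a^2+b^2)/(2 sigma^2)) / (2 pi sigma^2)."""
    return math.exp(-(a * a + b * b) / (2.0 * sigma * sigma)) / (
        2.0 * math.pi * sigma * sigma
    )


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Truncated discrete 1-D Gaussian kernel, renormalised to sum 1."""
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with reflected borders; sigma 0 copies."""
    if sigma <= 0:
        return image.copy()
    k = gaussian_kernel(sigma)
    out = correlate1d(image, k, axis=0, mode="reflect")
    return correlate1d(out, k, axis=1, mode="reflect")


@dataclass
class ScaleSpace:
    """Per-octave Gaussian stacks; each octave spatially halves the previous."""

    octaves: list[np.ndarray]  # each (n_levels, H_o, W_o)
    sigmas: np.ndarray  # per-level sigma within an octave
    k: float
    n_intervals: int
    base_sigma: float

    @property
    def n_levels(self) -> int:
        return self.sigmas.size


@dataclass
class DoGStack:
    """Adjacent-level differences of a scale space (levels - 1 per octave)."""

    octaves: list[np.ndarray]
    sigmas: np.ndarray
    k: float
    n_intervals: int
    base_sigma: float


@dataclass
class Keypoint:
    """A subpixel scale-space extremum in original-image coordinates."""

    x: float
    y: float
    octave: int
    interval: int
    sigma: float
    response: float
    orientation: float = 0.0


@dataclass
class SiftDescriptor:
    """A 128-d non-negative gradient-histogram vector with unit L2 norm."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (128,):
            raise ValueError(f"descriptor must have 128 values, got {self.values.shape}")


@dataclass
class HogDescriptor:
    values: np.ndarray = field(repr=False)
    geometry: tuple[int, int, int, int]  # (cell_px, block_cells, stride_cells, n_bins)


def build_scale_space(
    image,
    n_octaves: int = DEFAULT_N_OCTAVES,
    n_intervals: int = DEFAULT_N_INTERVALS,
    base_sigma: float = DEFAULT_BASE_SIGMA,
) -> ScaleSpace:
    """Build the Gaussian scale space with ``n_intervals + 3`` levels per octave.

    Level i of each octave sits at sigma = base_sigma * k**i with
    k = 2**(1/n_intervals); the next octave starts from the level at
    2*base_sigma, downsampled by 2 (floor division of the spatial size).
    """
    gray = to_grayscale(image)
    if n_octaves < 1 or n_intervals < 1:
        raise ValueError("n_octaves and n_intervals must be >= 1")
    h, w = gray.shape
    if min(h, w) < 16:
        raise ValueError(f"image {h}x{w} too small; need at least 16x16")
    if min(h, w) // 2 ** (n_octaves - 1) < _MIN_OCTAVE_SIZE:
        raise ValueError(
            f"image {h}x{w} too small for {n_octaves} octaves "
            f"(coarsest octave would be below {_MIN_OCTAVE_SIZE} px)"
        )
    n_levels = n_intervals + 3
    k = 2.0 ** (1.0 / n_intervals)
    sigmas = base_sigma * k ** np.arange(n_levels)

    octaves: list[np.ndarray] = []
    base = gray
    for o in range(n_octaves):
        if o == 0:
            # The input is treated as unblurred; absolute sigmas apply.
            levels = [gaussian_blur(base, s) for s in sigmas]
        else:
            # The octave base already carries base_sigma on its grid.
            deltas = np.sqrt(np.maximum(sigmas**2 - base_sigma**2, 0.0))
            levels = [gaussian_blur(base, d) for d in deltas]
        octaves.append(np.stack(levels))
        base = levels[n_intervals][::2, ::2]
    return ScaleSpace(octaves, sigmas, k, n_intervals, base_sigma)


def compute_dog(space: ScaleSpace) -> DoGStack:
    """Elementwise adjacent-level differences D_i = L_{i+1} - L_i per octave."""
    stacks = []
    for octave in space.octaves:
        if octave.shape[0] < 2:
            raise ValueError("each octave needs at least 2 Gaussian levels")
        stacks.append(octave[1:] - octave[:-1])
    return DoGStack(stacks, space.sigmas, space.k, space.n_intervals, space.base_sigma)


def detect_extrema(dog: DoGStack) -> list[tuple[int, int, int, int]]:
    """Integer-grid candidates: voxels strictly above or below all 26 neighbors.

    Returns ``(octave, level, row, col)`` tuples; border voxels (in scale or
    space) are excluded.
    """
    candidates: list[tuple[int, int, int, int]] = []
    offsets = [
        (ds, dy, dx)
        for ds in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (ds, dy, dx) != (0, 0, 0)
    ]
    for o, stack in enumerate(dog.octaves):
        nl, h, w = stack.shape
        if nl < 3 or h < 3 or w < 3:
            continue
        center = stack[1 : nl - 1, 1 : h - 1, 1 : w - 1]
        is_max = np.ones(center.shape, dtype=bool)
        is_min = np.ones(center.shape, dtype=bool)
        for ds, dy, dx in offsets:
            nbr = stack[
                1 + ds : nl - 1 + ds, 1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx
            ]
            is_max &= center > nbr
            is_min &= center < nbr
        for s, y, x in zip(*np.nonzero(is_max | is_min)):
            candidates.append((o, int(s) + 1, int(y) + 1, int(x) + 1))
    return candidates


def _gradient_hessian(stack: np.ndarray, s: int, y: int, x: int):
    g = np.array(
        [
            0.5 * (stack[s + 1, y, x] - stack[s - 1, y, x]),
            0.5 * (stack[s, y + 1, x] - stack[s, y - 1, x]),
            0.5 * (stack[s, y, x + 1] - stack[s, y, x - 1]),
        ]
    )
    c = stack[s, y, x]
    dss = stack[s + 1, y, x] - 2 * c + stack[s - 1, y, x]
    dyy = stack[s, y + 1, x] - 2 * c + stack[s, y - 1, x]
    dxx = stack[s, y, x + 1] - 2 * c + stack[s, y, x - 1]
    dsy = 0.25 * (
        stack[s + 1, y + 1, x] - stack[s + 1, y - 1, x]
        - stack[s - 1, y + 1, x] + stack[s - 1, y - 1, x]
    )
    dsx = 0.25 * (
        stack[s + 1, y, x + 1] - stack[s + 1, y, x - 1]
        - stack[s - 1, y, x + 1] + stack[s - 1, y, x - 1]
    )
    dyx = 0.25 * (
        stack[s, y + 1, x + 1] - stack[s, y + 1, x - 1]
        - stack[s, y - 1, x + 1] + stack[s, y - 1, x - 1]
    )
    hess = np.array([[dss, dsy, dsx], [dsy, dyy, dyx], [dsx, dyx, dxx]])
    return g, hess, (dyy, dxx, dyx)


def localize_keypoint(
    dog: DoGStack,
    candidate: tuple[int, int, int, int],
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    edge_ratio: float = DEFAULT_EDGE_RATIO,
    max_iter: int = 5,
) -> Keypoint | None:
    """Subpixel Taylor refinement of a candidate; None when rejected.

    Solves offset = -(d2D/da2)^-1 (dD/da) by finite differences; if any
    offset component reaches 0.5 the candidate re-centers on the neighboring
    voxel and retries (up to ``max_iter`` times).  Accepted keypoints must
    pass the contrast test |D(offset)| >= contrast_threshold and the edge
    test tr(H)^2 / det(H) < (r+1)^2 / r on the 2 x 2 spatial Hessian.
    """
    o, s, y, x = candidate
    stack = dog.octaves[o]
    nl, h, w = stack.shape
    offset = np.zeros(3)
    for _ in range(max_iter):
        if not (1 <= s < nl - 1 and 1 <= y < h - 1 and 1 <= x < w - 1):
            return None
        g, hess, spatial = _gradient_hessian(stack, s, y, x)
        try:
            offset = -np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(offset) < 0.5):
            break
        step = np.clip(np.rint(offset), -1, 1).astype(int)
        if np.all(step == 0):  # offset >= 0.5 but rounds to 0: nudge largest axis
            step[np.argmax(np.abs(offset))] = int(np.sign(offset[np.argmax(np.abs(offset))]))
        s, y, x = s + step[0], y + step[1], x + step[2]
    else:
        return None

    value = stack[s, y, x] + 0.5 * float(g @ offset)
    if abs(value) < contrast_threshold:
        return None
    dyy, dxx, dyx = spatial
    trace = dxx + dyy
    det = dxx * dyy - dyx * dyx
    if det <= 0 or trace * trace / det >= (edge_ratio + 1) ** 2 / edge_ratio:
        return None

    scale = 2.0**o
    sigma = dog.base_sigma * dog.k ** (s + offset[0]) * scale
    return Keypoint(
        x=(x + offset[2]) * scale,
        y=(y + offset[1]) * scale,
        octave=o,
        interval=s,
        sigma=float(sigma),
        response=abs(value),
    )


def _octave_local(space: ScaleSpace, kp: Keypoint):
    """Keypoint coordinates, scale and Gaussian level on its octave's grid."""
    scale = 2.0**kp.octave
    x, y = kp.x / scale, kp.y / scale
    sigma_oct = kp.sigma / scale
    level = int(round(math.log(max(sigma_oct, 1e-12) / space.base_sigma, space.k)))
    level = min(max(level, 0), space.n_levels - 1)
    return x, y, sigma_oct, space.octaves[kp.octave][level]


def _gradient_window(img: np.ndarray, cy: int, cx: int, radius: int):
    """Central-difference gradients in a clipped square window.

    Returns flattened (dy_off, dx_off, magnitude, angle) arrays; angle in
    [0, 2 pi) with the image convention dy = L[y+1] - L[y-1].
    """
    h, w = img.shape
    y0, y1 = max(cy - radius, 1), min(cy + radius, h - 2)
    x0, x1 = max(cx - radius, 1), min(cx + radius, w - 2)
    if y0 > y1 or x0 > x1:
        return None
    patch_dy = 0.5 * (img[y0 + 1 : y1 + 2, x0 : x1 + 1] - img[y0 - 1 : y1, x0 : x1 + 1])
    patch_dx = 0.5 * (img[y0 : y1 + 1, x0 + 1 : x1 + 2] - img[y0 : y1 + 1, x0 - 1 : x1])
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mag = np.hypot(patch_dx, patch_dy)
    ang = np.mod(np.arctan2(patch_dy, patch_dx), 2.0 * math.pi)
    return (
        (yy - cy).ravel().astype(float),
        (xx - cx).ravel().astype(float),
        mag.ravel(),
        ang.ravel(),
    )


def assign_orientations(
    space: ScaleSpace,
    kp: Keypoint,
    n_bins: int = 36,
    peak_ratio: float = 0.8,
) -> list[Keypoint]:
    """Dominant gradient orientations around a keypoint.

    Builds a 36-bin gradient-orientation histogram weighted by gradient
    magnitude and a Gaussian window of width 1.5 x scale; every histogram
    peak at >= 80% of the maximum yields a keypoint, with parabolic peak
    interpolation.  Returns [] when the keypoint has no usable support.
    """
    x, y, sigma_oct, img = _octave_local(space, kp)
    sigma_w = 1.5 * sigma_oct
    radius = max(1, int(round(3.0 * sigma_w)))
    win = _gradient_window(img, int(round(y)), int(round(x)), radius)
    if win is None:
        return []
    dy_off, dx_off, mag, ang = win
    weights = mag * np.exp(-(dy_off**2 + dx_off**2) / (2.0 * sigma_w**2))
    if not np.any(weights > 0):
        return []

    bin_width = 2.0 * math.pi / n_bins
    bins = np.floor(ang / bin_width).astype(int) % n_bins
    hist = np.bincount(bins, weights=weights, minlength=n_bins)
    for _ in range(2):  # light circular smoothing stabilises peak picking
        hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0

    peak = hist.max()
    if peak <= 0:
        return []
    out: list[Keypoint] = []
    left, right = np.roll(hist, 1), np.roll(hist, -1)
    for i in np.nonzero((hist >= peak_ratio * peak) & (hist > left) & (hist > right))[0]:
        denom = hist[(i - 1) % n_bins] - 2 * hist[i] + hist[(i + 1) % n_bins]
        shift = 0.0 if denom == 0 else 0.5 * (hist[(i - 1) % n_bins] - hist[(i + 1) % n_bins]) / denom
        theta = ((i + 0.5 + shift) * bin_width) % (2.0 * math.pi)
        out.append(replace(kp, orientation=float(theta)))
    return out


def compute_descriptor(
    space: ScaleSpace,
    kp: Keypoint,
    n_spatial: int = 4,
    n_orient: int = 8,
    clamp: float = 0.2,
) -> SiftDescriptor:
    """The 4 x 4 x 8 gradient-histogram descriptor of an oriented keypoint.

    Gradient orientations are taken relative to the keypoint orientation;
    contributions are trilinearly distributed over the spatial/orientation
    bins with Gaussian spatial weighting; the 128-vector is L2-normalised,
    clamped at ``clamp``, and renormalised.
    """
    x, y, sigma_oct, img = _octave_local(space, kp)
    hist_width = 3.0 * sigma_oct
    radius = int(round(hist_width * math.sqrt(2) * (n_spatial + 1) * 0.5))
    radius = max(1, min(radius, int(math.hypot(*img.shape))))
    win = _gradient_window(img, int(round(y)), int(round(x)), radius)
    hist = np.zeros((n_spatial, n_spatial, n_orient))
    if win is not None:
        dy_off, dx_off, mag, ang = win
        cos_t, sin_t = math.cos(kp.orientation), math.sin(kp.orientation)
        # Rotate offsets into the keypoint frame, in units of one subregion.
        u = (cos_t * dx_off + sin_t * dy_off) / hist_width
        v = (-sin_t * dx_off + cos_t * dy_off) / hist_width
        rbin = v + n_spatial / 2.0 - 0.5
        cbin = u + n_spatial / 2.0 - 0.5
        rel = np.mod(ang - kp.orientation, 2.0 * math.pi)
        obin = rel / (2.0 * math.pi) * n_orient
        keep = (rbin > -1) & (rbin < n_spatial) & (cbin > -1) & (cbin < n_spatial)
        rbin, cbin, obin = rbin[keep], cbin[keep], obin[keep]
        w = mag[keep] * np.exp(-(u[keep] ** 2 + v[keep] ** 2) / (2 * (0.5 * n_spatial) ** 2))

        r0 = np.floor(rbin).astype(int)
        c0 = np.floor(cbin).astype(int)
        o0 = np.floor(obin).astype(int)
        fr, fc, fo = rbin - r0, cbin - c0, obin - o0
        for dr in (0, 1):
            wr = w * np.where(dr, fr, 1 - fr)
            rr = r0 + dr
            for dc in (0, 1):
                wc = wr * np.where(dc, fc, 1 - fc)
                cc = c0 + dc
                ok = (rr >= 0) & (rr < n_spatial) & (cc >= 0) & (cc < n_spatial)
                for do in (0, 1):
                    wo = wc * np.where(do, fo, 1 - fo)
                    oo = (o0 + do) % n_orient
                    np.add.at(hist, (rr[ok], cc[ok], oo[ok]), wo[ok])

    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = np.minimum(vec / norm, clamp)
        norm2 = np.linalg.norm(vec)
        if norm2 > 0:
            vec = vec / norm2
    return SiftDescriptor(vec)


def detect_and_describe(
    image,
    n_octaves: int = DEFAULT_N_OCTAVES,
    n_intervals: int = DEFAULT_N_INTERVALS,
    base_sigma: float = DEFAULT_BASE_SIGMA,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    edge_ratio: float = DEFAULT_EDGE_RATIO,
) -> tuple[list[Keypoint], np.ndarray]:
    """End-to-end SIFT: keypoints plus an (n, 128) descriptor matrix."""
    space = build_scale_space(image, n_octaves, n_intervals, base_sigma)
    dog = compute_dog(space)
    keypoints: list[Keypoint] = []
    for cand in detect_extrema(dog):
        kp = localize_keypoint(dog, cand, contrast_threshold, edge_ratio)
        if kp is None:
            continue
        keypoints.extend(assign_orientations(space, kp))
    descriptors = np.zeros((len(keypoints), 128), dtype=np.float32)
    for i, kp in enumerate(keypoints):
        descriptors[i] = compute_descriptor(space, kp).values
    return keypoints, descriptors


def _circle_points(cx: int, cy: int, radius: int) -> list[tuple[int, int]]:
    """Integer midpoint-circle perimeter points."""
    if radius < 1:
        return [(cx, cy)]
    pts = set()
    x, y, err = radius, 0, 1 - radius
    while x >= y:
        for px, py in (
            (x, y), (y, x), (-x, y), (-y, x),
            (x, -y), (y, -x), (-x, -y), (-y, -x),
        ):
            pts.add((cx + px, cy + py))
        y += 1
        if err < 0:
            err += 2 * y + 1
        else:
            x -= 1
            err += 2 * (y - x) + 1
    return sorted(pts)


def overlay_keypoints(
    image: SignalImage,
    keypoints: list[Keypoint],
    color: tuple[int, int, int] = (255, 0, 0),
) -> SignalImage:
    """Copy of the image with each keypoint drawn as a red circle.

    Circle radius is ``round(kp.sigma)`` with a 1-px stroke; the input image
    is left unmodified and the output keeps its dimensions.
    """
    pixels = image.pixels.copy()
    h, w, _ = pixels.shape
    for kp in keypoints:
        cx, cy = int(round(kp.x)), int(round(kp.y))
        for px, py in _circle_points(cx, cy, max(1, int(round(kp.sigma)))):
            if 0 <= py < h and 0 <= px < w:
                pixels[py, px] = color
    return SignalImage(pixels, image.label, image.source)


def compute_hog(
    image,
    cell_px: int = 8,
    block_cells: int = 2,
    stride_cells: int = 1,
    n_bins: int = 9,
    eps: float = 1e-10,
) -> HogDescriptor:
    """Histogram-of-oriented-gradients descriptor with sliding-block L2 norm.

    Unsigned orientations (0-180 deg) with linear interpolation between the
    two nearest bins; per-block L2 normalisation with an epsilon guard (a
    constant image yields an all-zero descriptor).
    """
    gray = to_grayscale(image)
    h, w = gray.shape
    if h % cell_px or w % cell_px:
        raise ValueError(f"image {h}x{w} not divisible by cell size {cell_px}")
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), math.pi)  # unsigned orientation

    # Continuous bin coordinate with bin centers at (i + 0.5) * pi / n_bins.
    fbin = ang / math.pi * n_bins - 0.5
    b0 = np.floor(fbin).astype(int)
    frac = fbin - b0
    b0m = b0 % n_bins
    b1m = (b0 + 1) % n_bins

    ncy, ncx = h // cell_px, w // cell_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = yy // cell_px, xx // cell_px
    cells = np.zeros((ncy, ncx, n_bins))
    np.add.at(cells, (cy.ravel(), cx.ravel(), b0m.ravel()), (mag * (1 - frac)).ravel())
    np.add.at(cells, (cy.ravel(), cx.ravel(), b1m.ravel()), (mag * frac).ravel())

    blocks = []
    for by in range(0, ncy - block_cells + 1, stride_cells):
        for bx in range(0, ncx - block_cells + 1, stride_cells):
            v = cells[by : by + block_cells, bx : bx + block_cells].ravel()
            blocks.append(v / np.sqrt(np.sum(v * v) + eps * eps))
    values = np.concatenate(blocks) if blocks else np.zeros(0)
    return HogDescriptor(values, (cell_px, block_cells, stride_cells, n_bins))
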