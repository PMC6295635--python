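import numpy as np
import pytest

from thermoscreen.io import Thermogram
from thermoscreen.segmentation import (
    EdgeMap,
    ProjectionProfile,
    SegmentationError,
    binarize_edges,
    compute_breast_height,
    detect_lower_limit,
    detect_side_limits,
    detect_upper_limit,
    horizontal_projection_profile,
    segment_breasts,
    segment_thermogram,
    sobel_gradient,
    to_grayscale,
    vertical_projection_profile,
)


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 1.0), ((0, 0, 0), 0.0), ((255, 0, 0), 0.299)],
    )
    def test_luma_values(self, rgb, expected):
        img = np.tile(np.array(rgb, dtype=np.uint8), (2, 2, 1))
        assert to_grayscale(img)[0, 0] == pytest.approx(expected)

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4)))


class TestSobel:
    def test_flat_field_zero_magnitude(self):
        e = sobel_gradient(np.full((8, 8), 0.5))
        assert np.all(e.gradient_magnitude == 0.0)

    def test_vertical_step_edge_hand_convolution(self):
        # step of height 1 between two constant halves: the 3x3 kernel's
        # column weights (1, 2, 1) sum to 4, so the magnitude on the edge
        # columns is 4 * step, with direction along +x.
        img = np.zeros((9, 10))
        img[:, 5:] = 1.0
        e = sobel_gradient(img)
        assert e.gradient_magnitude[4, 4] == pytest.approx(4.0)
        assert e.gradient_magnitude[4, 5] == pytest.approx(4.0)
        assert e.gradient_direction[4, 4] == pytest.approx(0.0)
        assert np.all(e.gradient_magnitude[:, [0, 1, 2, 8, 9]] == 0.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12))
        mag = sobel_gradient(img).gradient_magnitude
        mag_rot = sobel_gradient(np.rot90(img)).gradient_magnitude
        assert np.allclose(mag_rot, np.rot90(mag))

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.random((10, 10))
        a = sobel_gradient(img).gradient_magnitude
        b = sobel_gradient(img + 7.5).gradient_magnitude
        assert np.allclose(a, b)

    def test_too_small_input(self):
        with pytest.raises(ValueError):
            sobel_gradient(np.zeros((2, 5)))


class TestBinarize:
    def test_flat_image_empty_edges_with_warning(self):
        e = sobel_gradient(np.full((8, 8), 0.3))
        with pytest.warns(UserWarning, match="flat"):
            out = binarize_edges(e, "otsu")
        assert np.all(out.binary == 0)

    def test_two_level_magnitude_separates(self):
        mag = np.zeros((6, 6))
        mag[2:4, 2:4] = 10.0
        e = EdgeMap(gradient_magnitude=mag, gradient_direction=np.zeros_like(mag))
        out = binarize_edges(e, "otsu")
        assert np.array_equal(out.binary, (mag == 10.0).astype(np.uint8))

    def test_fixed_threshold_override(self):
        mag = np.arange(16.0).reshape(4, 4)
        e = EdgeMap(gradient_magnitude=mag, gradient_direction=np.zeros_like(mag))
        out = binarize_edges(e, 8.0)
        assert np.array_equal(out.binary, (mag >= 8.0).astype(np.uint8))


def _binary_edge_map(binary):
    binary = np.asarray(binary, dtype=np.uint8)
    return EdgeMap(
        gradient_magnitude=binary.astype(float),
        gradient_direction=np.zeros_like(binary, dtype=float),
        binary=binary,
    )


class TestProjectionProfiles:
    def test_single_row_of_ones(self):
        b = np.zeros((6, 5), dtype=np.uint8)
        b[3] = 1
        p = horizontal_projection_profile(_binary_edge_map(b))
        assert list(p.counts) == [0, 0, 0, 5, 0, 0]

    def test_empty_map_zero_vector(self):
        p = vertical_projection_profile(_binary_edge_map(np.zeros((4, 7))))
        assert np.all(p.counts == 0)

    def test_random_maps_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            b = rng.integers(0, 2, (8, 8))
            hpp = horizontal_projection_profile(_binary_edge_map(b))
            vpp = vertical_projection_profile(_binary_edge_map(b))
            assert list(hpp.counts) == [sum(row) for row in b]
            assert list(vpp.counts) == [sum(col) for col in b.T]


class TestLowerLimit:
    def test_unique_peak(self):
        counts = np.zeros(200, dtype=int)
        counts[180] = 90
        p = ProjectionProfile(counts=counts, axis="horizontal")
        assert detect_lower_limit(p, 50, (120, 199)) == 180

    def test_bottom_up_scan_takes_first_hit(self):
        counts = np.zeros(200, dtype=int)
        counts[150] = 60
        counts[180] = 60
        p = ProjectionProfile(counts=counts, axis="horizontal")
        assert detect_lower_limit(p, 50, (120, 199)) == 180

    def test_no_line_detected(self):
        p = horizontal_projection_profile(_binary_edge_map(np.zeros((50, 50))))
        with pytest.raises(SegmentationError, match="infra-mammary"):
            detect_lower_limit(p, 10, (30, 49))


class TestHeightRule:
    def test_small_breast_branch(self):
        # d = 200 - 190 = 10 < 0.26 * 200: small-breast fraction applies
        assert compute_breast_height(190, 200) == 90

    def test_large_breast_branch(self):
        # d = 200 - 120 = 80 >= 0.26 * 200: large-breast fraction applies
        assert compute_breast_height(120, 200) == 70

    def test_clamp_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert compute_breast_height(30, 100) == 30

    @pytest.mark.parametrize("ll,h,ul", [(180, 90, 90), (90, 90, 0)])
    def test_upper_limit_arithmetic(self, ll, h, ul):
        assert detect_upper_limit(ll, h) == ul


class TestSideLimits:
    def test_two_pixel_case(self):
        b = np.zeros((200, 220), dtype=np.uint8)
        b[100, 40] = 1
        b[100, 160] = 1
        left, right, axis = detect_side_limits(_binary_edge_map(b), (90, 180))
        assert (left, right, axis) == (40, 160, 100)

    def test_all_ones_row(self):
        b = np.ones((10, 30), dtype=np.uint8)
        left, right, _ = detect_side_limits(_binary_edge_map(b), (0, 9))
        assert (left, right) == (0, 29)

    def test_no_contour(self):
        b = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(SegmentationError, match="contour"):
            detect_side_limits(_binary_edge_map(b), (0, 9))


class TestSegmentBreasts:
    def test_mask_arithmetic(self):
        t = Thermogram(temperature=np.full((200, 220), 30.0))
        seg = segment_breasts(t, (90, 180, 40, 160, 100))
        assert seg.left_mask.sum() == 91 * 60
        assert seg.right_mask.sum() == 91 * 61
        assert not np.any(seg.left_mask & seg.right_mask)

    def test_mirror_reflection_swaps_limits(self, symmetric_phantom):
        t, _ = symmetric_phantom
        seg = segment_thermogram(t)
        mirrored = Thermogram(
            temperature=t.temperature[:, ::-1].copy(),
            rgb=t.rgb[:, ::-1].copy(),
            meta=t.meta,
        )
        seg_m = segment_thermogram(mirrored)
        cols = t.shape[1]
        assert seg_m.lower_limit == seg.lower_limit
        assert abs(seg_m.left_limit - (cols - 1 - seg.right_limit)) <= 1
        assert abs(seg_m.right_limit - (cols - 1 - seg.left_limit)) <= 1
        assert abs(seg_m.central_axis - (cols - 1 - seg.central_axis)) <= 1

    def test_too_small_image_rejected(self):
        t = Thermogram(temperature=np.full((16, 16), 30.0))
        with pytest.raises(ValueError, match="too small"):
            segment_thermogram(t)


class TestOnPhantom:
    def test_recovers_fold_axis_and_breasts(self, symmetric_phantom):
        t, truth = symmetric_phantom
        seg = segment_thermogram(t)
        assert abs(seg.lower_limit - truth.fold_row) <= 3
        assert abs(seg.central_axis - truth.center_col) <= 2
        assert abs(seg.upper_limit - truth.axilla_row) <= 0.1 * t.shape[0]
        # each ground-truth breast ellipse sits almost entirely in its mask
        for ellipse, mask in (
            (truth.left_breast_mask, seg.left_mask),
            (truth.right_breast_mask, seg.right_mask),
        ):
            assert (ellipse & mask).sum() / ellipse.sum() >= 0.90

    def test_silhouette_boundary_in_edge_set(self, symmetric_phantom):
        t, truth = symmetric_phantom
        edges = binarize_edges(sobel_gradient(to_grayscale(t.rgb)), "otsu")
        # the infra-mammary line must contribute a dense horizontal edge row
        band = edges.binary[truth.fold_row - 2 : truth.fold_row + 3]
        assert band.sum(axis=1).max() >= 0.15 * t.shape[1]
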