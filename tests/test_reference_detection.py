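"""Hue segmentation, top-hat band-pass morphology, and corner detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vbtcam.errors import DetectionError
from vbtcam.reference_detection import (
    DetectionConfig,
    binarize_hue,
    circular_hue_difference,
    detect_reference_corners,
    find_polygon_candidates,
    hue_similarity_image,
    hue_threshold,
    ransac_line,
    reconstruct_markers,
    tophat_bandpass,
)
from vbtcam.synthetic_scene import make_default_scene, generate_motion_profile, render_sequence

from conftest import SMALL_SIZE


# ---------------------------------------------------------------------------
# independent morphology oracle: shift-and-combine Minkowski operations

def _shift(mask, dr, dc):
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs, re = max(dr, 0), min(h + dr, h)
    cs, ce = max(dc, 0), min(w + dc, w)
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = mask[rs - dr:re - dr, cs - dc:ce - dc]
    return out


def oracle_opening(mask, offsets):
    """Erosion then dilation by explicit structuring-element shifts."""
    er = np.ones_like(mask)
    for dr, dc in offsets:
        er &= _shift(mask, -dr, -dc)
    dil = np.zeros_like(mask)
    for dr, dc in offsets:
        dil |= _shift(er, dr, dc)
    return dil


def line_offsets(length, orientation):
    ks = range(-(length // 2), length // 2 + 1)
    if orientation == "vertical":
        return [(k, 0) for k in ks]
    if orientation == "horizontal":
        return [(0, k) for k in ks]
    if orientation == "diagonal":
        return [(k, k) for k in ks]
    return [(k, -k) for k in ks]


def _round_to_odd(x):
    n = max(int(round(x)), 1)
    return n if n % 2 else n + 1


def oracle_bandpass(mask, orientation, expected):
    ee1 = _round_to_odd(2 * expected)
    ee2 = _round_to_odd(expected / 2)
    th1 = mask & ~oracle_opening(mask, line_offsets(ee1, orientation))
    th2 = mask & ~oracle_opening(mask, line_offsets(ee2, orientation))
    return th1 & ~th2


# ---------------------------------------------------------------------------

class TestCircularHueDifference:
    def test_wraparound(self):
        assert circular_hue_difference(0.0, 0.9) == pytest.approx(0.1)

    def test_identity_and_antipode(self):
        assert circular_hue_difference(0.33, 0.33) == 0.0
        assert circular_hue_difference(0.25, 0.75) == pytest.approx(0.5)

    @given(st.floats(min_value=0, max_value=0.999),
           st.floats(min_value=0, max_value=0.999))
    def test_symmetric_and_bounded(self, h, t):
        d = circular_hue_difference(h, t)
        assert 0 <= d <= 0.5
        assert d == pytest.approx(circular_hue_difference(t, h))


class TestHueSimilarity:
    def test_pure_red_on_red_target(self):
        frame = np.zeros((2, 2, 3))
        frame[..., 0] = 1.0
        assert np.allclose(hue_similarity_image(frame, 0.0), 1.0)

    def test_gray_pixels_gated_out(self):
        frame = np.full((2, 2, 3), 0.7)
        assert np.allclose(hue_similarity_image(frame, 0.0), 0.0)

    def test_saturated_cyan_antipodal_to_red(self):
        frame = np.zeros((2, 2, 3))
        frame[..., 1] = frame[..., 2] = 1.0
        assert np.allclose(hue_similarity_image(frame, 0.0), 0.5)

    def test_saturation_gate_at_half(self):
        # saturation = 1 - min/max; 0.49 and 0.51 straddle the 50% gate
        frame = np.zeros((1, 2, 3))
        frame[0, 0] = [1.0, 0.51, 0.51]
        frame[0, 1] = [1.0, 0.49, 0.49]
        out = hue_similarity_image(frame, 0.0)
        assert out[0, 0] == 0.0 and out[0, 1] == 1.0

    def test_matches_skimage_hsv_on_random_frames(self):
        from skimage.color import rgb2hsv
        rng = np.random.default_rng(2)
        frame = rng.random((32, 32, 3))
        hsv = rgb2hsv(frame)
        expected = 1.0 - circular_hue_difference(hsv[..., 0], 0.3)
        expected[hsv[..., 1] < 0.5] = 0.0
        assert np.allclose(hue_similarity_image(frame, 0.3), expected,
                           atol=1e-6)


class TestBinarizeHue:
    def test_red_threshold_is_one_twelfth(self):
        assert hue_threshold(0.0) == pytest.approx(1.0 / 12.0)

    @pytest.mark.parametrize("hue,inside", [(0.05, True), (0.12, False)])
    def test_threshold_arithmetic_for_red(self, hue, inside):
        frame = np.zeros((1, 1, 3))
        # build an RGB pixel of the given hue at full saturation
        import colorsys
        frame[0, 0] = colorsys.hsv_to_rgb(hue, 1.0, 1.0)
        dif = hue_similarity_image(frame, 0.0)
        assert bool(binarize_hue(dif, 0.0)[0, 0]) is inside

    def test_unsaturated_pixel_false_regardless_of_hue(self):
        frame = np.full((1, 1, 3), 0.8)
        dif = hue_similarity_image(frame, 0.0)
        assert not binarize_hue(dif, 0.0).any()

    def test_yellow_target_threshold(self):
        # yellow (1/6) sits 1/6 from both red and green: threshold 1/12
        assert hue_threshold(1.0 / 6.0) == pytest.approx(1.0 / 12.0)


class TestTophatBandpass:
    def test_uniform_mask_maps_to_empty(self):
        mask = np.ones((64, 64), dtype=bool)
        assert not tophat_bandpass(mask, "vertical", 8).any()

    def test_bar_of_expected_size_retained(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:28, 30] = True  # length 8 = expected
        out = tophat_bandpass(mask, "vertical", 8)
        assert out[20:28, 30].all()

    def test_bar_three_times_expected_removed(self):
        mask = np.zeros((80, 64), dtype=bool)
        mask[10:34, 30] = True  # length 24 = 3x expected
        assert not tophat_bandpass(mask, "vertical", 8).any()

    def test_small_expected_size_rejected(self):
        with pytest.raises(ValueError):
            tophat_bandpass(np.zeros((8, 8), dtype=bool), "vertical", 1)

    @pytest.mark.parametrize("orientation",
                             ["vertical", "horizontal", "diagonal",
                              "antidiagonal"])
    def test_equals_bruteforce_oracle_on_random_masks(self, orientation):
        rng = np.random.default_rng(13)
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.35
            expected = int(rng.integers(3, 12))
            ours = tophat_bandpass(mask, orientation, expected)
            assert np.array_equal(
                ours, oracle_bandpass(mask, orientation, expected))


class TestReconstructMarkers:
    def test_markers_equal_mask_is_identity(self):
        rng = np.random.default_rng(3)
        mask = rng.random((32, 32)) < 0.3
        assert np.array_equal(reconstruct_markers(mask, mask), mask)

    def test_empty_markers_give_empty_output(self):
        mask = np.ones((8, 8), dtype=bool)
        assert not reconstruct_markers(np.zeros_like(mask), mask).any()

    def test_single_seed_recovers_exactly_its_blob(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        mask[16:19, 2:5] = True
        seed = np.zeros_like(mask)
        seed[11, 11] = True
        out = reconstruct_markers(seed, mask)
        expected = np.zeros_like(mask)
        expected[10:13, 10:13] = True
        assert np.array_equal(out, expected)

    def test_matches_skimage_reconstruction(self):
        from skimage.morphology import reconstruction
        rng = np.random.default_rng(17)
        mask = rng.random((48, 48)) < 0.4
        seed = mask & (rng.random((48, 48)) < 0.1)
        ours = reconstruct_markers(seed, mask)
        ref = reconstruction(seed.astype(np.uint8), mask.astype(np.uint8),
                             method="dilation", footprint=np.ones((3, 3)))
        assert np.array_equal(ours, ref.astype(bool))


class TestRansacLine:
    def test_recovers_line_with_outliers(self):
        rng = np.random.default_rng(23)
        y = np.linspace(0, 400, 12)
        x = 0.05 * y + 40.0
        pts = np.column_stack([x, y])
        pts[4] += [60.0, 0.0]  # gross outlier
        (a, b), inliers = ransac_line(
            pts, __import__("vbtcam").RansacParams(seed=1))
        assert a == pytest.approx(0.05, abs=1e-9)
        assert b == pytest.approx(40.0, abs=1e-6)
        assert not inliers[4] and inliers.sum() == 11

    def test_coincident_points_degenerate(self):
        pts = np.array([[10.0, 50.0], [11.0, 50.0]])
        with pytest.raises(DetectionError):
            ransac_line(pts, __import__("vbtcam").RansacParams())


class TestDetectReferenceCorners:
    def test_corners_match_renderer_truth(self, small_sequence):
        corners, inliers = detect_reference_corners(small_sequence.frame(0))
        truth = small_sequence.ground_truth.reference_pixels
        assert np.max(np.abs(corners - truth)) < 2.0
        assert len(inliers["left"]) == 6 and len(inliers["right"]) == 6

    def test_distractor_blob_rejected_as_outlier(self, small_scene):
        profile = generate_motion_profile("constant", 0.3, 0.4, fps=60)
        seq = render_sequence(small_scene, profile)
        frame = seq.frame(0).copy()
        # red distractor off the tape line, polygon-sized
        frame[250:261, 120:131] = (255, 0, 0)
        corners, inliers = detect_reference_corners(frame)
        truth = seq.ground_truth.reference_pixels
        assert np.max(np.abs(corners - truth)) < 2.0

    def test_no_red_content_raises(self):
        frame = np.full((240, 135, 3), 128, dtype=np.uint8)
        with pytest.raises(DetectionError):
            detect_reference_corners(frame)

    def test_brightness_invariance(self, small_sequence):
        frame = small_sequence.frame(0)
        dimmed = (frame.astype(float) * 0.55).astype(np.uint8)
        c1, _ = detect_reference_corners(frame)
        c2, _ = detect_reference_corners(dimmed)
        assert np.allclose(c1, c2)

    @pytest.mark.parametrize("tilt", [0.0, 10.0, 20.0])
    @pytest.mark.parametrize("palette", ["red_white", "black_yellow"])
    def test_detection_across_tilts_and_palettes(self, tilt, palette):
        scene = make_default_scene(image_size=SMALL_SIZE, tilt_deg=tilt,
                                   palette=palette)
        profile = generate_motion_profile("constant", 0.3, 0.4, fps=60)
        seq = render_sequence(scene, profile)
        hue = 0.0 if palette == "red_white" else 1.0 / 6.0
        corners, _ = detect_reference_corners(
            seq.frame(0), DetectionConfig(hue_target=hue))
        truth = seq.ground_truth.reference_pixels
        assert np.max(np.abs(corners - truth)) < 2.0


class TestPolygonCandidates:
    def test_corner_extraction(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:9, 3:8] = True
        cands = find_polygon_candidates(mask)
        assert len(cands) == 1
        c = cands[0]
        assert c.upper_left == (3.0, 5.0)
        assert c.bottom_right == (7.0, 8.0)
        assert c.area == 20

    def test_offset_applied(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 2:4] = True
        c = find_polygon_candidates(mask, offset=(100, 0))[0]
        assert c.upper_left == (102.0, 2.0)
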