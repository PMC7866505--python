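"""Search strips, mark detection, pairing, gap filling, metric mapping."""

import numpy as np
import pytest

from vbtcam.barbell_tracking import (
    MarkerTrack,
    build_search_strips,
    detect_marker_candidates,
    fill_missing_detections,
    pair_candidates,
    track_world_positions,
)
from vbtcam.camera_geometry import Homography
from vbtcam.errors import DetectionError, TrackingError
from vbtcam.machine_calibration import calibrate
from vbtcam.reference_detection import PolygonCandidate
from vbtcam.synthetic_scene import (
    generate_motion_profile,
    make_default_scene,
    render_sequence,
)

from conftest import SMALL_SIZE


def _cand(x, y, w=6, h=5, area=None):
    return PolygonCandidate(upper_left=(float(x), float(y)),
                            bottom_right=(float(x + w - 1), float(y + h - 1)),
                            bbox=(int(x), int(y), int(x + w - 1),
                                  int(y + h - 1)),
                            area=area or w * h)


class TestBuildSearchStrips:
    def test_axis_aligned_for_fronto_parallel_scene(self):
        scene = make_default_scene(image_size=SMALL_SIZE, tilt_deg=0.0)
        profile = generate_motion_profile("constant", 0.3, 0.4, fps=60)
        seq = render_sequence(scene, profile)
        from vbtcam.reference_detection import detect_reference_corners
        _, inliers = detect_reference_corners(seq.frame(0))
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        assert strips.left_line[0] == pytest.approx(0.0, abs=1e-6)
        assert strips.right_line[0] == pytest.approx(0.0, abs=1e-6)

    def test_strip_boundaries_follow_tilted_tape_line(self, small_detection):
        _, inliers = small_detection
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        # boundary slope equals the RANSAC fit through the tape corners
        pts = np.array([c.bottom_right for c in inliers["left"]])
        slope = np.polyfit(pts[:, 1], pts[:, 0], 1)[0]
        assert strips.left_line[0] == pytest.approx(slope, abs=0.05)
        # regions stay in their own halves and are disjoint
        assert strips.left_limit < SMALL_SIZE[0] / 2 < strips.right_limit

    def test_single_inlier_polygon_raises(self):
        with pytest.raises(DetectionError):
            build_search_strips([_cand(10, 10)], [_cand(200, 10),
                                                  _cand(201, 100)],
                                (270, 480))


class TestDetectMarkerCandidates:
    def test_one_candidate_per_side_at_rendered_location(
            self, small_sequence, small_detection):
        _, inliers = small_detection
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        frame = small_sequence.frame(10)
        truth = small_sequence.ground_truth
        for side in ("left", "right"):
            cands = detect_marker_candidates(frame, strips, side)
            assert len(cands) == 1
            assert np.max(np.abs(np.array(cands[0].upper_left)
                                 - truth.mark_pixels[side][10])) < 2.0

    def test_occluded_side_yields_empty_list(self, small_scene,
                                             small_detection):
        profile = generate_motion_profile("constant", 0.3, 0.4, fps=60)
        seq = render_sequence(small_scene, profile,
                              occlusions=((5, "left"),))
        _, inliers = small_detection
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        frame = seq.frame(5)
        assert detect_marker_candidates(frame, strips, "left") == []
        assert len(detect_marker_candidates(frame, strips, "right")) == 1

    def test_oversized_glare_blob_rejected(self, small_sequence,
                                           small_detection):
        _, inliers = small_detection
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        frame = small_sequence.frame(0).copy()
        c0, c1 = strips.column_span("left")
        # yellow glare ~5x the expected mark size in both directions
        size = 5 * max(int(round(SMALL_SIZE[1] / 60)), 2)
        frame[100:100 + size, c0 + 5:c0 + 5 + size] = (255, 255, 0)
        cands = detect_marker_candidates(frame, strips, "left")
        assert all(c.upper_left[1] > 150 for c in cands)  # only the true mark


class TestPairCandidates:
    def test_single_pair_at_equal_rows(self):
        l, r = _cand(40, 100), _cand(220, 100)
        assert pair_candidates([l], [r]) == (l, r)

    def test_true_pair_beats_spurious_high_blob(self):
        true_l, spur_l = _cand(40, 140), _cand(42, 100)
        true_r = _cand(220, 141)
        # oracle: enumerate row differences
        got = pair_candidates([spur_l, true_l], [true_r])
        assert got == (true_l, true_r)

    def test_tie_broken_by_combined_area(self):
        small_l, big_l = _cand(40, 100, area=10), _cand(42, 102, area=80)
        r = _cand(220, 101)
        got = pair_candidates([small_l, big_l], [r])
        assert got == (big_l, r)

    def test_empty_sides(self):
        assert pair_candidates([], []) == (None, None)
        l = _cand(40, 100)
        assert pair_candidates([l], []) == (l, None)


class TestFillMissing:
    def _track(self, detections, fps=60.0):
        return MarkerTrack.from_detections(detections, fps)

    def test_midpoint_interpolation(self):
        dets = [(_cand(40, 100), _cand(220, 100)),
                (None, _cand(220, 105)),
                (_cand(40, 110), _cand(220, 110))]
        track = fill_missing_detections(self._track(dets))
        assert track.pixels["left"][1, 1] == pytest.approx(105.0)
        assert track.status["left"][1] == "interpolated"
        assert track.status["right"][1] == "detected"

    def test_no_gaps_unchanged(self):
        dets = [(_cand(40, 100), _cand(220, 100)),
                (_cand(40, 105), _cand(220, 105))]
        track = self._track(dets)
        before = track.pixels["left"].copy()
        track = fill_missing_detections(track)
        assert np.array_equal(track.pixels["left"], before)
        assert all(s == "detected" for s in track.status["left"])

    def test_leading_gap_held_at_nearest(self):
        dets = [(None, _cand(220, 100)),
                (_cand(40, 105), _cand(220, 105)),
                (_cand(40, 110), _cand(220, 110))]
        track = fill_missing_detections(self._track(dets))
        assert track.pixels["left"][0, 1] == pytest.approx(105.0)

    def test_all_missing_side_raises(self):
        dets = [(None, _cand(220, 100)), (None, _cand(220, 105)),
                (None, _cand(220, 110))]
        with pytest.raises(TrackingError):
            fill_missing_detections(self._track(dets))

    def test_gap_on_constant_velocity_descent_within_1px(
            self, small_scene, small_detection):
        occl = tuple((i, s) for i in (20, 21, 22) for s in ("left", "right"))
        profile = generate_motion_profile("constant", 0.3, 0.5, fps=60)
        seq = render_sequence(small_scene, profile, occlusions=occl)
        _, inliers = small_detection
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        dets = []
        for frame in seq:
            l = detect_marker_candidates(frame, strips, "left")
            r = detect_marker_candidates(frame, strips, "right")
            dets.append(pair_candidates(l, r))
        track = fill_missing_detections(MarkerTrack.from_detections(dets, 60))
        truth = seq.ground_truth.mark_pixels
        for side in ("left", "right"):
            err = np.abs(track.pixels[side][20:23] - truth[side][20:23])
            assert err.max() < 1.5


class TestWorldMapping:
    def test_identity_homography_units(self):
        dets = [(_cand(40, 100), _cand(220, 100)),
                (_cand(40, 110), _cand(220, 110)),
                (_cand(40, 120), _cand(220, 120))]
        track = fill_missing_detections(
            MarkerTrack.from_detections(dets, 60.0))
        track = track_world_positions(track, Homography.identity())
        # 10 px/frame downward in pixels = 10 units/frame loss of height
        assert np.allclose(np.diff(track.heights_m), -10.0)
        assert track.points_mapped_per_frame <= 2

    def test_constant_height_barbell_flat_within_1mm(self, small_scene,
                                                     small_detection):
        corners, inliers = small_detection
        cal = calibrate(small_scene.geometry, corners,
                        intr=small_scene.intrinsics)
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     SMALL_SIZE)
        profile = generate_motion_profile("constant", 0.001, 0.2, fps=60,
                                          rest_before_s=0.1, rest_after_s=0.1)
        seq = render_sequence(small_scene, profile)
        dets = []
        for frame in seq:
            dets.append(pair_candidates(
                detect_marker_candidates(frame, strips, "left"),
                detect_marker_candidates(frame, strips, "right")))
        track = track_world_positions(
            fill_missing_detections(MarkerTrack.from_detections(dets, 60)),
            cal.Hg)
        assert np.ptp(track.heights_m) < 8e-3  # ~1 px at this tiny scale

    def test_full_resolution_range_recovery_within_2mm(self):
        """0.35 m rendered lift recovered within 2 mm at 1080 x 1920."""
        scene = make_default_scene(image_size=(1080, 1920), tilt_deg=12.0)
        profile = generate_motion_profile("constant", 0.35, 0.35, fps=240,
                                          rest_before_s=0.1, rest_after_s=0.1)
        seq = render_sequence(scene, profile)
        from vbtcam.reference_detection import detect_reference_corners
        corners, inliers = detect_reference_corners(seq.frame(0))
        cal = calibrate(scene.geometry, corners, intr=scene.intrinsics)
        strips = build_search_strips(inliers["left"], inliers["right"],
                                     (1080, 1920))
        dets = []
        for frame in seq:
            dets.append(pair_candidates(
                detect_marker_candidates(frame, strips, "left"),
                detect_marker_candidates(frame, strips, "right")))
        track = track_world_positions(
            fill_missing_detections(MarkerTrack.from_detections(dets, 240)),
            cal.Hg)
        h = track.heights_m
        truth = seq.ground_truth.heights_m
        rms = np.sqrt(np.mean(((h - h[0]) - (truth - truth[0])) ** 2))
        assert rms <= 2e-3
        assert abs(np.ptp(h) - 0.35) < 2e-3

    def test_track_dataframe_schema(self):
        dets = [(_cand(40, 100), _cand(220, 100)),
                (None, _cand(220, 105))]
        track = track_world_positions(
            fill_missing_detections(MarkerTrack.from_detections(dets, 60.0)),
            Homography.identity())
        df = track.to_dataframe()
        assert set(df.columns) >= {"frame", "time_s", "side", "px_x", "px_y",
                                   "X_g_m", "Y_g_m", "height_m", "status",
                                   "low_confidence"}
        assert len(df) == 4  # one row per side per frame
        assert (df["status"] == "interpolated").sum() == 1
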