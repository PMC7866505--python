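"""Per-frame barbell-mark detection, pairing, gap filling, and metric mapping.

A small piece of colored tape (yellow by default) on each end of the barbell
is detected with the same hue/morphology pipeline used for the reference
tapes, but restricted to two narrow search strips flanking the guide
pillars.  The strips are built once from the reference-tape inlier
polygons: a RANSAC line L1 through the bottom-right corners of the left
tape, shifted right by half the polygon width to give L2; the left search
region runs from L2 to the line halfway between L2 and the image's vertical
bisector.  The right side is mirrored.

Only the upper-left corner of each detected mark is mapped through the
guide homography Hg — two points per frame — which is what keeps the method
fast enough for real-time feedback: no perspective correction of whole
frames is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera_geometry import Homography, map_pixel_to_plane
from .errors import DetectionError, TrackingError
from .reference_detection import (
    DetectionConfig,
    PolygonCandidate,
    binarize_hue,
    find_polygon_candidates,
    hue_similarity_image,
    ransac_line,
    reconstruct_markers,
    tophat_bandpass,
)

__all__ = [
    "MarkConfig",
    "SearchStrips",
    "MarkerDetection",
    "MarkerTrack",
    "build_search_strips",
    "detect_marker_candidates",
    "pair_candidates",
    "fill_missing_detections",
    "track_world_positions",
]

#: gaps longer than this many frames are flagged low-confidence
LONG_GAP_FRAMES = 5


@dataclass(frozen=True)
class MarkConfig:
    """Barbell-mark detection parameters (yellow tape by default)."""

    hue_target: float = 1.0 / 6.0
    saturation_min: float = 0.5
    expected_mark_px: int | None = None   # None -> image_height / 60
    min_area_px: int = 4


@dataclass(frozen=True)
class SearchStrips:
    """Left/right barbell search regions.

    Each side stores the inner boundary line x = a*y + b (L2 on the left,
    its mirror on the right) and the constant x of the outer boundary
    (halfway to the vertical bisector).  The left region is
    ``L2(y) <= x <= x_mid_left``; the right region is mirrored.
    """

    left_line: tuple[float, float]
    left_limit: float
    right_line: tuple[float, float]
    right_limit: float
    image_width: int
    image_height: int

    def column_span(self, side: str) -> tuple[int, int]:
        """Inclusive-exclusive column range that bounds the side's region."""
        h = self.image_height
        ys = np.array([0.0, h - 1.0])
        if side == "left":
            a, b = self.left_line
            lo = int(np.floor(min(a * ys + b)))
            hi = int(np.ceil(self.left_limit)) + 1
        else:
            a, b = self.right_line
            lo = int(np.floor(self.right_limit))
            hi = int(np.ceil(max(a * ys + b))) + 1
        return max(lo, 0), min(hi, self.image_width)

    def region_mask(self, side: str, shape: tuple[int, int],
                    offset_x: int = 0) -> np.ndarray:
        """Boolean mask of the side's region for a (cropped) image."""
        h, w = shape
        ys = np.arange(h)[:, None]
        xs = np.arange(w)[None, :] + offset_x
        if side == "left":
            a, b = self.left_line
            return (xs >= a * ys + b) & (xs <= self.left_limit)
        a, b = self.right_line
        return (xs <= a * ys + b) & (xs >= self.right_limit)


@dataclass
class MarkerDetection:
    """One side's mark in one frame."""

    frame: int
    side: str
    pixel: tuple[float, float] | None   # upper-left corner (x, y)
    status: str                         # detected | interpolated | missing
    low_confidence: bool = False


def build_search_strips(left_inliers: list[PolygonCandidate],
                        right_inliers: list[PolygonCandidate],
                        image_size: tuple[int, int],
                        ransac=None) -> SearchStrips:
    """Construct the two search strips from the tape inlier polygons."""
    from .reference_detection import RansacParams
    ransac = ransac or RansacParams()
    width, height = image_size
    if len(left_inliers) < 2 or len(right_inliers) < 2:
        raise DetectionError("need >= 2 inlier polygons per side for strips")
    bisector = width / 2.0

    # left: line through bottom-right corners, shifted right by half a width
    lpts = np.array([c.bottom_right for c in left_inliers])
    (la, lb), _ = ransac_line(lpts, ransac)
    lw = float(np.median([c.width for c in left_inliers]))
    lb += lw / 2.0
    l_edge = min(la * 0 + lb, la * (height - 1) + lb)
    left_limit = (l_edge + bisector) / 2.0

    # right: mirrored, line through bottom-left corners shifted left
    rpts = np.array([(c.bbox[0], c.bottom_right[1]) for c in right_inliers])
    (ra, rb), _ = ransac_line(rpts, ransac)
    rw = float(np.median([c.width for c in right_inliers]))
    rb -= rw / 2.0
    r_edge = max(ra * 0 + rb, ra * (height - 1) + rb)
    right_limit = (r_edge + bisector) / 2.0

    strips = SearchStrips(left_line=(la, lb), left_limit=left_limit,
                          right_line=(ra, rb), right_limit=right_limit,
                          image_width=width, image_height=height)
    if left_limit >= right_limit or left_limit > bisector or right_limit < bisector:
        raise DetectionError("search strips overlap or cross the bisector")
    return strips


def detect_marker_candidates(frame: np.ndarray, strips: SearchStrips,
                             side: str, config: MarkConfig = MarkConfig(),
                             ) -> list[PolygonCandidate]:
    """Detect barbell-mark candidates inside one side's search strip.

    An empty list is a valid result (occlusion, glare, motion blur); the
    temporal gap filler handles it.
    """
    height = frame.shape[0]
    expected = config.expected_mark_px or max(int(round(height / 60)), 2)
    c0, c1 = strips.column_span(side)
    if c1 <= c0:
        return []
    sub = frame[:, c0:c1]
    dif = hue_similarity_image(sub, config.hue_target, config.saturation_min)
    binmask = binarize_hue(dif, config.hue_target)
    binmask &= strips.region_mask(side, binmask.shape, offset_x=c0)
    bp_v = tophat_bandpass(binmask, "vertical", expected)
    bp_h = tophat_bandpass(binmask, "horizontal", expected)
    rec = reconstruct_markers(bp_v & bp_h, binmask)
    return find_polygon_candidates(rec, config.min_area_px, offset=(c0, 0))


def pair_candidates(left: list[PolygonCandidate],
                    right: list[PolygonCandidate],
                    ) -> tuple[PolygonCandidate | None, PolygonCandidate | None]:
    """Select the left/right pair with the closest height (row) coordinate.

    The rigid bar constrains both marks to (nearly) equal height, so the
    pair minimizing the absolute row difference of the upper-left corners
    is chosen; ties break toward the largest combined area.  With
    candidates on only one side, the largest candidate there is returned
    with ``None`` for the other.
    """
    if left and right:
        best = min(
            ((lc, rc) for lc in left for rc in right),
            key=lambda p: (abs(p[0].upper_left[1] - p[1].upper_left[1]),
                           -(p[0].area + p[1].area)),
        )
        return best
    pick = (max(left, key=lambda c: c.area) if left else None,
            max(right, key=lambda c: c.area) if right else None)
    return pick


@dataclass
class MarkerTrack:
    """Per-frame barbell mark positions, pixel and (after mapping) metric.

    ``pixels[side]`` is an (n_frames, 2) float array of upper-left corners
    with NaN where missing; ``status[side]`` the per-frame detection status.
    ``world[side]`` holds guide-plane (X_g, Y_g) in metres once mapped, and
    ``heights_m`` the barbell height series -mean(Y_g) of the two sides
    (ascent = increasing height).
    """

    fps: float
    pixels: dict[str, np.ndarray]
    status: dict[str, list[str]]
    low_confidence: dict[str, np.ndarray] = field(default_factory=dict)
    world: dict[str, np.ndarray] = field(default_factory=dict)
    heights_m: np.ndarray | None = None
    points_mapped_per_frame: int = 0

    @property
    def n_frames(self) -> int:
        return self.pixels["left"].shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @classmethod
    def from_detections(cls, detections: list[tuple], fps: float) -> "MarkerTrack":
        """Build from a per-frame list of (left, right) PolygonCandidate pairs."""
        n = len(detections)
        pixels = {s: np.full((n, 2), np.nan) for s in ("left", "right")}
        status = {s: ["missing"] * n for s in ("left", "right")}
        for i, (lc, rc) in enumerate(detections):
            for side, cand in (("left", lc), ("right", rc)):
                if cand is not None:
                    pixels[side][i] = cand.upper_left
                    status[side][i] = "detected"
        return cls(fps=fps, pixels=pixels, status=status)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        t = self.times_s
        for side in ("left", "right"):
            world = self.world.get(side)
            low = self.low_confidence.get(
                side, np.zeros(self.n_frames, dtype=bool))
            for i in range(self.n_frames):
                px = self.pixels[side][i]
                rows.append({
                    "frame": i, "time_s": t[i], "side": side,
                    "px_x": px[0], "px_y": px[1],
                    "X_g_m": world[i, 0] if world is not None else np.nan,
                    "Y_g_m": world[i, 1] if world is not None else np.nan,
                    "height_m": (self.heights_m[i]
                                 if self.heights_m is not None else np.nan),
                    "status": self.status[side][i],
                    "low_confidence": bool(low[i]),
                })
        return pd.DataFrame(rows).sort_values(
            ["frame", "side"], ignore_index=True)


def fill_missing_detections(track: MarkerTrack) -> MarkerTrack:
    """Fill detection gaps by linear interpolation of corner coordinates.

    Interior gaps are interpolated between the bracketing detections;
    leading/trailing gaps are held at the nearest detection.  Gaps longer
    than :data:`LONG_GAP_FRAMES` frames are flagged low-confidence.
    """
    n = track.n_frames
    idx = np.arange(n)
    for side in ("left", "right"):
        px = track.pixels[side]
        have = ~np.isnan(px[:, 0])
        if not have.any():
            raise TrackingError(f"no detections at all on the {side} side")
        gaps = ~have
        if not gaps.any():
            track.low_confidence.setdefault(side, np.zeros(n, dtype=bool))
            continue
        for k in range(2):
            px[gaps, k] = np.interp(idx[gaps], idx[have], px[have, k])
        low = np.zeros(n, dtype=bool)
        run = 0
        for i in range(n):
            if gaps[i]:
                run += 1
            else:
                if run > LONG_GAP_FRAMES:
                    low[i - run:i] = True
                run = 0
        if run > LONG_GAP_FRAMES:
            low[n - run:] = True
        for i in idx[gaps]:
            track.status[side][i] = "interpolated"
        track.low_confidence[side] = low
    return track


def track_world_positions(track: MarkerTrack, Hg: Homography) -> MarkerTrack:
    """Map mark corners through Hg and derive the barbell height series.

    Exactly one point per side per frame is mapped (the upper-left mark
    corner); the height is -mean(Y_g) of the two sides, robust to small bar
    tilt.  Frames still missing on a side fall back to the other side's
    height.
    """
    per_frame = 0
    for side in ("left", "right"):
        px = track.pixels[side]
        world = np.full_like(px, np.nan)
        have = ~np.isnan(px[:, 0])
        if have.any():
            world[have] = map_pixel_to_plane(px[have], Hg)
            per_frame += 1
        track.world[side] = world
    assert per_frame <= 2, "world mapping must touch at most 2 points per frame"
    track.points_mapped_per_frame = per_frame
    ys = np.column_stack([track.world["left"][:, 1], track.world["right"][:, 1]])
    with np.errstate(invalid="ignore"):
        track.heights_m = -np.nanmean(ys, axis=1)
    return track
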