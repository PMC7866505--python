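"""Automatic detection of the warning-tape reference corners.

The machine's structural pillars carry two strips of striped warning tape
(red-white by default, black-yellow as the alternative palette).  The four
calibration points are the upper-left corners of the highest and lowest
tape polygons on each side.  Detection runs once, on the first frame of a
session:

1. RGB -> HSV; per-pixel circular hue distance to the target hue gives the
   similarity image ``DifHue = 1 - circularDif(hueTarget, h)``;
2. pixels with saturation below 50% are zeroed (achromatic content carries
   no usable hue);
3. ``DifHue`` is binarized at half the circular distance from the target to
   the nearest *other* primary/secondary hue (1/12 for pure red);
4. two size-selective top-hat band-pass filters (vertical and inclined
   linear structuring elements, lengths twice and half the expected polygon
   size) suppress regions that are too large or too small to be tape
   polygons; their intersection seeds a morphological reconstruction that
   restores the surviving polygons to full extent;
5. per image half, a first-degree line x = a*y + b is fitted to the polygon
   upper-left corners with RANSAC; outliers are discarded and the highest
   and lowest inlier corners become the reference points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import DetectionError, InputError

__all__ = [
    "RansacParams",
    "DetectionConfig",
    "PolygonCandidate",
    "circular_hue_difference",
    "rgb_to_hue_saturation",
    "hue_similarity_image",
    "binarize_hue",
    "hue_threshold",
    "tophat_bandpass",
    "reconstruct_markers",
    "find_polygon_candidates",
    "ransac_line",
    "detect_reference_corners",
]

PRIMARY_SECONDARY_HUES = np.arange(6) / 6.0

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RansacParams:
    """Line-fit robustness parameters (the consensus threshold is in px)."""

    threshold_px: float = 3.0
    iterations: int = 200
    seed: int = 0


@dataclass(frozen=True)
class DetectionConfig:
    """Reference-tape detection parameters.

    ``hue_target`` on the [0, 1) circular hue scale (red = 0, yellow = 1/6);
    ``expected_polygon_px`` is the expected tape-polygon size along the
    structuring elements (defaults to image_height / 40 when None).
    """

    hue_target: float = 0.0
    saturation_min: float = 0.5
    expected_polygon_px: int | None = None
    min_area_px: int = 9
    ransac: RansacParams = field(default_factory=RansacParams)


@dataclass(frozen=True)
class PolygonCandidate:
    """A connected component proposed as a tape polygon or barbell mark."""

    upper_left: tuple[float, float]    # (x, y) leftmost pixel of the topmost row
    bottom_right: tuple[float, float]  # (x, y) rightmost pixel of the bottommost row
    bbox: tuple[int, int, int, int]    # (x0, y0, x1, y1) inclusive
    area: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("candidate area must be positive")

    @property
    def width(self) -> int:
        return self.bbox[2] - self.bbox[0] + 1

    @property
    def height(self) -> int:
        return self.bbox[3] - self.bbox[1] + 1


def circular_hue_difference(h, target):
    """Shortest circular distance between hues on the [0, 1) wheel, in [0, 0.5]."""
    d = np.abs(np.asarray(h, dtype=float) - target)
    return np.minimum(d, 1.0 - d)


def rgb_to_hue_saturation(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue in [0, 1) and saturation in [0, 1] of an RGB image.

    Standard hexcone HSV hue/saturation (identical convention to
    skimage.color.rgb2hsv); the value channel is never needed by the
    detector, so it is not computed.  Accepts uint8 or float input.
    """
    frame = np.asarray(frame)
    if frame.size == 0 or frame.ndim != 3 or frame.shape[2] < 3:
        raise InputError("expected a non-empty RGB frame")
    rgb = np.ascontiguousarray(frame[..., :3], dtype=np.float32)
    if frame.dtype == np.uint8:
        rgb /= 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    chromatic = delta > 0
    safe = np.where(chromatic, delta, 1.0)
    hue = np.where(
        maxc == r, (g - b) / safe,
        np.where(maxc == g, (b - r) / safe + 2.0, (r - g) / safe + 4.0))
    hue = np.where(chromatic, (hue / 6.0) % 1.0, 0.0)
    sat = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
    return hue, sat


def hue_similarity_image(frame: np.ndarray, target: float,
                         saturation_min: float = 0.5) -> np.ndarray:
    """DifHue image: 1 - circular hue distance, gated by saturation.

    Returns values in [0.5, 1] where saturation >= ``saturation_min`` and 0
    elsewhere.  ``frame`` is an RGB image (uint8 or float).  Hue is only
    evaluated at pixels passing the saturation gate, which keeps the
    per-frame cost proportional to the (sparse) colored content.
    """
    frame = np.asarray(frame)
    if frame.size == 0 or frame.ndim != 3 or frame.shape[2] < 3:
        raise InputError("expected a non-empty RGB frame")
    rgb = np.ascontiguousarray(frame[..., :3], dtype=np.float32)
    if frame.dtype == np.uint8:
        rgb /= 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    # saturation gate first; hue is computed only where it can matter
    gate = delta >= saturation_min * maxc
    gate &= maxc > 0
    dif = np.zeros(maxc.shape, dtype=float)
    if gate.any():
        idx = np.nonzero(gate)
        rs, gs, bs = r[idx], g[idx], b[idx]
        ds = delta[idx]
        ms = maxc[idx]
        hue = np.where(
            ms == rs, (gs - bs) / ds,
            np.where(ms == gs, (bs - rs) / ds + 2.0, (rs - gs) / ds + 4.0))
        hue = (hue / 6.0) % 1.0
        dif[idx] = 1.0 - circular_hue_difference(hue, target)
    return dif


def hue_threshold(target: float) -> float:
    """Binarization half-range: half the circular distance from the target
    to the nearest primary/secondary hue other than the target's own bin."""
    dists = circular_hue_difference(PRIMARY_SECONDARY_HUES, target)
    own = int(np.argmin(dists))
    others = np.delete(dists, own)
    return 0.5 * float(np.min(others))


def binarize_hue(dif_hue: np.ndarray, target: float) -> np.ndarray:
    """DifHueBin: keep saturated pixels whose hue falls within the target band."""
    thr = hue_threshold(target)
    # DifHue = 1 - distance on gated pixels, 0 on rejected ones
    return (dif_hue > 0) & (dif_hue >= 1.0 - thr)


def _round_to_odd(x: float) -> int:
    n = max(int(round(x)), 1)
    return n if n % 2 == 1 else n + 1


def _linear_opening(mask: np.ndarray, length: int, orientation: str) -> np.ndarray:
    """Binary opening with a linear structuring element of odd ``length``.

    Orientations: 'vertical', 'horizontal', 'diagonal' (down-right, the
    inclined 135-degree element), 'antidiagonal' (down-left).  Diagonal
    openings are computed by shearing rows so the line becomes vertical,
    which keeps the cost independent of the element length.
    """
    if length <= 1:
        return mask.copy()
    m = mask.astype(np.uint8)
    if orientation in ("vertical", "horizontal"):
        axis = 0 if orientation == "vertical" else 1
        er = ndi.minimum_filter1d(m, length, axis=axis, mode="constant", cval=0)
        op = ndi.maximum_filter1d(er, length, axis=axis, mode="constant", cval=0)
        return op.astype(bool)
    if orientation not in ("diagonal", "antidiagonal"):
        raise ValueError(f"unknown orientation {orientation!r}")
    h, w = m.shape
    rows = np.arange(h)
    shift = (h - 1 - rows) if orientation == "diagonal" else rows
    sheared = np.zeros((h, w + h), dtype=np.uint8)
    cols = np.arange(w)[None, :] + shift[:, None]
    sheared[rows[:, None], cols] = m
    er = ndi.minimum_filter1d(sheared, length, axis=0, mode="constant", cval=0)
    op = ndi.maximum_filter1d(er, length, axis=0, mode="constant", cval=0)
    return op[rows[:, None], cols].astype(bool)


def tophat_bandpass(mask: np.ndarray, orientation: str,
                    expected_size: int) -> np.ndarray:
    """Size-selective band-pass: difference of two white top-hats.

    ``BP = tophat(mask, ee1) - tophat(mask, ee2)`` with linear structuring
    elements of lengths ~2x and ~0.5x the expected size (rounded to odd), so
    features larger than twice or smaller than half the expected size along
    the element's orientation are eliminated.
    """
    if expected_size < 2:
        raise ValueError("expected_size must be >= 2 px")
    mask = np.asarray(mask, dtype=bool)
    ee1 = _round_to_odd(2.0 * expected_size)
    ee2 = _round_to_odd(expected_size / 2.0)
    tophat1 = mask & ~_linear_opening(mask, ee1, orientation)
    tophat2 = mask & ~_linear_opening(mask, ee2, orientation)
    return tophat1 & ~tophat2


def reconstruct_markers(markers: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Morphological reconstruction by dilation of ``mask`` from ``markers``.

    Equivalent to keeping the 8-connected components of ``mask`` that
    intersect ``markers`` (markers are clipped into the mask first).
    """
    markers = np.asarray(markers, dtype=bool) & np.asarray(mask, dtype=bool)
    if not markers.any():
        return np.zeros_like(markers)
    labels, _ = ndi.label(mask, structure=_CONN8)
    keep = np.unique(labels[markers])
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def find_polygon_candidates(mask: np.ndarray, min_area: int = 1,
                            offset: tuple[int, int] = (0, 0),
                            ) -> list[PolygonCandidate]:
    """Extract connected components of ``mask`` as PolygonCandidates.

    ``offset`` (x0, y0) shifts reported coordinates back into a full-frame
    reference when ``mask`` is a cropped subimage.
    """
    labels, n = ndi.label(mask, structure=_CONN8)
    ox, oy = offset
    out: list[PolygonCandidate] = []
    slices = ndi.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == idx
        area = int(comp.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(comp)
        y0 = ys.min()
        y1 = ys.max()
        top_x = xs[ys == y0].min()
        bot_x = xs[ys == y1].max()
        r0, c0 = sl[0].start, sl[1].start
        out.append(PolygonCandidate(
            upper_left=(float(c0 + top_x + ox), float(r0 + y0 + oy)),
            bottom_right=(float(c0 + bot_x + ox), float(r0 + y1 + oy)),
            bbox=(int(c0 + xs.min() + ox), int(r0 + y0 + oy),
                  int(c0 + xs.max() + ox), int(r0 + y1 + oy)),
            area=area,
        ))
    return out


def ransac_line(points: np.ndarray, params: RansacParams,
                ) -> tuple[tuple[float, float], np.ndarray]:
    """Robustly fit x = a*y + b to (x, y) points.

    Returns ((a, b), boolean inlier mask).  The parametrization in y suits
    near-vertical tape lines.  Raises :class:`DetectionError` for fewer than
    2 points or an all-coincident configuration.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        raise DetectionError("need at least 2 corner points to fit a line")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) < 1e-9:
        raise DetectionError("degenerate line: all corners at the same height")

    def fit(idx):
        A = np.column_stack([y[idx], np.ones(len(idx))])
        coef, *_ = np.linalg.lstsq(A, x[idx], rcond=None)
        return coef

    if n == 2:
        coef = fit(np.arange(2))
        return (float(coef[0]), float(coef[1])), np.ones(2, dtype=bool)

    rng = np.random.default_rng(params.seed)
    best_inliers = None
    for _ in range(params.iterations):
        i, j = rng.choice(n, size=2, replace=False)
        if abs(y[i] - y[j]) < 1e-9:
            continue
        a = (x[i] - x[j]) / (y[i] - y[j])
        b = x[i] - a * y[i]
        resid = np.abs(x - (a * y + b))
        inliers = resid <= params.threshold_px
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 2:
        raise DetectionError("RANSAC consensus below minimum (2 inliers)")
    coef = fit(np.nonzero(best_inliers)[0])
    resid = np.abs(x - (coef[0] * y + coef[1]))
    inliers = resid <= params.threshold_px
    return (float(coef[0]), float(coef[1])), inliers


def _segment_tape(frame: np.ndarray, config: DetectionConfig,
                  expected: int) -> np.ndarray:
    dif = hue_similarity_image(frame, config.hue_target, config.saturation_min)
    binmask = binarize_hue(dif, config.hue_target)
    bp_v = tophat_bandpass(binmask, "vertical", expected)
    bp_d = tophat_bandpass(binmask, "diagonal", expected)
    # both orientations must agree for a seed: isolates compact tape polygons
    return reconstruct_markers(bp_v & bp_d, binmask)


def detect_reference_corners(frame: np.ndarray,
                             config: DetectionConfig = DetectionConfig(),
                             ) -> tuple[np.ndarray, dict]:
    """Detect the four tape reference corners on the first frame.

    Returns (corners, inliers): ``corners`` is a (4, 2) array of pixel
    points ordered P1 top-left, P2 bottom-left, P3 bottom-right, P4
    top-right; ``inliers`` maps 'left'/'right' to the per-side inlier
    :class:`PolygonCandidate` lists (needed later to build search strips).
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise InputError("empty frame")
    height, width = frame.shape[:2]
    expected = config.expected_polygon_px or max(int(round(height / 40)), 2)
    filtered = _segment_tape(frame, config, expected)

    half = width // 2
    sides = {}
    for side, sl in (("left", np.s_[:, :half]), ("right", np.s_[:, half:])):
        offset = (0, 0) if side == "left" else (half, 0)
        cands = find_polygon_candidates(filtered[sl], config.min_area_px, offset)
        if len(cands) < 2:
            raise DetectionError(
                f"fewer than 2 tape polygons detected on the {side} side")
        corners = np.array([c.upper_left for c in cands])
        try:
            _, inlier_mask = ransac_line(corners, config.ransac)
        except DetectionError as exc:
            raise DetectionError(f"{side} side: {exc}") from exc
        inliers = [c for c, keep in zip(cands, inlier_mask) if keep]
        if len(inliers) < 2:
            raise DetectionError(
                f"fewer than 2 inlier polygons on the {side} side")
        sides[side] = inliers

    def top_bottom(cands):
        ordered = sorted(cands, key=lambda c: c.upper_left[1])
        return ordered[0].upper_left, ordered[-1].upper_left

    p1, p2 = top_bottom(sides["left"])
    p4, p3 = top_bottom(sides["right"])
    return np.array([p1, p2, p3, p4], dtype=float), sides
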