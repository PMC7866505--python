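"""Synthetic multipower-machine scenes with exact ground truth.

The validation strategy of this package rests on rendered scenes whose
geometry is known to machine precision: two striped tape strips on the
structural plane (Z = 0), a barbell bar with one colored mark per end on
the parallel guide plane (Z = Dg), projected through an arbitrary pinhole
camera pose, with the bar following a prescribed vertical motion profile.
Every rendered sequence carries its ground truth — true mark pixel
positions (exact projections), true height series, and closed-form
repetition metrics — so the full detection / calibration / tracking /
kinematics pipeline can be checked end to end without any recorded video.

The default scene mirrors a realistic setup: a 1.5 m-wide machine filmed
in portrait 1080 x 1920 from 2.2 m at 240 fps, the camera covering ~1.7 m
horizontally (~1.6 mm per pixel on the structural plane).

A second generator produces paired instrument measurements (practical =
criterion + bias + noise, on top of between-subject and between-rep
variation) for exercising the agreement statistics with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .agreement_stats import PairedMeasurements
from .camera_geometry import CameraIntrinsics, PlanePose, project_points
from .errors import InputError
from .machine_calibration import MachineGeometry, ReferenceQuad, reconstruct_reference_quad

__all__ = [
    "MotionProfile",
    "generate_motion_profile",
    "SceneSpec",
    "make_default_scene",
    "GroundTruth",
    "SyntheticSequence",
    "render_sequence",
    "generate_paired_measurements",
]

RED = (1.0, 0.0, 0.0)
WHITE = (1.0, 1.0, 1.0)
YELLOW = (1.0, 1.0, 0.0)
BLACK = (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# motion profiles

@dataclass(frozen=True)
class MotionProfile:
    """Rest -> concentric lift -> rest height profile with closed forms.

    Families: 'constant' (constant-velocity ascent), 'half_sine'
    (half-sine velocity curve), 'min_jerk' (minimum-jerk displacement).
    Heights are the ascent above the rest position, in metres.
    """

    family: str
    range_m: float
    duration_s: float
    fps: float
    rest_before_s: float = 0.25
    rest_after_s: float = 0.25

    def __post_init__(self) -> None:
        if self.range_m <= 0 or self.duration_s <= 0 or self.fps <= 0:
            raise InputError("range, duration and fps must be positive")
        if self.family not in ("constant", "half_sine", "min_jerk"):
            raise InputError(f"unknown profile family {self.family!r}")
        if self.rest_before_s < 0 or self.rest_after_s < 0:
            raise InputError("rest durations must be non-negative")

    @property
    def total_s(self) -> float:
        return self.rest_before_s + self.duration_s + self.rest_after_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_s * self.fps)) + 1

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def mean_velocity_mps(self) -> float:
        return self.range_m / self.duration_s

    @property
    def peak_velocity_mps(self) -> float:
        vbar = self.mean_velocity_mps
        if self.family == "constant":
            return vbar
        if self.family == "half_sine":
            return float(np.pi / 2) * vbar
        return 1.875 * vbar  # minimum jerk: 30/16

    def lift(self, t) -> np.ndarray:
        """Ascent height at absolute time t (rest phases included)."""
        tau = np.clip((np.asarray(t, dtype=float) - self.rest_before_s)
                      / self.duration_s, 0.0, 1.0)
        r = self.range_m
        if self.family == "constant":
            return r * tau
        if self.family == "half_sine":
            return r / 2.0 * (1.0 - np.cos(np.pi * tau))
        return r * (10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5)

    @property
    def heights_m(self) -> np.ndarray:
        h = self.lift(self.times_s)
        return h if isinstance(h, np.ndarray) else np.asarray(h)


def generate_motion_profile(family: str, range_m: float, duration_s: float,
                            fps: float, rest_before_s: float = 0.25,
                            rest_after_s: float = 0.25) -> MotionProfile:
    """Build a lift profile; closed-form mean velocity is range / duration."""
    return MotionProfile(family=family, range_m=range_m, duration_s=duration_s,
                         fps=fps, rest_before_s=rest_before_s,
                         rest_after_s=rest_after_s)


# ---------------------------------------------------------------------------
# scene specification

@dataclass(frozen=True)
class SceneSpec:
    """A virtual machine + camera.  All world lengths in metres.

    ``tape_stripes``/``tape_gaps`` are (x0, y0, x1, y1) rectangles on the
    structural plane Z = 0 in the target and complementary tape colors;
    barbell marks are ``mark_size`` rectangles with left edges at
    ``mark_x`` on the guide plane Z = Dg, their top edge at
    ``bar_top_y - lift(t)``.
    """

    geometry: MachineGeometry
    quad: ReferenceQuad
    intrinsics: CameraIntrinsics
    pose: PlanePose
    image_size: tuple[int, int]            # (width, height)
    tape_stripes: tuple = ()
    tape_gaps: tuple = ()
    stripe_rgb: tuple = RED
    gap_rgb: tuple = WHITE
    mark_rgb: tuple = YELLOW
    mark_size: tuple[float, float] = (0.05, 0.04)
    mark_x: tuple[float, float] = (0.20, 1.25)
    bar_top_y: float = 0.95
    bar_rgb: tuple = (0.30, 0.30, 0.30)
    background_rgb: tuple = (0.55, 0.55, 0.55)

    @property
    def tape_hue_target(self) -> float:
        return 0.0 if self.stripe_rgb == RED else 1.0 / 6.0

    def project(self, points: np.ndarray) -> np.ndarray:
        """The renderer's own projection (shared with ground truth)."""
        return project_points(points, self.intrinsics, self.pose)

    def reference_corner_pixels(self) -> np.ndarray:
        """True projections of the four reference corners P1..P4."""
        return self.project(self.quad.points)

    def mark_corner_world(self, lift: float) -> dict[str, np.ndarray]:
        """World upper-left corner of each mark at a given ascent."""
        y = self.bar_top_y - lift
        dg = self.geometry.Dg
        return {"left": np.array([self.mark_x[0], y, dg]),
                "right": np.array([self.mark_x[1], y, dg])}


def _rot_x(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def make_default_scene(image_size: tuple[int, int] = (1080, 1920),
                       distance_m: float = 2.2,
                       tilt_deg: float = 0.0,
                       focal_px: float | None = None,
                       dg_m: float = 0.15,
                       palette: str = "red_white",
                       span_m: float = 1.7,
                       bar_top_y: float = 0.95) -> SceneSpec:
    """Standard machine layout seen by a tripod camera.

    Machine: reference strips 5 cm wide with left edges at x = 0 and
    x = 1.45 (outer width 1.5 m), stripes of 10 cm in the target color
    alternating with 10 cm gaps, target-color stripes starting at
    y = 0, 0.2, ..., 1.0 so the reference quad is 1.45 x 1.0 m.  Camera:
    pitch ``tilt_deg`` about the horizontal axis, looking at the machine
    centre from ``distance_m``; the focal length defaults to covering
    ``span_m`` horizontally.
    """
    width, height = image_size
    if palette == "red_white":
        stripe_rgb, gap_rgb = RED, WHITE
    elif palette == "black_yellow":
        stripe_rgb, gap_rgb = YELLOW, BLACK
    else:
        raise InputError(f"unknown tape palette {palette!r}")

    tape_w, stripe_h, period, n_stripes = 0.05, 0.1, 0.2, 6
    x_left, x_right = 0.0, 1.45
    stripes, gaps = [], []
    for x0 in (x_left, x_right):
        for k in range(n_stripes):
            y0 = k * period
            stripes.append((x0, y0, x0 + tape_w, y0 + stripe_h))
            if k < n_stripes - 1:
                gaps.append((x0, y0 + stripe_h, x0 + tape_w, y0 + period))

    geometry = MachineGeometry(
        D12=1.0, D23=1.45, D34=1.0, D41=1.45,
        D13=float(np.hypot(1.45, 1.0)), D24=float(np.hypot(1.45, 1.0)),
        Dg=dg_m)
    quad = reconstruct_reference_quad(geometry)

    f = focal_px if focal_px is not None else width * distance_m / span_m
    intr = CameraIntrinsics.simple(f, width, height)
    look_at = np.array([0.725, 0.55, 0.0])
    R = _rot_x(tilt_deg)
    t = np.array([0.0, 0.0, distance_m]) - R @ look_at
    pose = PlanePose(R, t)

    return SceneSpec(geometry=geometry, quad=quad, intrinsics=intr, pose=pose,
                     image_size=(width, height),
                     tape_stripes=tuple(stripes), tape_gaps=tuple(gaps),
                     stripe_rgb=stripe_rgb, gap_rgb=gap_rgb,
                     bar_top_y=bar_top_y)


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class GroundTruth:
    """Exact per-frame truth accompanying a rendered sequence."""

    mark_pixels: dict[str, np.ndarray]      # (n, 2) upper-left corners
    heights_m: np.ndarray                   # ascent above rest per frame
    reference_pixels: np.ndarray            # (4, 2) P1..P4 projections
    range_m: float
    mean_velocity_mps: float
    peak_velocity_mps: float
    duration_s: float
    fps: float


def _fill_rect(canvas: np.ndarray, spec: SceneSpec, rect, z: float,
               rgb: tuple) -> None:
    x0, y0, x1, y1 = rect
    corners = np.array([[x0, y0, z], [x0, y1, z], [x1, y1, z], [x1, y0, z]])
    pix = spec.project(corners)
    rr, cc = draw_polygon(pix[:, 1], pix[:, 0], shape=canvas.shape[:2])
    canvas[rr, cc] = rgb


class SyntheticSequence:
    """Lazily rendered frame sequence with ground truth.

    Frames are rendered on demand (``frame(i)`` or iteration) so that long
    high-resolution sequences never have to be held in memory at once.
    """

    def __init__(self, spec: SceneSpec, profile: MotionProfile,
                 noise_sigma: float = 0.0, seed: int = 0,
                 occlusions: tuple = ()):
        self.spec = spec
        self.profile = profile
        self.noise_sigma = float(noise_sigma)
        self.seed = int(seed)
        #: {(frame_index, side)} pairs whose mark is blanked (occluded)
        self.occlusions = frozenset(occlusions)
        self._static = self._render_static()
        self.ground_truth = self._compute_ground_truth()

    @property
    def n_frames(self) -> int:
        return self.profile.n_frames

    @property
    def fps(self) -> float:
        return self.profile.fps

    def _render_static(self) -> np.ndarray:
        w, h = self.spec.image_size
        canvas = np.empty((h, w, 3), dtype=float)
        canvas[:] = self.spec.background_rgb
        for rect in self.spec.tape_gaps:
            _fill_rect(canvas, self.spec, rect, 0.0, self.spec.gap_rgb)
        for rect in self.spec.tape_stripes:
            _fill_rect(canvas, self.spec, rect, 0.0, self.spec.stripe_rgb)
        return (canvas * 255).round().astype(np.uint8)

    def _compute_ground_truth(self) -> GroundTruth:
        spec, prof = self.spec, self.profile
        heights = prof.heights_m
        w, h = spec.image_size
        mark_pixels = {}
        dg = spec.geometry.Dg
        for side, x0 in zip(("left", "right"), spec.mark_x):
            corners = np.column_stack([
                np.full_like(heights, x0),
                spec.bar_top_y - heights,
                np.full_like(heights, dg)])
            pix = spec.project(corners)
            bad = np.nonzero((pix[:, 0] < 0) | (pix[:, 0] >= w) |
                             (pix[:, 1] < 0) | (pix[:, 1] >= h))[0]
            if bad.size:
                raise InputError(
                    f"bar path leaves the field of view on the {side} side "
                    f"in frames {bad[:10].tolist()}")
            mark_pixels[side] = pix
        return GroundTruth(
            mark_pixels=mark_pixels,
            heights_m=heights,
            reference_pixels=spec.reference_corner_pixels(),
            range_m=prof.range_m,
            mean_velocity_mps=prof.mean_velocity_mps,
            peak_velocity_mps=prof.peak_velocity_mps,
            duration_s=prof.duration_s,
            fps=prof.fps,
        )

    def frame(self, i: int) -> np.ndarray:
        """Render frame ``i`` as an (H, W, 3) uint8 RGB image."""
        if not 0 <= i < self.n_frames:
            raise IndexError(f"frame {i} out of range")
        spec = self.spec
        canvas = self._static.copy()
        lift = float(self.profile.lift(i / self.fps))
        y_top = spec.bar_top_y - lift
        wm, hm = spec.mark_size
        bar_rgb = tuple(int(round(255 * c)) for c in spec.bar_rgb)
        mark_rgb = tuple(int(round(255 * c)) for c in spec.mark_rgb)
        dg = spec.geometry.Dg
        # bar behind the marks, spanning between them
        bar = (spec.mark_x[0] - 0.02, y_top + 0.005,
               spec.mark_x[1] + wm + 0.02, y_top + 0.005 + 0.03)
        _fill_rect(canvas, spec, bar, dg, bar_rgb)
        for side, x0 in zip(("left", "right"), spec.mark_x):
            if (i, side) in self.occlusions:
                continue
            _fill_rect(canvas, spec, (x0, y_top, x0 + wm, y_top + hm),
                       dg, mark_rgb)
        if self.noise_sigma > 0:
            rng = np.random.default_rng((self.seed, i))
            noise = rng.normal(0.0, self.noise_sigma * 255.0,
                               canvas.shape)
            canvas = np.clip(canvas.astype(float) + noise,
                             0, 255).astype(np.uint8)
        return canvas

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    def __len__(self) -> int:
        return self.n_frames


def render_sequence(spec: SceneSpec, profile: MotionProfile,
                    noise_sigma: float = 0.0, seed: int = 0,
                    occlusions: tuple = ()) -> SyntheticSequence:
    """Render a lift sequence; raises if the bar path leaves the view."""
    return SyntheticSequence(spec, profile, noise_sigma=noise_sigma,
                             seed=seed, occlusions=occlusions)


# ---------------------------------------------------------------------------
# paired-measurement generator for the agreement statistics

def generate_paired_measurements(n_subjects: int = 20,
                                 reps_per_subject: int = 8,
                                 between_sd: float = 0.10,
                                 within_sd: float = 0.05,
                                 bias: float = -0.016,
                                 instrument_sd: float = 0.009,
                                 mu: float = 0.58,
                                 seed: int = 0) -> PairedMeasurements:
    """Simulate paired instrument readings with known truth structure.

    Subject true means are Normal(mu, between_sd^2); each repetition adds
    Normal(0, within_sd^2); the practical instrument reads the criterion
    value plus ``bias`` plus Normal(0, instrument_sd^2).  Defaults emulate
    a mean-velocity comparison across 20 athletes x 8 squats (values in
    m/s).
    """
    if n_subjects < 2:
        raise InputError("need at least 2 subjects")
    if reps_per_subject < 1:
        raise InputError("need at least 1 repetition per subject")
    if between_sd < 0 or within_sd < 0 or instrument_sd < 0:
        raise InputError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    subj_means = rng.normal(mu, between_sd, n_subjects)
    subjects = np.repeat(np.arange(n_subjects), reps_per_subject)
    criterion = (np.repeat(subj_means, reps_per_subject)
                 + rng.normal(0.0, within_sd, subjects.size))
    practical = criterion + bias + rng.normal(0.0, instrument_sd, subjects.size)
    return PairedMeasurements(a=practical, b=criterion, subjects=subjects)
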