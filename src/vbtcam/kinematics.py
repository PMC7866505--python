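"""Concentric-phase kinematics: range, velocity, force, and power.

The barbell height series h(t), sampled uniformly at the camera frame rate,
is the sole kinematic input.  Velocity is the time derivative of position
(central differences), acceleration the derivative of velocity, and the
force applied to the system follows from the equation of motion of the
lifted mass

    F(t) = (m_a + m_l) * (a_b(t) + g)

with athlete body mass ``m_a``, external load ``m_l``, barbell acceleration
``a_b`` and gravitational acceleration ``g``; instantaneous power is
``P = F * v``.  Per repetition, summary metrics are computed over the
concentric (lifting) phase only, detected from sustained threshold
crossings of the upward velocity.

The module also provides the closed-form capture-resolution arithmetic of a
video instrument (metres-per-pixel, milliseconds-per-frame, and the
inter-frame displacement of a mark moving at a given velocity), used to
reason about measurement precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "LoadConfig",
    "RepSegment",
    "RepMetrics",
    "SegmentationConfig",
    "differentiate_series",
    "segment_concentric_phase",
    "compute_force_power",
    "summarize_repetition",
    "spatial_resolution_mm",
    "temporal_resolution_ms",
    "interframe_displacement_cm",
]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class LoadConfig:
    """Masses entering the equation of motion, in kg."""

    m_athlete: float
    m_load: float
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.m_athlete < 0 or self.m_load < 0:
            raise ValueError("masses must be non-negative")
        if self.g <= 0:
            raise ValueError("g must be positive")

    @property
    def total_mass(self) -> float:
        return self.m_athlete + self.m_load


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds bounding the concentric phase.

    ``v_start`` (m/s): upward velocity that must be exceeded, sustained for
    ``sustain`` samples, for an ascent to begin.  ``v_stop`` (m/s): the
    ascent ends at the first sample opening a run of ``sustain`` samples
    whose velocity is non-positive or below ``v_stop`` in magnitude (the
    sustain requirement makes the boundary robust to single-sample
    dropouts from pixel quantization).
    """

    v_start: float = 0.05
    v_stop: float = 0.02
    sustain: int = 3


@dataclass(frozen=True)
class RepSegment:
    """Index range [start, end] of one concentric repetition."""

    start: int
    end: int
    fps: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError("segment start must precede its end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fps


@dataclass(frozen=True)
class RepMetrics:
    """Concentric-phase summary of one repetition."""

    range_cm: float
    mean_velocity_mps: float
    peak_velocity_mps: float
    mean_force_N: float
    mean_power_W: float
    time_to_peak_ms: float
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "range_cm": self.range_cm,
            "mean_velocity_mps": self.mean_velocity_mps,
            "peak_velocity_mps": self.peak_velocity_mps,
            "mean_force_N": self.mean_force_N,
            "mean_power_W": self.mean_power_W,
            "time_to_peak_ms": self.time_to_peak_ms,
            "duration_s": self.duration_s,
        }


def differentiate_series(series: np.ndarray, fps: float,
                         smooth_window: int | None = None) -> np.ndarray:
    """Differentiate a uniformly sampled series.

    Central differences in the interior, one-sided at the ends; an optional
    centered moving average of ``smooth_window`` samples is applied first.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InputError("need at least 3 samples to differentiate")
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(y, pad, mode="edge")
        y = np.convolve(padded, kernel, mode="valid")[:y.size]
    return np.gradient(y, 1.0 / fps)


def _sustained_crossing(flags: np.ndarray, start: int, sustain: int) -> int | None:
    """First index >= start where ``flags`` holds for ``sustain`` samples."""
    n = flags.size
    run = 0
    for i in range(start, n):
        run = run + 1 if flags[i] else 0
        if run >= sustain:
            return i - sustain + 1
    return None


def segment_concentric_phase(series: np.ndarray, fps: float,
                             config: SegmentationConfig = SegmentationConfig(),
                             smooth_window: int | None = None,
                             ) -> list[RepSegment]:
    """Detect the concentric (lifting) phases of a height series.

    Boundaries are found on interval (forward-difference) velocities
    ``v[i] = (h[i+1] - h[i]) * fps``: the sample at which the upward
    interval velocity first exceeds ``v_start`` (sustained) still holds the
    pre-ascent position, so it is the segment start; the ascent ends at the
    first sample opening a sustained run of non-positive or sub-threshold
    intervals.  Returns the repetitions in order; an empty list when no
    ascent is found.
    """
    h = np.asarray(series, dtype=float)
    if h.size / fps < 0.2:
        raise InputError("series shorter than 0.2 s")
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        h = np.convolve(np.pad(h, pad, mode="edge"), kernel,
                        mode="valid")[:h.size]
    v = np.diff(h) * fps  # v[i]: mean velocity over the interval [i, i+1]
    segments: list[RepSegment] = []
    n = v.size
    i = 0
    while True:
        start = _sustained_crossing(v > config.v_start, i, config.sustain)
        if start is None:
            break
        end = None
        run = 0
        for j in range(start + 1, n):
            if v[j] <= 0 or abs(v[j]) < config.v_stop:
                run += 1
                if run >= config.sustain:
                    end = j - config.sustain + 1
                    break
            else:
                run = 0
        if end is None:
            end = n  # ascent runs to the last sample of h
        if end > start:
            segments.append(RepSegment(start=start, end=end, fps=fps))
        i = end + 1
        if i >= n - config.sustain:
            break
    return segments


def compute_force_power(accel: np.ndarray, velocity: np.ndarray,
                        load: LoadConfig) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous force and power series from the equation of motion."""
    a = np.asarray(accel, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if a.shape != v.shape:
        raise InputError("acceleration and velocity series differ in length")
    force = load.total_mass * (a + load.g)
    return force, force * v


def summarize_repetition(series: np.ndarray, segment: RepSegment,
                         load: LoadConfig,
                         smooth_window: int | None = None) -> RepMetrics:
    """Concentric-phase summary metrics for one repetition.

    Mean velocity is range over duration (the standard VBT definition);
    force and power are averaged point-wise over the segment.
    """
    h = np.asarray(series, dtype=float)
    if segment.end >= h.size:
        raise InputError("segment exceeds the series length")
    fps = segment.fps
    v = differentiate_series(h, fps, smooth_window)
    a = differentiate_series(v, fps)
    force, power = compute_force_power(a, v, load)
    s, e = segment.start, segment.end
    rng = h[e] - h[s]
    duration = segment.duration_s
    seg_v = v[s:e + 1]
    peak_idx = int(np.argmax(seg_v))
    return RepMetrics(
        range_cm=float(rng * 100.0),
        mean_velocity_mps=float(rng / duration),
        peak_velocity_mps=float(seg_v[peak_idx]),
        mean_force_N=float(np.mean(force[s:e + 1])),
        mean_power_W=float(np.mean(power[s:e + 1])),
        time_to_peak_ms=float(peak_idx / fps * 1000.0),
        duration_s=float(duration),
    )


def spatial_resolution_mm(length_covered_m: float, pixels: int) -> float:
    """Metres of scene per pixel along one image axis, in millimetres."""
    if length_covered_m <= 0 or pixels <= 0:
        raise InputError("length and pixel count must be positive")
    return length_covered_m * 1000.0 / pixels


def temporal_resolution_ms(fps: float) -> float:
    """Time between consecutive frames, in milliseconds."""
    if fps <= 0:
        raise InputError("fps must be positive")
    return 1000.0 / fps


def interframe_displacement_cm(velocity_mps: float, fps: float) -> float:
    """Distance a mark moving at ``velocity_mps`` covers between frames, cm."""
    if fps <= 0:
        raise InputError("fps must be positive")
    return velocity_mps * 100.0 / fps
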