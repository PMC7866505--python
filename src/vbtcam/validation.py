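"""Synthetic end-to-end validation harness.

Because no recorded gym videos ship with the package, the instrument is
validated against rendered scenes with exact ground truth: a batch of lift
sequences spanning the velocity range relevant to velocity-based training
and a realistic range of camera tilts is rendered, pushed through the full
pipeline (reference detection, two-plane calibration, tracking,
kinematics), and the recovered per-repetition metrics are compared with
the renderer's closed-form truth.
"""

from __future__ import annotations

import numpy as np

from .cli_io import PipelineConfig, run_pipeline
from .kinematics import LoadConfig
from .synthetic_scene import (
    generate_motion_profile,
    make_default_scene,
    render_sequence,
)

__all__ = ["end_to_end_recovery"]


def end_to_end_recovery(n_sequences: int = 20,
                        fps: float = 240.0,
                        image_size: tuple[int, int] = (1080, 1920),
                        velocity_range: tuple[float, float] = (0.4, 1.2),
                        tilt_range_deg: tuple[float, float] = (0.0, 20.0),
                        range_m: float = 0.35,
                        load: LoadConfig = LoadConfig(80.0, 20.0),
                        ) -> list[dict]:
    """Render constant-velocity lifts and measure pipeline recovery error.

    Sequences sweep mean velocity and camera tilt jointly across their
    ranges.  The camera intrinsics are passed to calibration (the
    metadata-supplied-focal path); everything else — reference corners,
    pose, guide homography, tracking, segmentation — is recovered from the
    rendered frames.  Returns one record per sequence with the prescribed
    and recovered mean velocity and range plus their errors.
    """
    velocities = np.linspace(*velocity_range, n_sequences)
    tilts = np.linspace(*tilt_range_deg, n_sequences)
    records = []
    for v, tilt in zip(velocities, tilts):
        scene = make_default_scene(image_size=image_size, tilt_deg=float(tilt))
        profile = generate_motion_profile(
            "constant", range_m, range_m / float(v), fps,
            rest_before_s=0.12, rest_after_s=0.12)
        seq = render_sequence(scene, profile)
        config = PipelineConfig(geometry=scene.geometry, fps=fps, load=load,
                                intrinsics=scene.intrinsics)
        result = run_pipeline(seq, config)
        if len(result.reps) != 1:
            records.append({
                "velocity_mps": float(v), "tilt_deg": float(tilt),
                "n_reps": len(result.reps),
                "velocity_error_pct": np.inf, "range_error_mm": np.inf})
            continue
        rep = result.reps[0]
        records.append({
            "velocity_mps": float(v),
            "tilt_deg": float(tilt),
            "n_reps": 1,
            "recovered_velocity_mps": rep.mean_velocity_mps,
            "recovered_range_cm": rep.range_cm,
            "velocity_error_pct":
                abs(rep.mean_velocity_mps - v) / v * 100.0,
            "range_error_mm": abs(rep.range_cm - range_m * 100.0) * 10.0,
            "mean_force_N": rep.mean_force_N,
            "mean_power_W": rep.mean_power_W,
        })
    return records
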