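"""Two-plane autocalibration of a multipower (Smith) machine.

The barbell of a multipower machine slides on two parallel guide pillars, so
its motion is confined to a plane (the *guide plane*).  Reference tape can
only be fixed to the *structural* pillars, which form a second plane parallel
to the first at a perpendicular gap ``Dg``.  Calibration therefore proceeds
in two stages:

1. the four taped reference points are reconstructed metrically from six
   tape-measured distances (four sides, two diagonals) by the law of
   cosines, giving a planar quadrilateral with the origin at the top-left
   point, X rightward, Y downward and Z = 0;
2. the structural homography ``Hs`` is estimated from the four detected
   image corners, the camera pose is recovered from ``Hs`` (self-calibrating
   the focal length when no intrinsics are supplied), four virtual guide
   points ``P_ig = (X_is, Y_is, Dg)`` are projected through that pose, and a
   second homography ``Hg`` is fitted to these synthetic correspondences.

``Hg`` maps barbell-mark pixels to metric coordinates in the guide plane and
remains valid for the whole session while the camera sits on its tripod.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .camera_geometry import (
    CameraIntrinsics,
    Homography,
    PlanePose,
    estimate_focal_from_homography,
    estimate_homography,
    pose_from_homography,
    project_points,
)
from .errors import (
    CalibrationError,
    GeometryError,
    MeasurementInconsistencyError,
    PointBehindCameraError,
)

__all__ = [
    "MachineGeometry",
    "ReferenceQuad",
    "CalibrationResult",
    "reconstruct_reference_quad",
    "calibrate_structural",
    "synthesize_guide_correspondences",
    "calibrate_guide",
    "calibrate",
]

#: tolerance for the redundant sixth tape-measured distance (realistic
#: tape-measure error)
REDUNDANCY_TOL_M = 0.005


@dataclass(frozen=True)
class MachineGeometry:
    """Six inter-mark distances and the structural-to-guide gap, in metres.

    Sides ``D12``..``D41`` and diagonals ``D13``, ``D24`` of the reference
    quadrilateral P1 (top-left), P2 (bottom-left), P3 (bottom-right),
    P4 (top-right); ``Dg`` is the perpendicular gap between the structural
    plane (tapes) and the guide plane (barbell).
    """

    D12: float
    D23: float
    D34: float
    D41: float
    D13: float
    D24: float
    Dg: float

    def __post_init__(self) -> None:
        for name in ("D12", "D23", "D34", "D41", "D13", "D24", "Dg"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"distance {name} must be positive")
        for tri in (("D12", "D23", "D13"), ("D12", "D41", "D24"),
                    ("D34", "D23", "D24"), ("D34", "D41", "D13")):
            a, b, c = (getattr(self, n) for n in tri)
            if a + b <= c or b + c <= a or c + a <= b:
                raise GeometryError(
                    f"triangle inequality violated for ({', '.join(tri)})")

    @classmethod
    def from_yaml(cls, path) -> "MachineGeometry":
        """Load from a YAML file {units: cm|m, D12s..D24s, Dg}."""
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "MachineGeometry":
        units = str(data.get("units", "m")).lower()
        if units not in ("m", "cm"):
            raise GeometryError(f"unknown units {units!r} (use 'm' or 'cm')")
        scale = 0.01 if units == "cm" else 1.0

        def get(key: str) -> float:
            for k in (key, key + "s"):
                if k in data:
                    return float(data[k]) * scale
            raise GeometryError(f"missing distance {key!r} in geometry file")

        return cls(D12=get("D12"), D23=get("D23"), D34=get("D34"),
                   D41=get("D41"), D13=get("D13"), D24=get("D24"),
                   Dg=get("Dg"))

    def to_dict(self) -> dict:
        return {"units": "m", "D12s": self.D12, "D23s": self.D23,
                "D34s": self.D34, "D41s": self.D41, "D13s": self.D13,
                "D24s": self.D24, "Dg": self.Dg}


@dataclass(frozen=True)
class ReferenceQuad:
    """Metric reconstruction of the four reference points, Z = 0.

    ``points`` is a (4, 3) array ordered P1 top-left (the origin), P2
    bottom-left, P3 bottom-right, P4 top-right; X rightward, Y downward.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(4, 3)
        object.__setattr__(self, "points", pts)
        if not np.allclose(pts[:, 2], 0.0, atol=1e-12):
            raise GeometryError("reference points must lie in the Z = 0 plane")
        if not np.allclose(pts[0], 0.0, atol=1e-12):
            raise GeometryError("P1 must be the origin")

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    def distances(self) -> dict:
        p = self.points

        def d(i, j):
            return float(np.linalg.norm(p[i] - p[j]))

        return {"D12": d(0, 1), "D23": d(1, 2), "D34": d(2, 3),
                "D41": d(3, 0), "D13": d(0, 2), "D24": d(1, 3)}


def reconstruct_reference_quad(geom: MachineGeometry) -> ReferenceQuad:
    """Embed the reference quadrilateral from its six measured distances.

    P1 = (0, 0); P2 lies along +Y (downward) at D12; P3 and P4 are fixed by
    the law of cosines from two distances each, with X > 0 (machine's right
    side).  The sixth distance D34 is redundant and is checked against the
    embedding within :data:`REDUNDANCY_TOL_M`.
    """
    g = geom
    P1 = np.zeros(2)
    P2 = np.array([0.0, g.D12])
    # angle at P2 in triangle P1-P2-P3 (sides D12, D23, diagonal D13)
    cos_a = (g.D12 ** 2 + g.D23 ** 2 - g.D13 ** 2) / (2 * g.D12 * g.D23)
    # angle at P1 in triangle P1-P2-P4 (sides D12, D41, diagonal D24)
    cos_b = (g.D12 ** 2 + g.D41 ** 2 - g.D24 ** 2) / (2 * g.D12 * g.D41)
    if not (-1.0 <= cos_a <= 1.0) or not (-1.0 <= cos_b <= 1.0):
        raise GeometryError("law-of-cosines embedding impossible "
                            "(check measured distances)")
    sin_a = np.sqrt(1.0 - cos_a ** 2)
    sin_b = np.sqrt(1.0 - cos_b ** 2)
    # from P2, direction to P1 is (0, -1); rotate toward +X by the angle at P2
    P3 = P2 + g.D23 * np.array([sin_a, -cos_a])
    # from P1, direction to P2 is (0, +1); rotate toward +X by the angle at P1
    P4 = P1 + g.D41 * np.array([sin_b, cos_b])

    d34 = float(np.linalg.norm(P3 - P4))
    if abs(d34 - g.D34) > REDUNDANCY_TOL_M:
        raise MeasurementInconsistencyError(
            f"redundant distance D34s inconsistent with the other five: "
            f"measured {g.D34:.4f} m, implied {d34:.4f} m "
            f"(tolerance {REDUNDANCY_TOL_M * 1000:.0f} mm)")
    pts = np.zeros((4, 3))
    pts[:, :2] = np.stack([P1, P2, P3, P4])
    return ReferenceQuad(pts)


def calibrate_structural(quad: ReferenceQuad, pixels: np.ndarray,
                         intr: CameraIntrinsics | None = None,
                         image_size: tuple[int, int] | None = None,
                         ) -> tuple[Homography, PlanePose, CameraIntrinsics, float]:
    """Estimate the structural homography and camera pose.

    ``pixels`` must be ordered to match P1..P4.  When ``intr`` is None the
    focal length is self-calibrated from the homography and the principal
    point is placed at the centre of ``image_size`` (width, height), which
    must then be given.
    Returns (Hs, pose, intrinsics, reprojection residual in px).
    """
    pixels = np.asarray(pixels, dtype=float).reshape(4, 2)
    Hs = estimate_homography(quad.xy, pixels)
    if intr is None:
        if image_size is None:
            raise CalibrationError(
                "image_size is required to self-calibrate intrinsics")
        w, h = image_size
        c_x, c_y = (w - 1) / 2.0, (h - 1) / 2.0
        f = estimate_focal_from_homography(Hs, c_x, c_y)
        intr = CameraIntrinsics(f_x=f, f_y=f, c_x=c_x, c_y=c_y,
                                width=int(w), height=int(h))
    pose = pose_from_homography(Hs, intr)
    residual = float(np.max(np.linalg.norm(Hs.apply(quad.xy) - pixels, axis=1)))
    return Hs, pose, intr, residual


def synthesize_guide_correspondences(
        quad: ReferenceQuad, geom: MachineGeometry, intr: CameraIntrinsics,
        pose: PlanePose, guide_sign: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Project virtual guide-plane points behind each reference point.

    Guide points share the in-plane coordinates of the structural points and
    sit at Z = Dg (``guide_sign=-1`` flips the offset for mirrored setups
    where the guide plane is closer to the camera).
    Returns ((4, 2) world XY on the guide plane, (4, 2) pixels).
    """
    world = quad.points.copy()
    world[:, 2] = guide_sign * geom.Dg
    try:
        pix = project_points(world, intr, pose)
    except PointBehindCameraError as exc:
        raise CalibrationError(
            f"guide plane falls behind the camera: {exc}") from exc
    return world[:, :2], pix


def calibrate_guide(guide_world: np.ndarray, guide_pixels: np.ndarray) -> Homography:
    """Fit the guide-plane homography Hg from the synthetic correspondences."""
    return estimate_homography(guide_world, guide_pixels)


@dataclass
class CalibrationResult:
    """Session calibration: computed once per camera placement, reused per frame."""

    geometry: MachineGeometry
    quad: ReferenceQuad
    intrinsics: CameraIntrinsics
    Hs: Homography
    pose: PlanePose
    Hg: Homography
    residual_px: float

    def to_json(self, path=None) -> str:
        payload = {
            "geometry": self.geometry.to_dict(),
            "quad_points_m": self.quad.points.tolist(),
            "intrinsics": {
                "f_x": self.intrinsics.f_x, "f_y": self.intrinsics.f_y,
                "c_x": self.intrinsics.c_x, "c_y": self.intrinsics.c_y,
                "skew": self.intrinsics.skew,
                "width": self.intrinsics.width, "height": self.intrinsics.height,
            },
            "Hs": self.Hs.matrix.tolist(),
            "pose": {"rotation": self.pose.rotation.tolist(),
                     "translation": self.pose.translation.tolist()},
            "Hg": self.Hg.matrix.tolist(),
            "residual_px": self.residual_px,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationResult":
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") \
            else str(source)
        data = json.loads(text)
        geom = MachineGeometry.from_dict(data["geometry"])
        return cls(
            geometry=geom,
            quad=ReferenceQuad(np.array(data["quad_points_m"])),
            intrinsics=CameraIntrinsics(**data["intrinsics"]),
            Hs=Homography(np.array(data["Hs"])),
            pose=PlanePose(np.array(data["pose"]["rotation"]),
                           np.array(data["pose"]["translation"])),
            Hg=Homography(np.array(data["Hg"])),
            residual_px=float(data["residual_px"]),
        )


def calibrate(geom: MachineGeometry, reference_pixels: np.ndarray,
              intr: CameraIntrinsics | None = None,
              image_size: tuple[int, int] | None = None,
              guide_sign: int = 1) -> CalibrationResult:
    """Full two-plane calibration from the four detected reference pixels."""
    quad = reconstruct_reference_quad(geom)
    Hs, pose, intr, residual = calibrate_structural(
        quad, reference_pixels, intr=intr, image_size=image_size)
    gw, gp = synthesize_guide_correspondences(quad, geom, intr, pose,
                                              guide_sign=guide_sign)
    Hg = calibrate_guide(gw, gp)
    return CalibrationResult(geometry=geom, quad=quad, intrinsics=intr,
                             Hs=Hs, pose=pose, Hg=Hg, residual_px=residual)
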