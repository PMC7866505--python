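"""Pinhole projection, planar homographies, and pose recovery.

The measurement principle is projective: a pinhole camera with intrinsic
matrix

    K = [[f_x, s, c_x],
         [0, f_y, c_y],
         [0,   0,   1]]

maps a scene point ``P = (X, Y, Z)`` (camera frame, metres) to homogeneous
pixel coordinates ``(a, b, c) = K P`` with image coordinates ``x = a/c``,
``y = b/c`` measured from the upper-left corner, x rightward, y downward.
Points on a known scene plane are related to their images by a 3x3
homography ``H``, estimated here by the normalized DLT.  Because the
reference plane is metric (coordinates in metres), the camera pose relative
to that plane — and a single unknown focal length — can be recovered from
``H`` alone, which is what makes unattended autocalibration possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, DegenerateViewError, PointBehindCameraError

__all__ = [
    "CameraIntrinsics",
    "PlanePose",
    "Homography",
    "project_point",
    "project_points",
    "estimate_homography",
    "estimate_focal_from_homography",
    "pose_from_homography",
    "map_pixel_to_plane",
]

_MIN_DEPTH = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixel units.

    ``f_x``/``f_y`` are focal lengths in pixels, ``(c_x, c_y)`` the principal
    point from the image upper-left corner, ``skew`` the sensor shear term
    (zero for modern smartphone sensors).
    """

    f_x: float
    f_y: float
    c_x: float
    c_y: float
    width: int
    height: int
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f_x > 0 and self.f_y > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.c_x <= self.width and 0 <= self.c_y <= self.height):
            raise ValueError("principal point must lie inside the sensor")

    @classmethod
    def simple(cls, f: float, width: int, height: int) -> "CameraIntrinsics":
        """Square pixels, zero skew, principal point at the image centre."""
        return cls(f_x=f, f_y=f, c_x=(width - 1) / 2.0, c_y=(height - 1) / 2.0,
                   width=width, height=height)

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.f_x, self.skew, self.c_x],
             [0.0, self.f_y, self.c_y],
             [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class PlanePose:
    """Rigid transform from scene (plane) coordinates to camera coordinates.

    ``X_cam = rotation @ X_scene + translation`` (translation in metres).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls, depth: float = 0.0) -> "PlanePose":
        return cls(np.eye(3), np.array([0.0, 0.0, depth]))

    @property
    def matrix(self) -> np.ndarray:
        """3x4 matrix [R | t]."""
        return np.hstack([self.rotation, self.translation.reshape(3, 1)])

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation


class Homography:
    """Invertible 3x3 projective map between a metric plane and the image.

    Normalized so ``H[2, 2] == 1`` when that entry is nonzero, else to unit
    Frobenius norm.
    """

    def __init__(self, matrix: np.ndarray):
        H = np.asarray(matrix, dtype=float).reshape(3, 3).copy()
        if abs(np.linalg.det(H)) < 1e-15:
            raise CalibrationError("homography matrix is singular")
        if abs(H[2, 2]) > 1e-12:
            H = H / H[2, 2]
        else:
            H = H / np.linalg.norm(H)
        self.matrix = H

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @property
    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) plane points to (N, 2) pixel points (or vice versa)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((pts.shape[0], 1))]) @ self.matrix.T
        w = hom[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise CalibrationError("point maps to the plane at infinity")
        out = hom[:, :2] / w[:, None]
        return out if np.asarray(points).ndim > 1 else out[0]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Homography({np.array2string(self.matrix, precision=4)})"


def project_points(points: np.ndarray, intr: CameraIntrinsics,
                   pose: PlanePose) -> np.ndarray:
    """Perspective-project scene points (N, 3) in metres to pixels (N, 2).

    Raises :class:`PointBehindCameraError` if any point has non-positive
    depth after the pose transform.
    """
    cam = pose.transform(points)
    z = cam[:, 2]
    if np.any(z <= _MIN_DEPTH):
        raise PointBehindCameraError(
            f"{int(np.sum(z <= _MIN_DEPTH))} point(s) at or behind the camera")
    hom = cam @ intr.matrix.T
    return hom[:, :2] / hom[:, 2:3]


def project_point(point, intr: CameraIntrinsics, pose: PlanePose) -> np.ndarray:
    """Project a single (X, Y, Z) scene point to an (x, y) pixel point."""
    return project_points(np.asarray(point, dtype=float).reshape(1, 3),
                          intr, pose)[0]


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform sending the centroid to 0 and RMS radius to sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    scale = np.sqrt(2.0) / rms if rms > 1e-12 else 1.0
    T = np.array([[scale, 0.0, -scale * centroid[0]],
                  [0.0, scale, -scale * centroid[1]],
                  [0.0, 0.0, 1.0]])
    return T


def estimate_homography(world_pts: np.ndarray, pixel_pts: np.ndarray) -> Homography:
    """Estimate the plane-to-image homography by the normalized DLT.

    Parameters
    ----------
    world_pts : (N, 2) plane coordinates in metres, N >= 4.
    pixel_pts : (N, 2) corresponding image points in pixels.
    """
    W = np.atleast_2d(np.asarray(world_pts, dtype=float))
    Q = np.atleast_2d(np.asarray(pixel_pts, dtype=float))
    if W.shape[0] < 4 or Q.shape[0] != W.shape[0] or W.shape[1] != 2:
        raise CalibrationError("need >= 4 matched (world, pixel) point pairs")
    if _has_collinear_triple_only(W):
        raise CalibrationError("degenerate configuration: world points collinear")
    if _has_collinear_triple_only(Q):
        raise CalibrationError("degenerate configuration: pixel points collinear")

    Tw = _hartley_normalization(W)
    Tq = _hartley_normalization(Q)
    Wn = np.hstack([W, np.ones((W.shape[0], 1))]) @ Tw.T
    Qn = np.hstack([Q, np.ones((Q.shape[0], 1))]) @ Tq.T

    n = W.shape[0]
    A = np.zeros((2 * n, 9))
    for i in range(n):
        X, Y, _ = Wn[i]
        x, y, _ = Qn[i]
        A[2 * i] = [-X, -Y, -1, 0, 0, 0, x * X, x * Y, x]
        A[2 * i + 1] = [0, 0, 0, -X, -Y, -1, y * X, y * Y, y]
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * max(s[0], 1.0):
        raise CalibrationError("degenerate configuration for DLT")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tq) @ Hn @ Tw
    return Homography(H)


def _has_collinear_triple_only(pts: np.ndarray) -> bool:
    """True for configurations that cannot support a homography fit."""
    n = pts.shape[0]
    d = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.sum(d * d, axis=-1))
    distinct = n - np.sum(np.triu(dist < 1e-9, k=1).any(axis=0))
    if distinct < 4:
        return True
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        return True
    if n == 4:
        # with a minimal set, any collinear triple is degenerate
        span = dist.max()
        for i in range(4):
            tri = pts[[j for j in range(4) if j != i]]
            u, v = tri[1] - tri[0], tri[2] - tri[0]
            area = abs(u[0] * v[1] - u[1] * v[0])
            if area < 1e-9 * max(span ** 2, 1.0):
                return True
    return False


def estimate_focal_from_homography(H: Homography, c_x: float, c_y: float) -> float:
    """Self-calibrate a single focal length from a metric-plane homography.

    With K = diag(f, f, 1) plus principal point and H ~ K [r1 r2 t], the
    orthonormality of r1, r2 gives two linear constraints on 1/f^2, combined
    by least squares.  A fronto-parallel view makes both constraints
    degenerate and raises :class:`DegenerateViewError`.
    """
    h = H.matrix
    a1, b1, c1 = h[0, 0] - c_x * h[2, 0], h[1, 0] - c_y * h[2, 0], h[2, 0]
    a2, b2, c2 = h[0, 1] - c_x * h[2, 1], h[1, 1] - c_y * h[2, 1], h[2, 1]
    # constraints:  (a1 a2 + b1 b2) u + c1 c2 = 0
    #               (a1^2 + b1^2 - a2^2 - b2^2) u + (c1^2 - c2^2) = 0,  u = 1/f^2
    A = np.array([a1 * a2 + b1 * b2,
                  (a1 ** 2 + b1 ** 2) - (a2 ** 2 + b2 ** 2)])
    b = np.array([-c1 * c2, c2 ** 2 - c1 ** 2])
    scale = np.max(np.abs(np.array([a1, b1, a2, b2]))) ** 2
    denom = float(A @ A)
    if denom < 1e-12 * scale ** 2 or scale < 1e-24:
        raise DegenerateViewError(
            "fronto-parallel view: focal length unobservable; supply camera intrinsics")
    u = float(A @ b) / denom
    if u <= 0.0:
        raise DegenerateViewError(
            "self-calibration constraints give non-positive f^2; supply intrinsics")
    return 1.0 / np.sqrt(u)


def pose_from_homography(H: Homography, intr: CameraIntrinsics) -> PlanePose:
    """Decompose a metric-plane homography into the plane pose.

    Columns of K^-1 H are proportional to (r1, r2, t); the scale is fixed so
    the mean of |r1|, |r2| is one, r3 = r1 x r2, the rotation is projected to
    the nearest orthogonal matrix (SVD), and the translation sign is chosen
    so the plane lies in front of the camera.
    """
    K = intr.matrix
    try:
        M = np.linalg.solve(K, H.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise CalibrationError("non-invertible intrinsic matrix") from exc
    m1, m2, m3 = M[:, 0], M[:, 1], M[:, 2]
    n1, n2 = np.linalg.norm(m1), np.linalg.norm(m2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise CalibrationError("degenerate homography: zero rotation column")
    lam = 2.0 / (n1 + n2)
    if (lam * m3)[2] < 0:  # plane must be in front of the camera
        lam = -lam
    r1, r2, t = lam * m1, lam * m2, lam * m3
    R0 = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(R0)
    R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    return PlanePose(R, t)


def map_pixel_to_plane(pixel, H: Homography) -> np.ndarray:
    """Map image pixels back to metric (X, Y) coordinates on the plane of H."""
    return H.inverse.apply(pixel)
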