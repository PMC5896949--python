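"""Pinhole camera back-end for metric measurement in the participant plane.

The measurement geometry is planar: the participant's medial line, the
checkerboard and the reference sheet all lie in the world plane ``z = 0``
(X rightwards, Y downwards, millimetres).  A photo is modelled by a pinhole
camera with radial/tangential lens distortion and a per-photo rigid pose
mapping plane coordinates into the camera frame.  Annotated pixels are
undistorted and back-projected along their viewing ray to the plane, after
which distances are plain 2-D Euclidean distances in millimetres.

Intrinsics are recovered from checkerboard views with Zhang's linear
closed-form method (homographies -> constraints on the image of the
absolute conic); per-photo plane poses come from decomposing the
board-to-image homography.  No nonlinear refinement is performed and
distortion coefficients are taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import ImagePoint, WorldPoint

__all__ = [
    "CameraIntrinsics",
    "DistortionCoefficients",
    "PlanePose",
    "CameraModel",
    "CameraError",
    "project",
    "project_3d",
    "undistort",
    "homography_from_correspondences",
    "pose_from_homography",
    "calibrate_intrinsics",
    "back_project_to_plane",
]


class CameraError(ValueError):
    """Raised for invalid camera configurations or degenerate geometry."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels: focal lengths, principal point, skew."""

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise CameraError(f"focal lengths must be positive (fx={self.fx}, fy={self.fy})")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, self.skew, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class DistortionCoefficients:
    """Radial (k1, k2, k3) and tangential (p1, p2) lens distortion terms."""

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.k3, self.p1, self.p2)
        if not all(np.isfinite(vals)):
            raise CameraError(f"non-finite distortion coefficients {vals}")

    @property
    def is_zero(self) -> bool:
        return self.k1 == self.k2 == self.k3 == self.p1 == self.p2 == 0.0

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Distort normalized camera coordinates (shape (..., 2))."""
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))
        xd = x * radial + 2.0 * self.p1 * x * y + self.p2 * (r2 + 2.0 * x * x)
        yd = y * radial + self.p1 * (r2 + 2.0 * y * y) + 2.0 * self.p2 * x * y
        return np.stack([xd, yd], axis=-1)


@dataclass(frozen=True)
class PlanePose:
    """Rigid transform taking plane coordinates (X, Y, 0) to the camera frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise CameraError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise CameraError("rotation matrix has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def to_camera(self, world_xyz: np.ndarray) -> np.ndarray:
        return world_xyz @ self.rotation.T + self.translation


@dataclass(frozen=True)
class CameraModel:
    """Intrinsics + distortion + per-photo plane pose."""

    intrinsics: CameraIntrinsics
    distortion: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    pose: PlanePose | None = None

    def _require_pose(self) -> PlanePose:
        if self.pose is None:
            raise CameraError("operation requires a per-photo plane pose")
        return self.pose


def project_3d(world_xyz: Sequence[float], cam: CameraModel) -> ImagePoint:
    """Project an arbitrary 3-D world point (z may be nonzero) to distorted pixels.

    Raises :class:`CameraError` when the point is at or behind the camera.
    """
    pose = cam._require_pose()
    pc = pose.to_camera(np.asarray(world_xyz, dtype=float))
    if pc[2] <= 1e-9:
        raise CameraError(f"point {world_xyz} has non-positive depth {pc[2]:.3g}")
    xy = pc[:2] / pc[2]
    xyd = cam.distortion.apply(xy)
    K = cam.intrinsics
    u = K.fx * xyd[0] + K.skew * xyd[1] + K.cx
    v = K.fy * xyd[1] + K.cy
    return ImagePoint(float(u), float(v))


def project(world: WorldPoint, cam: CameraModel) -> ImagePoint:
    """Project a participant-plane point (z = 0) to distorted pixel coordinates."""
    return project_3d([world.x, world.y, 0.0], cam)


def _pixel_to_normalized(p: ImagePoint, K: CameraIntrinsics) -> np.ndarray:
    y = (p.y - K.cy) / K.fy
    x = (p.x - K.cx - K.skew * y) / K.fx
    return np.array([x, y])


def undistort(
    p: ImagePoint, cam: CameraModel, *, tol: float = 1e-10, max_iter: int = 50
) -> ImagePoint:
    """Remove lens distortion from a pixel point.

    Inverts the distortion model by fixed-point iteration on normalized
    coordinates (x <- (xd - tangential(x)) / radial(x)), then re-applies
    the intrinsics.  Raises :class:`CameraError` on non-convergence.
    """
    if cam.distortion.is_zero:
        return p
    xyd = _pixel_to_normalized(p, cam.intrinsics)
    d = cam.distortion
    xy = xyd.copy()
    for _ in range(max_iter):
        x, y = xy
        r2 = x * x + y * y
        radial = 1.0 + r2 * (d.k1 + r2 * (d.k2 + r2 * d.k3))
        dx = 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
        dy = d.p1 * (r2 + 2.0 * y * y) + 2.0 * d.p2 * x * y
        xy_new = (xyd - np.array([dx, dy])) / radial
        if np.max(np.abs(xy_new - xy)) < tol:
            xy = xy_new
            break
        xy = xy_new
    else:
        raise CameraError(f"undistortion did not converge for pixel {p}")
    K = cam.intrinsics
    u = K.fx * xy[0] + K.skew * xy[1] + K.cx
    v = K.fy * xy[1] + K.cy
    return ImagePoint(float(u), float(v))


def _hartley_normalization(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform sending the points to centroid 0, RMS distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if rms < 1e-12:
        raise CameraError("degenerate correspondence set (all points coincide)")
    s = np.sqrt(2.0) / rms
    T = np.array([[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]])
    homog = np.column_stack([pts, np.ones(len(pts))])
    return (homog @ T.T)[:, :2], T


def homography_from_correspondences(
    pairs: Sequence[tuple[WorldPoint, ImagePoint]],
) -> np.ndarray:
    """DLT estimate of the plane-to-image homography, with Hartley normalization.

    Needs at least four non-collinear correspondences; image points should
    be undistorted beforehand.  The result is scaled to H[2, 2] = 1.
    """
    if len(pairs) < 4:
        raise CameraError(f"need >= 4 correspondences, got {len(pairs)}")
    w = np.array([[p.x, p.y] for p, _ in pairs], dtype=float)
    im = np.array([[q.x, q.y] for _, q in pairs], dtype=float)
    wn, Tw = _hartley_normalization(w)
    imn, Ti = _hartley_normalization(im)
    A = np.zeros((2 * len(pairs), 9))
    for i, ((X, Y), (u, v)) in enumerate(zip(wn, imn)):
        A[2 * i] = [-X, -Y, -1, 0, 0, 0, u * X, u * Y, u]
        A[2 * i + 1] = [0, 0, 0, -X, -Y, -1, v * X, v * Y, v]
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-9 * sv[0]:
        raise CameraError("degenerate configuration: correspondences are rank-deficient")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Ti) @ Hn @ Tw
    if abs(H[2, 2]) < 1e-12:
        raise CameraError("ill-conditioned homography (vanishing scale)")
    return H / H[2, 2]


def pose_from_homography(H: np.ndarray, intr: CameraIntrinsics) -> PlanePose:
    """Zhang-style decomposition of a plane homography into a rigid pose.

    With K the intrinsic matrix, H ~ K [r1 r2 t]; the rotation is completed
    by r3 = r1 x r2 and re-orthonormalized by SVD.  The sign is fixed so the
    plane sits in front of the camera (positive depth).
    """
    M = np.linalg.inv(intr.matrix) @ np.asarray(H, dtype=float)
    lam = 1.0 / np.linalg.norm(M[:, 0])
    if M[2, 2] * lam < 0:  # plane origin must have positive depth
        lam = -lam
    r1, r2, t = lam * M[:, 0], lam * M[:, 1], lam * M[:, 2]
    R = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    if t[2] <= 0:
        raise CameraError("decomposed pose places the plane behind the camera")
    return PlanePose(R, t)


def calibrate_intrinsics(
    views: Sequence[Sequence[tuple[WorldPoint, ImagePoint]]],
) -> CameraIntrinsics:
    """Zhang's linear closed-form intrinsic calibration from plane views.

    Each view is a set of board-to-image correspondences (distortion-free
    or pre-undistorted).  Homographies give two constraints per view on
    B = K^-T K^-1; the intrinsics are read off the null-space solution.
    Requires at least three views in genuinely distinct orientations.
    """
    if len(views) < 3:
        raise CameraError(f"need >= 3 checkerboard views, got {len(views)}")
    Hs = [homography_from_correspondences(v) for v in views]

    def vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
        return np.array(
            [
                H[0, i] * H[0, j],
                H[0, i] * H[1, j] + H[1, i] * H[0, j],
                H[1, i] * H[1, j],
                H[2, i] * H[0, j] + H[0, i] * H[2, j],
                H[2, i] * H[1, j] + H[1, i] * H[2, j],
                H[2, i] * H[2, j],
            ]
        )

    V = np.vstack([np.stack([vij(H, 0, 1), vij(H, 0, 0) - vij(H, 1, 1)]) for H in Hs])
    _, sv, Vt = np.linalg.svd(V)
    # a well-posed problem determines the conic up to scale: rank must be 5
    if sv[4] < 1e-8 * sv[0]:
        raise CameraError("ill-conditioned calibration: views are not in distinct orientations")
    b11, b12, b22, b13, b23, b33 = Vt[-1]
    denom = b11 * b22 - b12 * b12
    if abs(denom) < 1e-16 * max(abs(b11 * b22), 1e-30):
        raise CameraError("ill-conditioned calibration: views are not in distinct orientations")
    cy = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13 * b13 + cy * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0:
        raise CameraError("ill-conditioned calibration (negative focal-length estimate)")
    fx = np.sqrt(lam / b11)
    fy_sq = lam * b11 / denom
    if fy_sq <= 0:
        raise CameraError("ill-conditioned calibration (negative focal-length estimate)")
    fy = np.sqrt(fy_sq)
    skew = -b12 * fx * fx * fy / lam
    cx = skew * cy / fy - b13 * fx * fx / lam
    return CameraIntrinsics(float(fx), float(fy), float(cx), float(cy), float(skew))


def back_project_to_plane(p: ImagePoint, cam: CameraModel) -> WorldPoint:
    """Intersect the viewing ray of an undistorted pixel with the plane z = 0.

    Implemented by inverting the plane-to-image homography K [r1 r2 t], so a
    point that was projected with zero distortion round-trips exactly.
    Raises :class:`CameraError` when the ray is (numerically) parallel to
    the plane.
    """
    pose = cam._require_pose()
    H = cam.intrinsics.matrix @ np.column_stack(
        [pose.rotation[:, 0], pose.rotation[:, 1], pose.translation]
    )
    sv = np.linalg.svd(H, compute_uv=False)
    if sv[2] < 1e-12 * sv[0]:
        raise CameraError("camera views the participant plane edge-on (singular homography)")
    uv1 = np.array([p.x, p.y, 1.0])
    w = np.linalg.solve(H, uv1)
    if abs(w[2]) < 1e-9 * np.linalg.norm(w):
        raise CameraError(f"viewing ray of {p} is parallel to the participant plane")
    return WorldPoint(float(w[0] / w[2]), float(w[1] / w[2]))
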