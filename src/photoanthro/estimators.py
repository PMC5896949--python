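"""Per-photo measurement extraction and the closed-form estimators.

From one annotated photo the pipeline extracts up to three quantities, via
either metric back-end (camera calibration or reference object):

* ``H_LD`` — linear-distance height: Euclidean distance from the head
  landmark to its perpendicular foot on the floor line (the line through
  the two bottom corners of the checkerboard sheet).
* ``H_BB`` — bounding-box height: mean of the two vertical side lengths
  ``(d_AC + d_BD) / 2`` of the box enclosing the silhouette.
* ``r`` — mid-upper-arm radius: half the distance between the two
  annotated arm-edge markers.

MUAC is then estimated from radii by one of three cross-section shape
models: a circle (``2 pi r``), an ellipse with the two radii as semi-axes
(Ramanujan's first perimeter approximation), or an ellipse-rectangle mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from .camera import CameraModel, back_project_to_plane, undistort
from .geometry import ImagePoint, euclidean, line_through, project_point_to_line
from .refscale import ReferenceObject, distance_mm

__all__ = [
    "Backend",
    "ArmSide",
    "PhotoAnnotation",
    "MeasurementRecord",
    "MeasurementError",
    "height_linear_distance",
    "height_bounding_box",
    "arm_radius",
    "muac_circle",
    "muac_ellipse",
    "muac_mix",
    "measure_photo",
]

Backend = Literal["calibration", "reference"]
ArmSide = Literal["left", "right", "both"]

VIEWS = (1, 2, 3, 4, 5)
#: Views in which both arms are unobstructed in a single photo (front, back).
BOTH_ARM_VIEWS = (1, 5)


class MeasurementError(ValueError):
    """Raised for missing landmarks or invalid measurement results."""


@dataclass(frozen=True)
class PhotoAnnotation:
    """All manually marked landmarks of one photo plus its identity.

    ``arm_side`` declares which arms are unobstructed: views 1 and 5 show
    ``both``, views 2-4 are captured twice, once per arm.  ``arm_edges``
    maps each visible arm to its pair of edge markers.  All image points
    are in original (distorted) pixel coordinates; the calibration
    back-end undistorts them internally.
    """

    participant_id: str
    session_id: int
    view: int
    arm_side: ArmSide
    head: Optional[ImagePoint] = None
    floor_pts: Optional[tuple[ImagePoint, ImagePoint]] = None
    bbox: Optional[tuple[ImagePoint, ImagePoint, ImagePoint, ImagePoint]] = None
    arm_edges: dict[str, tuple[ImagePoint, ImagePoint]] = field(default_factory=dict)
    reference: Optional[ReferenceObject] = None
    camera: Optional[CameraModel] = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise MeasurementError(f"view must be in {VIEWS}, got {self.view}")
        if self.bbox is not None:
            a, b, c, d = self.bbox
            if not (a.y < c.y and b.y < d.y):
                raise MeasurementError("bounding box top edge must lie above its bottom edge")
        sides = ("left", "right") if self.arm_side == "both" else (self.arm_side,)
        for side in sides:
            if self.arm_edges and side not in self.arm_edges:
                raise MeasurementError(
                    f"arm_side declares {side!r} visible but arm_edges has no entry for it"
                )

    @property
    def visible_arms(self) -> tuple[str, ...]:
        return ("left", "right") if self.arm_side == "both" else (self.arm_side,)


@dataclass(frozen=True)
class MeasurementRecord:
    """Flat per-photo, per-backend measurement row (all values in mm)."""

    participant_id: str
    session_id: int
    view: int
    backend: Backend
    H_LD: Optional[float] = None
    H_BB: Optional[float] = None
    r_left: Optional[float] = None
    r_right: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("H_LD", "H_BB", "r_left", "r_right"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise MeasurementError(f"{name} must be finite and positive, got {v}")


def _require(annotation: PhotoAnnotation, attr: str):
    value = getattr(annotation, attr)
    if value is None:
        raise MeasurementError(f"annotation for photo {annotation.participant_id}/"
                               f"s{annotation.session_id}/v{annotation.view} lacks {attr!r}")
    return value


def _require_camera(a: PhotoAnnotation) -> CameraModel:
    cam = a.camera
    if cam is None:
        raise MeasurementError("calibration backend requires a camera model on the annotation")
    return cam


def _require_reference(a: PhotoAnnotation) -> ReferenceObject:
    if a.reference is None:
        raise MeasurementError("reference backend requires reference-object corners")
    return a.reference


def height_linear_distance(a: PhotoAnnotation, backend: Backend) -> float:
    """Height as distance from the head point to the extrapolated floor line.

    Calibration: head and floor points are undistorted and back-projected
    to the participant plane; the perpendicular distance is metric
    directly.  Reference: the perpendicular foot is found in pixel space
    and the pixel segment converted via the reference sheet.
    """
    head = _require(a, "head")
    f1, f2 = _require(a, "floor_pts")
    if backend == "calibration":
        cam = _require_camera(a)
        hw, f1w, f2w = (
            back_project_to_plane(undistort(p, cam), cam) for p in (head, f1, f2)
        )
        foot = project_point_to_line(hw, line_through(f1w, f2w))
        return euclidean(hw, foot)
    ref = _require_reference(a)
    foot_px = project_point_to_line(head, line_through(f1, f2))
    return distance_mm(head, foot_px, ref)


def height_bounding_box(a: PhotoAnnotation, backend: Backend) -> float:
    """Bounding-box height ``(d_AC + d_BD) / 2`` via the chosen back-end.

    In pixel space the two sides of an axis-aligned box are equal; the
    reference back-end still converts both and averages, which matters
    when the sheet scale differs between the two abscissae.
    """
    A, B, C, D = _require(a, "bbox")
    if backend == "calibration":
        cam = _require_camera(a)
        Aw, Bw, Cw, Dw = (back_project_to_plane(undistort(p, cam), cam) for p in (A, B, C, D))
        return (euclidean(Aw, Cw) + euclidean(Bw, Dw)) / 2.0
    ref = _require_reference(a)
    return (distance_mm(A, C, ref) + distance_mm(B, D, ref)) / 2.0


def arm_radius(a: PhotoAnnotation, side: str, backend: Backend) -> float:
    """Mid-upper-arm radius: half the metric distance between the edge markers."""
    if side not in a.arm_edges:
        raise MeasurementError(
            f"no arm-edge pair for side {side!r} in photo {a.participant_id}/"
            f"s{a.session_id}/v{a.view}"
        )
    e1, e2 = a.arm_edges[side]
    if backend == "calibration":
        cam = _require_camera(a)
        w1 = back_project_to_plane(undistort(e1, cam), cam)
        w2 = back_project_to_plane(undistort(e2, cam), cam)
        return euclidean(w1, w2) / 2.0
    ref = _require_reference(a)
    return distance_mm(e1, e2, ref) / 2.0


def _check_radius(*radii: float) -> None:
    for r in radii:
        if not (math.isfinite(r) and r > 0):
            raise MeasurementError(f"arm radius must be finite and positive, got {r}")


def muac_circle(r_i: float) -> float:
    """Circle model: MUAC = 2 pi r."""
    _check_radius(r_i)
    return 2.0 * math.pi * r_i


def muac_ellipse(r_i: float, r_j: float) -> float:
    """Ellipse model: Ramanujan's first perimeter approximation.

    The two radii (from two views of the same arm) are the semi-axes:
    ``pi * (3(r_i + r_j) - sqrt((r_i + 3 r_j)(3 r_i + r_j)))``.  Exact for
    a circle; relative error well below 0.1% for moderate eccentricity.
    """
    _check_radius(r_i, r_j)
    return math.pi * (3.0 * (r_i + r_j) - math.sqrt((r_i + 3.0 * r_j) * (3.0 * r_i + r_j)))


def muac_mix(r_i: float, r_j: float) -> float:
    """Ellipse-rectangle mix: ``2(r_i + r_j) + muac_ellipse(r_i, r_j) / 2``."""
    _check_radius(r_i, r_j)
    return 2.0 * (r_i + r_j) + muac_ellipse(r_i, r_j) / 2.0


def measure_photo(a: PhotoAnnotation, backend: Backend) -> MeasurementRecord:
    """Extract every available measurement from one annotated photo.

    Quantities whose landmarks are absent are left as None; present but
    invalid (non-finite / non-positive) results raise so that evaluation
    tables can never silently contain bad rows.
    """
    h_ld = height_linear_distance(a, backend) if (a.head and a.floor_pts) else None
    h_bb = height_bounding_box(a, backend) if a.bbox else None
    radii = {}
    for side in a.visible_arms:
        if side in a.arm_edges:
            radii[side] = arm_radius(a, side, backend)
    return MeasurementRecord(
        participant_id=a.participant_id,
        session_id=a.session_id,
        view=a.view,
        backend=backend,
        H_LD=h_ld,
        H_BB=h_bb,
        r_left=radii.get("left"),
        r_right=radii.get("right"),
    )
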