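"""Synthetic capture sessions with fully known ground truth.

The generator emulates the study conditions end to end: a cohort of
participants with heights ~ N(1706.5, 89.1^2) mm and MUAC targets
~ N(292, 38^2) mm, photographed from five relative orientations (0, 45,
90, 135, 180 degrees) at three camera-subject distances around 3.1-3.4 m
with the camera about 1.125 m above the floor.  The participant's medial
plane coincides with the plane of a 7x10-square (90 mm) checkerboard
printed on an 840 x 1186 mm sheet whose bottom edge rests on the floor.

Each photo yields an exact landmark annotation (noise-free projections
through the session camera, including lens distortion) and a noisy copy
with i.i.d. Gaussian pixel noise on every annotated coordinate, plus the
camera model, so every estimator and the full evaluation sweep can be run
against known truth.  Three deliberate, view-dependent effects give the
multi-view regression something real to correct:

* the mid-upper arm cross-section is an ellipse of a-priori unknown
  orientation, so its silhouette half-width is the ellipse support
  function of the viewing angle;
* the feet protrude towards the camera by a view-dependent amount, so the
  bounding-box bottom edge sits below the floor line in the image;
* when repositioning for each view the subject stands slightly off the
  board plane (towards the camera) by a view-dependent typical amount,
  which inflates every subject-borne distance by roughly offset/distance.

The exact annotations use the idealized in-plane geometry; the noisy
copies include both the plane misalignment and the pixel noise.

"Manual" reference measurements are simulated as truth plus Gaussian
repeat noise whose scale matches the study's manual TEMs (2.24 mm for
height, 3.76 mm for MUAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .camera import CameraIntrinsics, CameraModel, DistortionCoefficients, PlanePose, project_3d
from .estimators import PhotoAnnotation
from .geometry import ImagePoint
from .refscale import ReferenceObject
from .regression_eval import ManualMeasurements

__all__ = [
    "SyntheticParticipant",
    "SceneConfig",
    "PhotoRecord",
    "GroundTruthBundle",
    "apparent_arm_radius",
    "support_half_width",
    "true_ellipse_perimeter",
    "generate_bundle",
]

#: Idealized participant orientation per view, radians.
VIEW_ANGLES = {1: 0.0, 2: math.pi / 4, 3: math.pi / 2, 4: 3 * math.pi / 4, 5: math.pi}


def true_ellipse_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by adaptive quadrature of the arc-length integral.

    Serves as the independent oracle for the closed-form shape models;
    relative tolerance ~1e-12.
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"semi-axes must be positive, got ({a}, {b})")
    integrand = lambda t: math.sqrt(a * a * math.sin(t) ** 2 + b * b * math.cos(t) ** 2)
    val, _ = quad(integrand, 0.0, math.pi / 2, epsabs=1e-12, epsrel=1e-12, limit=200)
    return 4.0 * val


def support_half_width(a: float, b: float, angle: float) -> float:
    """Silhouette half-width of an ellipse viewed from direction ``angle``.

    For semi-axes a >= b with the major axis at angle 0, the support
    function is ``sqrt(a^2 sin^2(angle) + b^2 cos^2(angle))``: viewing
    along the major axis shows the minor semi-axis and vice versa.
    """
    s, c = math.sin(angle), math.cos(angle)
    return math.sqrt(a * a * s * s + b * b * c * c)


def apparent_arm_radius(semi_axes: tuple[float, float], azimuth: float, view: int) -> float:
    """Half-width of the arm silhouette for one of the five idealized views."""
    a, b = semi_axes
    if not (a >= b > 0):
        raise ValueError(f"semi-axes must satisfy a >= b > 0, got ({a}, {b})")
    return support_half_width(a, b, VIEW_ANGLES[view] - azimuth)


@dataclass(frozen=True)
class SyntheticParticipant:
    """Ground-truth body parameters of one simulated participant."""

    participant_id: str
    true_height: float
    arm_semi_axes: dict[str, tuple[float, float]]
    arm_azimuth: dict[str, float]
    foot_forward_extent: float
    true_muac: dict[str, float]

    def __post_init__(self) -> None:
        for side, (a, b) in self.arm_semi_axes.items():
            if not (a >= b > 0):
                raise ValueError(f"{side} arm semi-axes must satisfy a >= b > 0, got ({a}, {b})")
            m = self.true_muac[side]
            if not (2 * math.pi * b - 1e-6 <= m <= 2 * math.pi * a + 1e-6):
                raise ValueError(f"{side} MUAC {m:.1f} outside [2*pi*b, 2*pi*a]")


@dataclass(frozen=True)
class SceneConfig:
    """Generator configuration; defaults reproduce the study conditions."""

    n_participants: int = 31
    n_sessions: int = 3
    seed: int = 0
    # population (mm)
    height_mean_mm: float = 1706.5
    height_sd_mm: float = 89.1
    height_range_mm: tuple[float, float] = (1450.0, 1950.0)
    muac_mean_mm: float = 292.0
    muac_sd_mm: float = 38.0
    muac_range_mm: tuple[float, float] = (200.0, 400.0)
    arm_asymmetry_sd_mm: float = 5.0
    axis_ratio_range: tuple[float, float] = (1.0, 1.5)
    arm_azimuth_max_rad: float = math.pi / 2
    foot_extent_mean_mm: float = 120.0
    foot_extent_sd_mm: float = 20.0
    bbox_half_width_mm: float = 250.0
    arm_offset_mm: float = 180.0
    arm_height_fraction: float = 0.72
    # capture geometry (mm / rad)
    camera_distances_mm: tuple[float, ...] = (3390.0, 3250.0, 3120.0)
    camera_distance_jitter_mm: float = 100.0
    camera_height_mm: float = 1125.0
    camera_height_jitter_mm: float = 30.0
    aim_jitter_mm: float = 50.0
    view_jitter_rad: float = math.radians(3.0)
    # subject-plane misalignment: when repositioning for each view the
    # participant tends to stand slightly in front of the board plane
    # (towards the camera), by a view-dependent typical amount plus
    # per-photo variation; applied to the noisy annotations only.
    plane_offset_view_mm: tuple[float, float, float, float, float] = (20.0, 35.0, 25.0, 40.0, 30.0)
    plane_offset_sd_mm: float = 10.0
    participant_offset_mm: float = 755.0  # medial line right of the board origin
    # board / reference sheet (mm)
    checkerboard_cols: int = 7
    checkerboard_rows: int = 10
    square_mm: float = 90.0
    sheet_width_mm: float = 840.0
    sheet_height_mm: float = 1186.0
    # camera model
    image_size_px: tuple[int, int] = (4000, 3000)
    fx_px: float = 3240.0
    fy_px: float = 3240.0
    distortion: DistortionCoefficients = field(
        default_factory=lambda: DistortionCoefficients(k1=-0.05, k2=0.01, p1=1e-4, p2=-1e-4)
    )
    # noise
    annotation_noise_px: float = 2.0
    manual_noise_height_mm: float = 2.24
    manual_noise_muac_mm: float = 3.76
    n_manual_repeats: int = 3

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_sessions < 1:
            raise ValueError("need at least one participant and one session")
        if self.annotation_noise_px < 0 or self.manual_noise_height_mm < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def intrinsics(self) -> CameraIntrinsics:
        w, h = self.image_size_px
        return CameraIntrinsics(self.fx_px, self.fy_px, w / 2.0, h / 2.0)


@dataclass(frozen=True)
class PhotoRecord:
    """One simulated photo: exact and noisy annotations plus ground truth."""

    exact: PhotoAnnotation
    noisy: PhotoAnnotation
    camera: CameraModel
    true_height: float
    true_radii: dict[str, float]


@dataclass(frozen=True)
class GroundTruthBundle:
    """Everything the evaluation pipeline needs, with full ground truth."""

    config: SceneConfig
    participants: tuple[SyntheticParticipant, ...]
    photos: tuple[PhotoRecord, ...]
    manual: ManualMeasurements

    def annotations(self, noisy: bool = True) -> list[PhotoAnnotation]:
        return [p.noisy if noisy else p.exact for p in self.photos]

    def true_heights(self) -> dict[str, float]:
        return {p.participant_id: p.true_height for p in self.participants}

    def true_muacs(self) -> dict[tuple[str, str], float]:
        return {
            (p.participant_id, side): m
            for p in self.participants
            for side, m in p.true_muac.items()
        }


# ---------------------------------------------------------------------------
# scene geometry


@dataclass(frozen=True)
class _SceneFrame:
    """Fixed world-frame coordinates derived from the board and sheet sizes.

    World origin is the board's top-left inner corner, X rightwards along
    the top edge, Y downwards, mm; the sheet is centred on the board.
    """

    sheet_tl: tuple[float, float]
    sheet_tr: tuple[float, float]
    sheet_bl: tuple[float, float]
    sheet_br: tuple[float, float]
    floor_y: float


def _scene_frame(cfg: SceneConfig) -> _SceneFrame:
    board_w = cfg.checkerboard_cols * cfg.square_mm
    board_h = cfg.checkerboard_rows * cfg.square_mm
    margin_x = (cfg.sheet_width_mm - board_w) / 2.0
    margin_y = (cfg.sheet_height_mm - board_h) / 2.0
    if margin_x < 0 or margin_y < 0:
        raise ValueError("checkerboard does not fit on the reference sheet")
    # board outer top-left is one square up/left of the inner-corner origin
    tl_x = -(margin_x + cfg.square_mm)
    tl_y = -(margin_y + cfg.square_mm)
    return _SceneFrame(
        sheet_tl=(tl_x, tl_y),
        sheet_tr=(tl_x + cfg.sheet_width_mm, tl_y),
        sheet_bl=(tl_x, tl_y + cfg.sheet_height_mm),
        sheet_br=(tl_x + cfg.sheet_width_mm, tl_y + cfg.sheet_height_mm),
        floor_y=tl_y + cfg.sheet_height_mm,
    )


def _look_at_pose(center: np.ndarray, target: np.ndarray) -> PlanePose:
    """Camera pose looking from ``center`` to ``target``, image y downwards."""
    f = target - center
    f = f / np.linalg.norm(f)
    y_hint = np.array([0.0, 1.0, 0.0])  # world y is down
    x_axis = np.cross(y_hint, f)
    x_axis = x_axis / np.linalg.norm(x_axis)
    y_axis = np.cross(f, x_axis)
    R = np.vstack([x_axis, y_axis, f])
    return PlanePose(R, -R @ center)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    raise RuntimeError("truncated normal sampling failed (bounds too tight)")


def _draw_participant(rng: np.random.Generator, cfg: SceneConfig, idx: int) -> SyntheticParticipant:
    height = _truncated_normal(rng, cfg.height_mean_mm, cfg.height_sd_mm, *cfg.height_range_mm)
    base_muac = _truncated_normal(rng, cfg.muac_mean_mm, cfg.muac_sd_mm, *cfg.muac_range_mm)
    semi_axes, azimuths, muacs = {}, {}, {}
    for side in ("left", "right"):
        m = float(
            np.clip(base_muac + rng.normal(0.0, cfg.arm_asymmetry_sd_mm), *cfg.muac_range_mm)
        )
        q = rng.uniform(*cfg.axis_ratio_range)
        a = m / true_ellipse_perimeter(1.0, 1.0 / q)  # perimeter scales linearly
        semi_axes[side] = (a, a / q)
        azimuths[side] = rng.uniform(-cfg.arm_azimuth_max_rad, cfg.arm_azimuth_max_rad)
        muacs[side] = m
    foot = max(10.0, rng.normal(cfg.foot_extent_mean_mm, cfg.foot_extent_sd_mm))
    return SyntheticParticipant(
        participant_id=f"P{idx:03d}",
        true_height=height,
        arm_semi_axes=semi_axes,
        arm_azimuth=azimuths,
        foot_forward_extent=foot,
        true_muac=muacs,
    )


def _noisy_point(p: ImagePoint, rng: np.random.Generator, sigma: float) -> ImagePoint:
    if sigma == 0:
        return p
    return ImagePoint(p.x + rng.normal(0.0, sigma), p.y + rng.normal(0.0, sigma))


def _perturb_annotation(
    a: PhotoAnnotation, rng: np.random.Generator, sigma: float
) -> PhotoAnnotation:
    np_ = lambda p: _noisy_point(p, rng, sigma)
    ref = a.reference
    return replace(
        a,
        head=np_(a.head),
        floor_pts=(np_(a.floor_pts[0]), np_(a.floor_pts[1])),
        bbox=tuple(np_(p) for p in a.bbox),
        arm_edges={s: (np_(e1), np_(e2)) for s, (e1, e2) in a.arm_edges.items()},
        reference=ReferenceObject(
            np_(ref.tl), np_(ref.tr), np_(ref.bl), np_(ref.br), ref.width_mm, ref.height_mm
        ),
    )


def _make_photo(
    part: SyntheticParticipant,
    cfg: SceneConfig,
    frame: _SceneFrame,
    cam: CameraModel,
    session: int,
    view: int,
    arm_side: str,
    theta: float,
    rng: np.random.Generator,
) -> PhotoRecord:
    x_p = cfg.participant_offset_mm
    floor_y = frame.floor_y

    def build(dz: float) -> tuple[PhotoAnnotation, dict[str, float]]:
        """Annotation with the subject's medial plane at z = -dz (towards camera)."""
        proj = lambda xy: project_3d([xy[0], xy[1], 0.0], cam)
        subj = lambda xy: project_3d([xy[0], xy[1], -dz], cam)
        head_px = subj((x_p, floor_y - part.true_height))
        floor_px = (proj(frame.sheet_bl), proj(frame.sheet_br))
        ref = ReferenceObject(
            proj(frame.sheet_tl),
            proj(frame.sheet_tr),
            proj(frame.sheet_bl),
            proj(frame.sheet_br),
            cfg.sheet_width_mm,
            cfg.sheet_height_mm,
        )
        # bounding box: top edge through the head, bottom edge through the
        # image of the forward-most foot point (off-plane, so it appears
        # below the floor line); left/right edges at the silhouette extremes.
        foot_extent = part.foot_forward_extent * abs(math.cos(theta))
        foot_px = project_3d([x_p, floor_y, -(dz + foot_extent)], cam)
        y_mid = floor_y - part.true_height / 2.0
        left_px = subj((x_p - cfg.bbox_half_width_mm, y_mid))
        right_px = subj((x_p + cfg.bbox_half_width_mm, y_mid))
        bbox = (
            ImagePoint(left_px.x, head_px.y),
            ImagePoint(right_px.x, head_px.y),
            ImagePoint(left_px.x, foot_px.y),
            ImagePoint(right_px.x, foot_px.y),
        )
        sides = ("left", "right") if arm_side == "both" else (arm_side,)
        y_arm = floor_y - cfg.arm_height_fraction * part.true_height
        arm_edges, radii = {}, {}
        for side in sides:
            a, b = part.arm_semi_axes[side]
            w = support_half_width(a, b, theta - part.arm_azimuth[side])
            x_arm = x_p + (-cfg.arm_offset_mm if side == "left" else cfg.arm_offset_mm)
            arm_edges[side] = (subj((x_arm - w, y_arm)), subj((x_arm + w, y_arm)))
            radii[side] = w
        annotation = PhotoAnnotation(
            participant_id=part.participant_id,
            session_id=session,
            view=view,
            arm_side=arm_side,
            head=head_px,
            floor_pts=floor_px,
            bbox=bbox,
            arm_edges=arm_edges,
            reference=ref,
            camera=cam,
        )
        return annotation, radii

    exact, true_radii = build(0.0)
    dz = cfg.plane_offset_view_mm[view - 1] + rng.normal(0.0, cfg.plane_offset_sd_mm)
    offset_annotation, _ = build(dz)
    noisy = _perturb_annotation(offset_annotation, rng, cfg.annotation_noise_px)
    return PhotoRecord(exact, noisy, cam, part.true_height, true_radii)


def generate_bundle(cfg: Optional[SceneConfig] = None) -> GroundTruthBundle:
    """Generate a full synthetic study: photos, cameras, manual repeats.

    Deterministic for a fixed config (including its seed).  With the
    defaults this yields 31 participants x 3 sessions x 8 photos = 744
    photo annotations: views 1 and 5 show both arms in a single photo,
    views 2-4 are captured twice, once per arm side.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    frame = _scene_frame(cfg)
    participants = tuple(_draw_participant(rng, cfg, i) for i in range(cfg.n_participants))

    sheet_center_x = (frame.sheet_tl[0] + frame.sheet_tr[0]) / 2.0
    # frame both the board and the participant: aim midway between them
    scene_center_x = (sheet_center_x + cfg.participant_offset_mm) / 2.0
    photos: list[PhotoRecord] = []
    manual = ManualMeasurements()
    for part in participants:
        for s in range(cfg.n_sessions):
            session = s + 1
            distance = cfg.camera_distances_mm[s % len(cfg.camera_distances_mm)] + rng.normal(
                0.0, cfg.camera_distance_jitter_mm
            )
            cam_height = cfg.camera_height_mm + rng.normal(0.0, cfg.camera_height_jitter_mm)
            center = np.array([scene_center_x, frame.floor_y - cam_height, -abs(distance)])
            target = np.array(
                [
                    scene_center_x + rng.normal(0.0, cfg.aim_jitter_mm),
                    frame.floor_y - part.true_height / 2.0 + rng.normal(0.0, cfg.aim_jitter_mm),
                    0.0,
                ]
            )
            cam = CameraModel(cfg.intrinsics, cfg.distortion, _look_at_pose(center, target))
            for view in (1, 2, 3, 4, 5):
                arm_list = ("both",) if view in (1, 5) else ("left", "right")
                for arm_side in arm_list:
                    theta = VIEW_ANGLES[view] + rng.uniform(
                        -cfg.view_jitter_rad, cfg.view_jitter_rad
                    )
                    photos.append(
                        _make_photo(part, cfg, frame, cam, session, view, arm_side, theta, rng)
                    )
        manual.height[part.participant_id] = [
            part.true_height + rng.normal(0.0, cfg.manual_noise_height_mm)
            for _ in range(cfg.n_manual_repeats)
        ]
        for side in ("left", "right"):
            manual.muac[(part.participant_id, side)] = [
                part.true_muac[side] + rng.normal(0.0, cfg.manual_noise_muac_mm)
                for _ in range(cfg.n_manual_repeats)
            ]
    return GroundTruthBundle(cfg, participants, tuple(photos), manual)
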