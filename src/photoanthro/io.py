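"""File formats: annotation JSON, camera parameter YAML, CSV tables.

Annotations are serialized as versioned, strictly validated JSON (unknown
or missing fields are rejected with messages naming the field and schema
version).  Flat tables (measurement records, manual measurements,
evaluation tables) are CSV with explicit units in the column names and a
``#``-prefixed provenance header.  Coordinates are always pixels, lengths
always millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .camera import CameraIntrinsics, CameraModel, DistortionCoefficients, PlanePose
from .estimators import MeasurementRecord, PhotoAnnotation
from .geometry import ImagePoint
from .refscale import ReferenceObject
from .regression_eval import ManualMeasurements

__all__ = [
    "SCHEMA_VERSION",
    "FormatError",
    "read_annotations",
    "write_annotations",
    "read_camera_file",
    "write_camera_file",
    "read_manual_measurements",
    "write_manual_measurements",
    "read_measurement_records",
    "write_measurement_records",
    "write_evaluation_table",
    "photo_key",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed or schema-violating input files."""


def photo_key(participant_id: str, session_id: int, view: int, arm_side: str) -> str:
    """Stable identifier of one photo, also used to key camera poses."""
    return f"{participant_id}/s{session_id}/v{view}/{arm_side}"


# ---------------------------------------------------------------------------
# annotation JSON


def _point_out(p: ImagePoint) -> list[float]:
    return [p.x, p.y]


def _point_in(obj, where: str) -> ImagePoint:
    if not (isinstance(obj, (list, tuple)) and len(obj) == 2):
        raise FormatError(f"{where}: expected [x, y], got {obj!r}")
    return ImagePoint(float(obj[0]), float(obj[1]))


_PHOTO_REQUIRED = {
    "participant_id",
    "session_id",
    "view",
    "arm_side",
    "head",
    "floor_pts",
    "bbox",
    "arm_edges",
    "reference",
}
_PHOTO_OPTIONAL = {"camera_id"}


def _photo_out(a: PhotoAnnotation) -> dict:
    return {
        "participant_id": a.participant_id,
        "session_id": a.session_id,
        "view": a.view,
        "arm_side": a.arm_side,
        "head": _point_out(a.head),
        "floor_pts": [_point_out(p) for p in a.floor_pts],
        "bbox": {k: _point_out(p) for k, p in zip("ABCD", a.bbox)},
        "arm_edges": {s: [_point_out(e) for e in pair] for s, pair in a.arm_edges.items()},
        "reference": {
            "tl": _point_out(a.reference.tl),
            "tr": _point_out(a.reference.tr),
            "bl": _point_out(a.reference.bl),
            "br": _point_out(a.reference.br),
            "width_mm": a.reference.width_mm,
            "height_mm": a.reference.height_mm,
        },
        "camera_id": photo_key(a.participant_id, a.session_id, a.view, a.arm_side),
    }


def _photo_in(obj: dict, idx: int, cameras: Optional[Mapping[str, CameraModel]]) -> PhotoAnnotation:
    where = f"photos[{idx}]"
    if not isinstance(obj, dict):
        raise FormatError(f"{where}: expected an object")
    unknown = set(obj) - _PHOTO_REQUIRED - _PHOTO_OPTIONAL
    if unknown:
        raise FormatError(
            f"{where}: unknown field(s) {sorted(unknown)} for annotation schema v{SCHEMA_VERSION}"
        )
    missing = _PHOTO_REQUIRED - set(obj)
    if missing:
        raise FormatError(f"{where}: missing required field(s) {sorted(missing)}")
    ref = obj["reference"]
    for corner in ("tl", "tr", "bl", "br"):
        if corner not in ref:
            raise FormatError(f"{where}.reference: missing corner {corner!r}")
    reference = ReferenceObject(
        _point_in(ref["tl"], f"{where}.reference.tl"),
        _point_in(ref["tr"], f"{where}.reference.tr"),
        _point_in(ref["bl"], f"{where}.reference.bl"),
        _point_in(ref["br"], f"{where}.reference.br"),
        float(ref.get("width_mm", 840.0)),
        float(ref.get("height_mm", 1186.0)),
    )
    bbox = obj["bbox"]
    for corner in "ABCD":
        if corner not in bbox:
            raise FormatError(f"{where}.bbox: missing corner {corner!r}")
    camera = None
    if cameras is not None:
        cam_id = obj.get("camera_id") or photo_key(
            obj["participant_id"], obj["session_id"], obj["view"], obj["arm_side"]
        )
        if cam_id not in cameras:
            raise FormatError(f"{where}: no camera pose found for photo {cam_id!r}")
        camera = cameras[cam_id]
    return PhotoAnnotation(
        participant_id=str(obj["participant_id"]),
        session_id=int(obj["session_id"]),
        view=int(obj["view"]),
        arm_side=str(obj["arm_side"]),
        head=_point_in(obj["head"], f"{where}.head"),
        floor_pts=tuple(_point_in(p, f"{where}.floor_pts") for p in obj["floor_pts"]),
        bbox=tuple(_point_in(bbox[c], f"{where}.bbox.{c}") for c in "ABCD"),
        arm_edges={
            s: tuple(_point_in(e, f"{where}.arm_edges.{s}") for e in pair)
            for s, pair in obj["arm_edges"].items()
        },
        reference=reference,
        camera=camera,
    )


def write_annotations(
    annotations: Sequence[PhotoAnnotation], path, *, provenance: Optional[dict] = None
) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": {"image": "px", "lengths": "mm"},
        "generator": {"package": "photoanthro", "version": __version__, **(provenance or {})},
        "photos": [_photo_out(a) for a in annotations],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotations(
    path, cameras: Optional[Mapping[str, CameraModel]] = None
) -> list[PhotoAnnotation]:
    """Parse an annotation file; optionally attach per-photo camera models.

    Raises :class:`FormatError` with the offending field for any schema
    violation; write-then-read is the identity on the annotation content.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict) or "photos" not in doc:
        raise FormatError(f"{path}: missing top-level 'photos' list")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported annotation schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    return [_photo_in(obj, i, cameras) for i, obj in enumerate(doc["photos"])]


# ---------------------------------------------------------------------------
# camera parameter file (YAML)


def write_camera_file(
    path,
    intrinsics: CameraIntrinsics,
    distortion: DistortionCoefficients,
    poses: Mapping[str, PlanePose],
    *,
    provenance: Optional[dict] = None,
) -> None:
    doc = {
        "package": "photoanthro",
        "version": __version__,
        "units": "mm",
        **(provenance or {}),
        "intrinsics": {
            "fx": intrinsics.fx,
            "fy": intrinsics.fy,
            "cx": intrinsics.cx,
            "cy": intrinsics.cy,
            "skew": intrinsics.skew,
        },
        "distortion": {
            "k1": distortion.k1,
            "k2": distortion.k2,
            "k3": distortion.k3,
            "p1": distortion.p1,
            "p2": distortion.p2,
        },
        "poses": {
            key: {
                "rotation": [float(v) for v in pose.rotation.reshape(-1)],
                "translation": [float(v) for v in pose.translation],
            }
            for key, pose in poses.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_camera_file(path) -> dict[str, CameraModel]:
    """Read a camera parameter file into per-photo camera models."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise FormatError(f"{path}: not valid YAML ({e})") from e
    for section in ("intrinsics", "distortion", "poses"):
        if not isinstance(doc, dict) or section not in doc:
            raise FormatError(f"{path}: missing section {section!r}")
    try:
        intr = CameraIntrinsics(**doc["intrinsics"])
        dist = DistortionCoefficients(**doc["distortion"])
    except TypeError as e:
        raise FormatError(f"{path}: bad intrinsics/distortion fields ({e})") from e
    cams = {}
    for key, p in doc["poses"].items():
        rot = np.array(p["rotation"], dtype=float)
        if rot.size != 9:
            raise FormatError(f"{path}: pose {key!r} rotation must have 9 entries (row-major)")
        pose = PlanePose(rot.reshape(3, 3), np.array(p["translation"], dtype=float))
        cams[key] = CameraModel(intr, dist, pose)
    return cams


# ---------------------------------------------------------------------------
# CSV tables


def _write_csv(df: pd.DataFrame, path, provenance: Optional[dict]) -> None:
    header = {"package": "photoanthro", "version": __version__, **(provenance or {})}
    lines = "".join(f"# {k}: {v}\n" for k, v in header.items())
    Path(path).write_text(lines + df.to_csv(index=False))


MANUAL_COLUMNS = ["participant_id", "quantity", "arm", "repeat", "value_mm"]


def write_manual_measurements(manual: ManualMeasurements, path, *, provenance=None) -> None:
    rows = []
    for pid in sorted(manual.height):
        for j, v in enumerate(manual.height[pid], start=1):
            rows.append((pid, "height", "", j, v))
    for (pid, arm) in sorted(manual.muac):
        for j, v in enumerate(manual.muac[(pid, arm)], start=1):
            rows.append((pid, "muac", arm, j, v))
    _write_csv(pd.DataFrame(rows, columns=MANUAL_COLUMNS), path, provenance)


def read_manual_measurements(path) -> ManualMeasurements:
    """Read the manual reference CSV (repeats retained for TEM/R).

    Per-unit means of the repeats serve as the ground-truth ``x_i``.
    """
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    missing = set(MANUAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manual measurement CSV lacks column(s) {sorted(missing)}")
    manual = ManualMeasurements()
    for row in df.itertuples(index=False):
        value = float(row.value_mm)
        if not value > 0:
            raise FormatError(f"{path}: non-positive manual value {value} for {row.participant_id}")
        if row.quantity == "height":
            manual.height.setdefault(str(row.participant_id), []).append(value)
        elif row.quantity == "muac":
            if row.arm not in ("left", "right"):
                raise FormatError(f"{path}: MUAC row needs arm left/right, got {row.arm!r}")
            manual.muac.setdefault((str(row.participant_id), row.arm), []).append(value)
        else:
            raise FormatError(f"{path}: unknown quantity {row.quantity!r}")
    if not manual.height and not manual.muac:
        raise FormatError(f"{path}: no manual measurements found")
    return manual


RECORD_COLUMNS = [
    "participant_id",
    "session_id",
    "view",
    "backend",
    "H_LD_mm",
    "H_BB_mm",
    "r_left_mm",
    "r_right_mm",
]


def write_measurement_records(records: Iterable[MeasurementRecord], path, *, provenance=None) -> None:
    rows = [
        (r.participant_id, r.session_id, r.view, r.backend, r.H_LD, r.H_BB, r.r_left, r.r_right)
        for r in records
    ]
    _write_csv(pd.DataFrame(rows, columns=RECORD_COLUMNS), path, provenance)


def read_measurement_records(path) -> list[MeasurementRecord]:
    df = pd.read_csv(path, comment="#")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: measurement CSV lacks column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        opt = lambda v: None if pd.isna(v) else float(v)
        out.append(
            MeasurementRecord(
                participant_id=str(row.participant_id),
                session_id=int(row.session_id),
                view=int(row.view),
                backend=str(row.backend),
                H_LD=opt(row.H_LD_mm),
                H_BB=opt(row.H_BB_mm),
                r_left=opt(row.r_left_mm),
                r_right=opt(row.r_right_mm),
            )
        )
    return out


def write_evaluation_table(table: pd.DataFrame, path, *, provenance=None) -> None:
    _write_csv(table, path, provenance)
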