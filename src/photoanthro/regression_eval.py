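"""View-subset linear regression with leave-one-out cross-validation, and
the reliability statistics used to evaluate every estimator.

An estimate from a view subset ``S`` (a non-empty subset of {1..5}) is
``sum_{i in S} w_i * f_i + b`` where ``f_i`` is the per-view feature
(linear-distance height, bounding-box height, or arm radius) and the
weights are fitted by ordinary least squares against the manual reference.
Models are scored by LOOCV: all rows of one unit (a participant for
height, a single arm for MUAC) are held out per fold, so a unit's own
reference value never influences its prediction.

Agreement and reliability metrics:

* ``MAD_i``  — per-unit mean absolute difference from the manual mean.
* ``MAPD_i`` — per-unit mean absolute percentage difference.
* ``TEM``    — technical error of measurement, the within-unit standard
  deviation of repeated estimates, pooled over units.
* ``R``      — coefficient of reliability ``1 - TEM^2 / s^2`` with ``s``
  the standard deviation of all pooled estimates; R > 0.95 is the
  conventional acceptability threshold, and a photo TEM within
  ``+/- 2.8 x`` the manual TEM is deemed adequate.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    MeasurementRecord,
    muac_circle,
    muac_ellipse,
    muac_mix,
)

__all__ = [
    "ViewSet",
    "RegressionModel",
    "ObservationMatrix",
    "ManualMeasurements",
    "EvaluationError",
    "all_view_subsets",
    "feature_table",
    "assemble_observations",
    "fit_regression",
    "predict",
    "loocv_predict",
    "mad_mapd",
    "tem",
    "reliability",
    "adequacy",
    "acceptable_r",
    "sweep_view_combinations",
    "EVALUATION_COLUMNS",
]

ALL_VIEWS = (1, 2, 3, 4, 5)

#: Column schema of evaluation tables (units encoded in the names).
EVALUATION_COLUMNS = [
    "method",
    "backend",
    "view_set",
    "mad_mean_mm",
    "mad_sd_mm",
    "mapd_mean_pct",
    "mapd_sd_pct",
    "tem_mm",
    "r",
    "adequate_tem",
    "acceptable_r",
    "optimal",
]


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs (missing views, bad repeat counts...)."""


@dataclass(frozen=True)
class ViewSet:
    """A non-empty, sorted, duplicate-free subset of the five views."""

    members: tuple[int, ...]

    def __post_init__(self) -> None:
        members = tuple(sorted(set(int(v) for v in self.members)))
        if not members or any(v not in ALL_VIEWS for v in members):
            raise EvaluationError(f"view set must be a non-empty subset of {ALL_VIEWS}, got {self.members}")
        object.__setattr__(self, "members", members)

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return "{" + ",".join(str(v) for v in self.members) + "}"


def all_view_subsets() -> list[ViewSet]:
    """The 31 non-empty subsets of {1..5}, by size then lexicographically."""
    out = []
    for k in range(1, 6):
        for combo in itertools.combinations(ALL_VIEWS, k):
            out.append(ViewSet(combo))
    return out


@dataclass(frozen=True)
class RegressionModel:
    """Fitted per-view weights and bias for one view subset."""

    view_set: ViewSet
    weights: Mapping[int, float]
    bias: float
    target: str

    def __post_init__(self) -> None:
        if tuple(sorted(self.weights)) != self.view_set.members:
            raise EvaluationError("weights must be keyed exactly by the view set's members")
        vals = list(self.weights.values()) + [self.bias]
        if not all(math.isfinite(v) for v in vals):
            raise EvaluationError(f"non-finite regression coefficients {vals}")


@dataclass(frozen=True)
class ObservationMatrix:
    """Design matrix for one (target, view subset): one row per unit-session.

    ``unit_ids[i]`` identifies the cross-validation unit of row ``i`` (a
    participant id for height, ``(participant id, arm)`` for MUAC);
    ``X[i, j]`` is the feature of view ``view_set.members[j]`` in mm, and
    ``x_ref[i]`` the unit's manual reference value (mean of repeats).
    """

    view_set: ViewSet
    target: str
    unit_ids: tuple
    session_ids: tuple[int, ...]
    X: np.ndarray
    x_ref: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        x_ref = np.asarray(self.x_ref, dtype=float)
        n = len(self.unit_ids)
        if X.shape != (n, len(self.view_set)) or x_ref.shape != (n,) or len(self.session_ids) != n:
            raise EvaluationError("inconsistent observation matrix shapes")
        if not (np.isfinite(X).all() and np.isfinite(x_ref).all()):
            raise EvaluationError("observation matrix contains non-finite cells")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "x_ref", x_ref)

    @property
    def units(self) -> list:
        seen: dict = {}
        for u in self.unit_ids:
            seen.setdefault(u, None)
        return list(seen)


@dataclass
class ManualMeasurements:
    """Repeated manual reference measurements.

    ``height[pid]`` and ``muac[(pid, arm)]`` are lists of repeats in mm
    (three per unit in the study design).  Unit means serve as the ground
    truth ``x_i``; the repeats themselves yield the manual TEM and R that
    anchor the adequacy rule.
    """

    height: dict[str, list[float]] = field(default_factory=dict)
    muac: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def means(self, quantity: str) -> dict:
        table = self.height if quantity == "height" else self.muac
        if any(len(v) == 0 for v in table.values()) or not table:
            raise EvaluationError(f"no manual repeats available for {quantity!r}")
        return {unit: float(np.mean(reps)) for unit, reps in table.items()}

    def tem(self, quantity: str) -> float:
        table = self.height if quantity == "height" else self.muac
        return tem([table[u] for u in sorted(table)])


# ---------------------------------------------------------------------------
# feature assembly


def feature_table(records: Iterable[MeasurementRecord], target: str) -> dict:
    """Per-unit, per-session, per-view feature values in mm.

    ``target`` is ``height_ld``, ``height_bb`` or ``muac``.  For height,
    views photographed twice per session (once per arm side, views 2-4)
    contribute the mean of the two photos' values.  For MUAC the unit is
    an arm and each view contributes the radius from the photo in which
    that arm is unobstructed.
    """
    if target not in ("height_ld", "height_bb", "muac"):
        raise EvaluationError(f"unknown target {target!r}")
    acc: dict = {}
    for rec in records:
        if target == "muac":
            for side, value in (("left", rec.r_left), ("right", rec.r_right)):
                if value is not None:
                    unit = (rec.participant_id, side)
                    acc.setdefault(unit, {}).setdefault(rec.session_id, {}).setdefault(
                        rec.view, []
                    ).append(value)
        else:
            value = rec.H_LD if target == "height_ld" else rec.H_BB
            if value is not None:
                acc.setdefault(rec.participant_id, {}).setdefault(
                    rec.session_id, {}
                ).setdefault(rec.view, []).append(value)
    return {
        unit: {
            sess: {view: float(np.mean(vals)) for view, vals in by_view.items()}
            for sess, by_view in by_sess.items()
        }
        for unit, by_sess in acc.items()
    }


def assemble_observations(
    records: Iterable[MeasurementRecord],
    target: str,
    view_set: ViewSet,
    reference_means: Mapping,
) -> ObservationMatrix:
    """Build the design matrix for one view subset.

    Rows are ordered by unit then session for determinism.  A unit-session
    lacking any view in the subset raises :class:`EvaluationError` naming
    the offending cell.
    """
    feats = feature_table(records, target)
    unit_ids, session_ids, rows, refs = [], [], [], []
    for unit in sorted(feats):
        if unit not in reference_means:
            raise EvaluationError(f"no manual reference value for unit {unit!r}")
        for sess in sorted(feats[unit]):
            row = []
            for view in view_set:
                if view not in feats[unit][sess]:
                    raise EvaluationError(
                        f"unit {unit!r}, session {sess} has no measurement for view {view}"
                    )
                row.append(feats[unit][sess][view])
            unit_ids.append(unit)
            session_ids.append(sess)
            rows.append(row)
            refs.append(reference_means[unit])
    return ObservationMatrix(
        view_set=view_set,
        target=target,
        unit_ids=tuple(unit_ids),
        session_ids=tuple(session_ids),
        X=np.array(rows, dtype=float),
        x_ref=np.array(refs, dtype=float),
    )


# ---------------------------------------------------------------------------
# regression


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares of y on [X, 1]; warns when rank-deficient."""
    A = np.column_stack([X, np.ones(len(X))])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "rank-deficient design matrix; using the minimum-norm solution",
            RuntimeWarning,
            stacklevel=3,
        )
    return coef


def fit_regression(obs: ObservationMatrix) -> RegressionModel:
    """Ordinary least squares with intercept on the full observation matrix."""
    n, k = obs.X.shape
    if n < k + 2:
        raise EvaluationError(f"need at least |S|+2 = {k + 2} rows to fit, got {n}")
    coef = _ols(obs.X, obs.x_ref)
    weights = {view: float(w) for view, w in zip(obs.view_set, coef[:-1])}
    return RegressionModel(obs.view_set, weights, float(coef[-1]), obs.target)


def predict(model: RegressionModel, obs: ObservationMatrix) -> np.ndarray:
    if obs.view_set != model.view_set:
        raise EvaluationError("observation matrix and model use different view sets")
    w = np.array([model.weights[v] for v in model.view_set], dtype=float)
    return obs.X @ w + model.bias


def loocv_predict(obs: ObservationMatrix) -> np.ndarray:
    """Leave-one-unit-out predictions, aligned with the matrix rows.

    For each unit, a model fitted on all other units' rows predicts every
    row of that unit; the held-out unit's reference values never enter its
    own training set.
    """
    units = obs.units
    if len(units) < 3:
        raise EvaluationError(f"LOOCV needs at least 3 units, got {len(units)}")
    unit_arr = np.array([units.index(u) for u in obs.unit_ids])
    preds = np.empty(len(obs.unit_ids))
    A = np.column_stack([obs.X, np.ones(len(obs.X))])
    for idx in range(len(units)):
        held = unit_arr == idx
        coef = _ols(obs.X[~held], obs.x_ref[~held])
        preds[held] = A[held] @ coef
    return preds


# ---------------------------------------------------------------------------
# metrics


def mad_mapd(x_i: float, estimates: Sequence[float]) -> tuple[float, float]:
    """Per-unit mean absolute difference (mm) and percentage difference (%)."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise EvaluationError("MAD/MAPD need at least one estimate")
    if x_i <= 0:
        raise EvaluationError(f"reference value must be positive for MAPD, got {x_i}")
    abs_diff = np.abs(x_i - est)
    return float(abs_diff.mean()), float(100.0 * (abs_diff / x_i).mean())


def tem(estimates: Sequence[Sequence[float]]) -> float:
    """Technical error of measurement over units with a common repeat count.

    ``TEM = sqrt( sum_i [ sum_j x_ij^2 - (sum_j x_ij)^2 / N ] / (M (N-1)) )``
    for M units of N repeats each; the study design has N = 3 sessions.
    Units with unequal or fewer than two repeats raise.
    """
    groups = [np.asarray(g, dtype=float) for g in estimates]
    if not groups:
        raise EvaluationError("TEM needs at least one unit")
    n = len(groups[0])
    if any(len(g) != n for g in groups):
        raise EvaluationError("TEM requires the same repeat count for every unit")
    if n < 2:
        raise EvaluationError("TEM requires at least two repeats per unit")
    m = len(groups)
    total = sum(float(np.sum(g**2) - np.sum(g) ** 2 / n) for g in groups)
    # clip tiny negative rounding residue from cancellation
    return math.sqrt(max(total, 0.0) / (m * (n - 1)))


def reliability(tem_value: float, estimates: Sequence[float]) -> float:
    """Coefficient of reliability ``R = 1 - TEM^2 / s^2``, clamped to [0, 1].

    ``s`` is the standard deviation of all pooled estimates over the
    population (sample SD).  Zero pooled variance raises.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise EvaluationError("R needs at least two pooled estimates")
    s = float(np.std(est, ddof=1))
    if s <= 0:
        raise EvaluationError("zero pooled variance: R is undefined")
    return float(min(1.0, max(0.0, 1.0 - tem_value**2 / s**2)))


def adequacy(tem_photo: float, tem_manual: float) -> bool:
    """Adequate iff the photo TEM is within +/- 2.8 x the manual TEM of it."""
    if tem_manual < 0:
        raise EvaluationError(f"manual TEM must be non-negative, got {tem_manual}")
    return abs(tem_photo - tem_manual) <= 2.8 * tem_manual


def acceptable_r(r: float) -> bool:
    """Acceptable reliability iff R > 0.95 (strict)."""
    return r > 0.95


# ---------------------------------------------------------------------------
# table sweep


def _score_estimates(
    est_by_unit: "dict[object, list[float]]",
    reference_means: Mapping,
    tem_manual: float,
) -> dict:
    units = sorted(est_by_unit)
    mads, mapds = [], []
    for u in units:
        mad_u, mapd_u = mad_mapd(reference_means[u], est_by_unit[u])
        mads.append(mad_u)
        mapds.append(mapd_u)
    tem_value = tem([est_by_unit[u] for u in units])
    pooled = [e for u in units for e in est_by_unit[u]]
    r = reliability(tem_value, pooled)
    return {
        "mad_mean_mm": float(np.mean(mads)),
        "mad_sd_mm": float(np.std(mads, ddof=1)),
        "mapd_mean_pct": float(np.mean(mapds)),
        "mapd_sd_pct": float(np.std(mapds, ddof=1)),
        "tem_mm": tem_value,
        "r": r,
        "adequate_tem": adequacy(tem_value, tem_manual),
        "acceptable_r": acceptable_r(r),
    }


def _group_predictions(obs: ObservationMatrix, preds: np.ndarray) -> dict:
    out: dict = {}
    for unit, p in zip(obs.unit_ids, preds):
        out.setdefault(unit, []).append(float(p))
    return out


def _regression_rows(
    records, target: str, method: str, backend: str, reference_means, tem_manual: float
) -> list[dict]:
    rows = []
    for vs in all_view_subsets():
        obs = assemble_observations(records, target, vs, reference_means)
        preds = loocv_predict(obs)
        row = {"method": method, "backend": backend, "view_set": str(vs)}
        row.update(_score_estimates(_group_predictions(obs, preds), reference_means, tem_manual))
        rows.append(row)
    return rows


def _baseline_rows_height(records, backend: str, reference_means, tem_manual: float) -> list[dict]:
    feats = feature_table(records, "height_ld")
    rows = []
    for view in ALL_VIEWS:
        est_by_unit = {
            unit: [by_view[view] for _, by_view in sorted(by_sess.items())]
            for unit, by_sess in feats.items()
        }
        row = {"method": "linear_distance", "backend": backend, "view_set": str(ViewSet((view,)))}
        row.update(_score_estimates(est_by_unit, reference_means, tem_manual))
        rows.append(row)
    return rows


def _shape_model_rows(records, backend: str, reference_means, tem_manual: float) -> list[dict]:
    feats = feature_table(records, "muac")
    rows = []
    for view in ALL_VIEWS:
        est_by_unit = {
            unit: [muac_circle(by_view[view]) for _, by_view in sorted(by_sess.items())]
            for unit, by_sess in feats.items()
        }
        row = {"method": "shape_circle", "backend": backend, "view_set": str(ViewSet((view,)))}
        row.update(_score_estimates(est_by_unit, reference_means, tem_manual))
        rows.append(row)
    for name, fn in (("shape_ellipse", muac_ellipse), ("shape_ellipse_rectangle", muac_mix)):
        for vi, vj in itertools.combinations(ALL_VIEWS, 2):
            est_by_unit = {
                unit: [
                    fn(by_view[vi], by_view[vj]) for _, by_view in sorted(by_sess.items())
                ]
                for unit, by_sess in feats.items()
            }
            row = {"method": name, "backend": backend, "view_set": str(ViewSet((vi, vj)))}
            row.update(_score_estimates(est_by_unit, reference_means, tem_manual))
            rows.append(row)
    return rows


def _flag_optimal(df: pd.DataFrame) -> pd.DataFrame:
    """Mark the best row (smallest mean MAD) per method block.

    Ties break towards fewer views, then lexicographically smaller sets,
    mirroring the bold-row convention of the published result tables.
    """
    df = df.copy()
    df["optimal"] = False

    def sort_key(row):
        views = tuple(int(v) for v in row["view_set"].strip("{}").split(","))
        return (row["mad_mean_mm"], len(views), views)

    for method, block in df.groupby("method"):
        best = min(block.to_dict("records"), key=sort_key)
        mask = (df["method"] == method) & (df["view_set"] == best["view_set"])
        df.loc[mask, "optimal"] = True
    return df[EVALUATION_COLUMNS]


def sweep_view_combinations(
    records: Sequence[MeasurementRecord],
    manual: ManualMeasurements,
    target: str,
    backend: str,
) -> pd.DataFrame:
    """Full evaluation table for one target and back-end.

    ``target``:

    * ``height_ld`` — 5 single-view linear-distance baseline rows plus 31
      regression-of-linear-distance rows;
    * ``height_bb`` — 31 regression-of-bounding-box rows;
    * ``muac``      — 5 circle + 10 ellipse + 10 ellipse/rectangle shape
      model rows plus 31 regression-of-radius rows.

    Regression rows are scored on LOOCV predictions; baseline and shape
    model rows need no fitting and are scored on their direct estimates.
    The result is deterministic for identical inputs.
    """
    records = [r for r in records if r.backend == backend]
    if not records:
        raise EvaluationError(f"no measurement records for backend {backend!r}")
    quantity = "muac" if target == "muac" else "height"
    reference_means = manual.means(quantity)
    tem_manual = manual.tem(quantity)
    if target == "height_ld":
        rows = _baseline_rows_height(records, backend, reference_means, tem_manual)
        rows += _regression_rows(
            records, "height_ld", "linear_distance_regression", backend, reference_means, tem_manual
        )
    elif target == "height_bb":
        rows = _regression_rows(
            records, "height_bb", "bounding_box_regression", backend, reference_means, tem_manual
        )
    elif target == "muac":
        rows = _shape_model_rows(records, backend, reference_means, tem_manual)
        rows += _regression_rows(
            records, "muac", "radius_regression", backend, reference_means, tem_manual
        )
    else:
        raise EvaluationError(f"unknown target {target!r}")
    return _flag_optimal(pd.DataFrame(rows))
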