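"""Recover pinhole intrinsics and a plane pose from checkerboard views.

Synthesizes distortion-free views of the 7x10-square (90 mm) board through
a known camera, runs the linear closed-form intrinsic calibration, and
back-projects a segment to verify metric measurement in the plane.
"""

import numpy as np

from photoanthro.camera import (
    CameraIntrinsics, CameraModel, DistortionCoefficients, PlanePose,
    back_project_to_plane, calibrate_intrinsics, homography_from_correspondences,
    pose_from_homography, project,
)
from photoanthro.geometry import WorldPoint, euclidean


def rotation(rx, ry):
    cx, sx, cy, sy = np.cos(rx), np.sin(rx), np.cos(ry), np.sin(ry)
    return np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]]) @ np.array(
        [[1, 0, 0], [0, cx, -sx], [0, sx, cx]])


truth = CameraIntrinsics(fx=3240.0, fy=3240.0, cx=2000.0, cy=1500.0)
board = [WorldPoint(90.0 * i, 90.0 * j) for i in range(6) for j in range(9)]

views = []
for rx, ry in [(0.0, 0.0), (0.3, 0.1), (-0.25, 0.2), (0.1, -0.35), (-0.15, -0.2)]:
    cam = CameraModel(truth, DistortionCoefficients(),
                      PlanePose(rotation(rx, ry), np.array([0.0, 0.0, 3000.0])))
    views.append([(w, project(w, cam)) for w in board])

est = calibrate_intrinsics(views)
print(f"true intrinsics      : fx {truth.fx:.1f}  fy {truth.fy:.1f}  cx {truth.cx:.1f}  cy {truth.cy:.1f}")
print(f"recovered intrinsics : fx {est.fx:.1f}  fy {est.fy:.1f}  cx {est.cx:.1f}  cy {est.cy:.1f}")

pose = pose_from_homography(homography_from_correspondences(views[1]), est)
cam = CameraModel(est, DistortionCoefficients(), pose)
a, b = WorldPoint(200.0, -800.0), WorldPoint(200.0, 906.5)
aw = back_project_to_plane(project(a, CameraModel(truth, DistortionCoefficients(),
                                                  PlanePose(rotation(0.3, 0.1), np.array([0.0, 0.0, 3000.0])))), cam)
bw = back_project_to_plane(project(b, CameraModel(truth, DistortionCoefficients(),
                                                  PlanePose(rotation(0.3, 0.1), np.array([0.0, 0.0, 3000.0])))), cam)
print(f"\n1706.5 mm segment measured through the recovered camera: {euclidean(aw, bw):.3f} mm")
# The linear Zhang solution recovers the intrinsics to <0.1% on clean
# synthetic views, so in-plane distances round-trip to sub-micrometre error.
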