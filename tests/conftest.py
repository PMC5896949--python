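import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photoanthro.camera import CameraIntrinsics, CameraModel, DistortionCoefficients, PlanePose
from photoanthro.synthetic import SceneConfig, generate_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def noiseless_config(**overrides) -> SceneConfig:
    """Study-geometry config with every noise source switched off."""
    defaults = dict(
        annotation_noise_px=0.0,
        plane_offset_view_mm=(0.0,) * 5,
        plane_offset_sd_mm=0.0,
        manual_noise_height_mm=0.0,
        manual_noise_muac_mm=0.0,
        seed=7,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


def fronto_parallel_camera(
    distance_mm: float = 3200.0,
    center_xy: tuple[float, float] = (400.0, 500.0),
    distortion: DistortionCoefficients | None = None,
    tilt_rad: float = 0.0,
) -> CameraModel:
    """Camera looking straight at the plane, optionally pitched by ``tilt_rad``."""
    c, s = np.cos(tilt_rad), np.sin(tilt_rad)
    R = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    center = np.array([center_xy[0], center_xy[1], -distance_mm])
    pose = PlanePose(R, -R @ center)
    return CameraModel(
        CameraIntrinsics(3240.0, 3240.0, 2000.0, 1500.0),
        distortion or DistortionCoefficients(),
        pose,
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Full-size study bundle (31 x 3 x 8 photos) with all noise off."""
    return generate_bundle(noiseless_config())


@pytest.fixture(scope="session")
def small_noiseless_bundle():
    return generate_bundle(noiseless_config(n_participants=4, n_sessions=2, seed=5))


@pytest.fixture(scope="session")
def default_bundle():
    """Default (noisy) study bundle used by evaluation-level tests."""
    return generate_bundle(SceneConfig(seed=11))


@pytest.fixture(scope="session")
def default_records(default_bundle):
    from photoanthro.estimators import measure_photo

    return [
        measure_photo(p.noisy, backend)
        for p in default_bundle.photos
        for backend in ("calibration", "reference")
    ]
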