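import pytest

import kneeflex as kf
from kneeflex.experiments import run_synthetic_session


def make_scenario(**overrides):
    """Scenario factory with noise-free defaults and known misalignments."""
    params = dict(
        profile=kf.MotionProfile(duration=20.0),
        mounts=kf.SensorMountSpec(delta_f=5.0, delta_t=-3.0),
        camera=kf.CameraSpec(),
        time_lag=0.5,
        box_pose_angle=60.0,
        goniometer_error=0.0,
        sway_deg=0.15,
        rng_seed=3,
    )
    params.update(overrides)
    return kf.SyntheticScenario(**params)


@pytest.fixture(scope="session")
def nf_result():
    """Noise-free end-to-end run: delta_F=5, delta_T=-3, lag 0.5 s."""
    return run_synthetic_session(make_scenario(), fit_piecewise=False)


@pytest.fixture(scope="session")
def noisy_result():
    """End-to-end run with realistic sensor and camera noise."""
    scn = make_scenario(
        profile=kf.MotionProfile(duration=30.0),
        mounts=kf.SensorMountSpec(
            delta_f=5.0, delta_t=-3.0, gyro_noise_sd=0.2,
            gyro_bias=0.02, accel_noise_sd=0.01,
        ),
        camera=kf.CameraSpec(pixel_noise_sd=2.0, dropout_prob=0.02),
        time_lag=-0.8,
        box_pose_angle=62.0,
        rng_seed=7,
    )
    return run_synthetic_session(scn, fit_piecewise=False)
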