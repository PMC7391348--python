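import numpy as np
import pytest

from yawkit import (
    DistortionSpec,
    fit_ellipsoid,
    generate_calibration_rotation,
    simulate_trajectory,
    synthesize_imu,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def distorted_spec():
    """Canonical hard+soft iron distortion, noiseless."""
    return DistortionSpec.noiseless(
        hard_iron=[0.10, -0.05, 0.20], soft_iron=np.diag([1.2, 0.9, 1.1])
    )


@pytest.fixture
def noiseless_deployment(distorted_spec):
    """Short noiseless distorted deployment: circling + quiescent, level."""
    plan = [
        {"behavior": "circling", "duration_s": 60, "rate_dps": 6.0},
        {"behavior": "quiescent", "duration_s": 30, "jitter_sd": 0.0},
        {"behavior": "oscillatory-search", "duration_s": 30},
    ]
    truth = simulate_trajectory(plan, rate_hz=40.0, seed=11)
    raw = synthesize_imu(truth, distorted_spec, seed=12)
    cal = generate_calibration_rotation(distorted_spec, 500, seed=13)
    return truth, raw, fit_ellipsoid(cal.mag)


@pytest.fixture
def dive_deployment():
    """Realistic-noise deployment with two flat U-dives and a shallow bob."""
    spec = DistortionSpec(hard_iron=[0.05, -0.02, 0.1], soft_iron=np.diag([1.1, 0.95, 1.05]))
    plan = [
        {"behavior": "quiescent", "duration_s": 30, "jitter_sd": 0.2},
        {"behavior": "circling", "duration_s": 180, "rate_dps": 6.0, "dive_depth": 8.0},
        {"behavior": "quiescent", "duration_s": 30, "jitter_sd": 0.2},
        {"behavior": "oscillatory-search", "duration_s": 240, "dive_depth": 5.0},
        {"behavior": "quiescent", "duration_s": 20, "jitter_sd": 0.2},
        {"behavior": "transit", "duration_s": 40, "dive_depth": 2.0},
        {"behavior": "quiescent", "duration_s": 20, "jitter_sd": 0.2},
    ]
    truth = simulate_trajectory(plan, rate_hz=40.0, seed=21)
    raw = synthesize_imu(truth, spec, seed=22)
    cal = generate_calibration_rotation(spec, 600, seed=23)
    return truth, raw, fit_ellipsoid(cal.mag)
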