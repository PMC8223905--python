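import dataclasses

import numpy as np
import pytest

from proswing.containers import DampingCondition
from proswing.pipeline import PipelineParams, analyze_bundle, run_sweep
from proswing.simulate import SimConfig, generate_trial

TABLE_COEFFICIENTS = (0.0, 0.37, 0.56, 0.80, 1.10)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def short_config():
    """Three-stride trial; enough for event/tracking checks."""
    return dataclasses.replace(SimConfig(), n_strides=3)


@pytest.fixture(scope="session")
def noise_free_output(short_config):
    return generate_trial(dataclasses.replace(short_config,
                                              marker_noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_output(short_config):
    return generate_trial(short_config)


@pytest.fixture(scope="session")
def analyzed_noise_free(noise_free_output):
    return analyze_bundle(noise_free_output.bundle, PipelineParams())


@pytest.fixture(scope="session")
def sweep_result():
    """Full damping sweep of the default synthetic participant."""
    return run_sweep(SimConfig())


@pytest.fixture(scope="session")
def stationary_pendulum_config():
    """Hanging pendulum: fixed pivot, no drive, no device torques."""
    return dataclasses.replace(
        SimConfig(),
        hip_speed=0.0,
        hip_vertical_amplitude=0.0,
        hip_flexion_amplitude=0.0,
        hip_flexion_offset=0.0,
        bumper_stiffness=0.0,
        bumper_damping=0.0,
        damping=DampingCondition("free", 0.0, 0.0),
    )


def event_errors_frames(output, result):
    """Detected-minus-truth event errors in kinematic frames, per type."""
    tr = output.truth
    rate = output.bundle.trial.rate
    errs = {"foot_off": [], "foot_contact": [], "mid_swing": []}
    for side in ("left", "right"):
        strides = [s for s in result.events.strides if s.side == side]
        for k, s in enumerate(strides):
            errs["foot_off"].append(s.foot_off - tr.foot_off_s[side][k] * rate)
            errs["foot_contact"].append(
                s.foot_contact - tr.foot_contact_s[side][k] * rate)
            errs["mid_swing"].append(
                s.mid_swing - tr.mid_swing_s[side][k] * rate)
    return {k: np.asarray(v) for k, v in errs.items()}
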