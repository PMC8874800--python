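import numpy as np
import pytest

from vrmotion import assemble_variable_table, build_dataset, segment_session
from vrmotion.synthetic import SubjectParams, generate_calibration_session


@pytest.fixture(scope="session")
def noise_free_params():
    return SubjectParams(
        position_noise_sd=0.0,
        angle_noise_sd=0.0,
        position_white_sd=0.0,
        angle_white_sd=0.0,
        hmd_position_noise_sd=0.0,
        hmd_angle_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def calibration():
    """One default synthetic calibration session with derived artifacts."""
    session, truth = generate_calibration_session(seed=0)
    table = assemble_variable_table(session)
    segments = segment_session(session)
    return session, truth, table, segments


@pytest.fixture(scope="session")
def window_dataset(calibration):
    _, _, table, _ = calibration
    return build_dataset(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
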