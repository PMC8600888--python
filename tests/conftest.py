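import numpy as np
import pytest

import caremirt as cm


@pytest.fixture(scope="session")
def true_params():
    """Reference generating parameters of the ten-item two-factor scale."""
    return cm.default_true_params()


@pytest.fixture(scope="session")
def calibration_cohort(true_params):
    """One n=1000 cohort simulated from the reference parameters."""
    thetas = cm.sample_thetas(1000, 0.5, 4242)
    data = cm.sample_responses(true_params, thetas, 4343)
    return thetas, data


@pytest.fixture(scope="session")
def fitted_model(true_params, calibration_cohort):
    """EM fit of the reference structure on the calibration cohort (shared)."""
    _, data = calibration_cohort
    params, ability, indices = cm.fit(data, true_params.structure)
    return data, params, ability, indices
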