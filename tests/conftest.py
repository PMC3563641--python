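import numpy as np
import pytest

import modeldiscrim as md


def _decay_rhs(x, p, inputs, t):
    return np.array([-p[0] * x[0]])


@pytest.fixture(scope="session")
def decay_model():
    """dS/dt = -k S: the closed-form workhorse for simulator/estimation tests."""
    return md.KineticModel(
        name="decay",
        species=("S",),
        parameters=("k",),
        rhs=_decay_rhs,
        observed=("S",),
    )


@pytest.fixture(scope="session")
def exact_objective_config():
    """Step configs steep enough that weights are exactly 1 at benign points.

    With steepness 50 the tanh saturates to ±1 in double precision well away
    from the center, so hand-computed objective sums match to the last bit.
    """
    return md.ObjectiveConfig(
        variance=md.VarianceModel(sigma=1.0),
        dt_step=md.StepFunctionConfig(width=2.0, center=1.0, steepness=50.0),
        pert_step=md.StepFunctionConfig(width=0.1, center=0.05, steepness=50.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
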