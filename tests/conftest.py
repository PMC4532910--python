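import numpy as np
import pandas as pd
import pytest

from durcue import (ModelSpec, ObserverParams, build_priors,
                    build_schedule_exp1, build_schedule_exp2,
                    build_schedule_exp3, simulate_responses)
from durcue.observer import default_observer


@pytest.fixture(scope="session")
def exp1():
    return build_schedule_exp1(1)


@pytest.fixture(scope="session")
def exp2():
    return build_schedule_exp2(1)


@pytest.fixture(scope="session")
def exp3():
    return build_schedule_exp3(1)


@pytest.fixture(scope="session")
def best_model():
    return ModelSpec("weighting", "decay", "double")


@pytest.fixture(scope="session")
def best_params(best_model):
    return default_observer(best_model)


@pytest.fixture(scope="session")
def exp3_responses(exp3, best_model, best_params):
    """One synthetic observer on the Experiment-3 schedule."""
    return simulate_responses(exp3, best_model, best_params, seed=7)
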