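import warnings

import pytest
from hypothesis import HealthCheck, settings

from epireact.alignment import AlignmentParams, score_matrix
from epireact.synthetic import make_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# scikit-learn emits convergence chatter on tiny refits; irrelevant to assertions
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def tiny_set():
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_matrices(tiny_set):
    mg = score_matrix(tiny_set, AlignmentParams(mode="global"))
    ml = score_matrix(tiny_set, AlignmentParams(mode="local"))
    return mg, ml
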