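import numpy as np
import pytest
from hypothesis import settings

from bmcoop import LearnerParams, run_pdg, square_lattice

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

CONDITIONS = ("all", "prev_C", "prev_D")


@pytest.fixture(scope="session")
def lattice10():
    return square_lattice(10)


@pytest.fixture(scope="session")
def mcc_result(lattice10):
    """Reference lattice ensemble in the CC+MCC regime (beta=0.4, A=0.5)."""
    return run_pdg(
        lattice10, LearnerParams(beta=0.4, A=0.5), t_max=25, n_runs=150, seed=1234
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
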