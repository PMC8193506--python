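import numpy as np
import pytest

from linform import (
    INParameters,
    ProblemInput,
    build_network,
    initial_state,
)


@pytest.fixture(scope="session")
def in_network():
    """The IN network at the published fit parameters (built once)."""
    return build_network(INParameters())


@pytest.fixture(scope="session")
def problem_7x8():
    return ProblemInput(7, 8)


@pytest.fixture(scope="session")
def state_7x8(in_network, problem_7x8):
    return initial_state(in_network, problem_7x8)
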