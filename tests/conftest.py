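import numpy as np
import pytest
from hypothesis import settings

import prefsolv as ps

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenarios() -> dict[str, ps.ExchangeParams]:
    return ps.scenario_library()


@pytest.fixture(scope="session")
def grid21() -> np.ndarray:
    return np.linspace(0.0, 1.0, 21)


@pytest.fixture(scope="session")
def grid99() -> np.ndarray:
    """Interior-only grid used for normalization / sign property checks."""
    return np.linspace(0.01, 0.99, 99)


def relerr(a: float, b: float) -> float:
    return abs(a - b) / max(abs(b), 1e-300)
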