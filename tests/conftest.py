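import numpy as np
import pytest

from s10pos.genome import CellCycleParams, default_layout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def params():
    """Fast-growth fixture: tau 30 min, C1 40 min, so C/tau = 4/3."""
    return CellCycleParams(tau_min=30.0, C1_min=40.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
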