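import numpy as np
import pytest

from cbmcn.annual_simulator import RunConfig, run_prepared
from cbmcn.synthetic_fixtures import LandscapeSpec, generate_landscape, generate_parameters


@pytest.fixture(scope="session")
def params():
    """A complete synthetic parameter set (fixed seed)."""
    return generate_parameters(7)


@pytest.fixture(scope="session")
def small_landscape():
    """40 stands, 1990-2016, with a consistent event schedule."""
    spec = LandscapeSpec(seed=11, n_stands=40)
    return generate_landscape(spec)


@pytest.fixture(scope="session")
def small_run(small_landscape):
    """A completed 40-stand simulation (annual table + ledger + inputs)."""
    stands, climate, events = small_landscape
    p = generate_parameters(11)
    cfg = RunConfig(parameters="", inventory="", climate="", start_year=1990, end_year=2016)
    annual, ledger = run_prepared(stands, p, climate, events, cfg)
    return {"annual": annual, "ledger": ledger, "stands": stands, "climate": climate,
            "events": events, "params": p, "config": cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(123)
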