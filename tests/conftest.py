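import numpy as np
import pytest

from chronomr.harmonise import harmonise_set
from chronomr.sumstats import load_fixture

EPOCHS = ("birth", "infancy", "early_childhood", "later_childhood")


@pytest.fixture(scope="session")
def fixture_tables():
    """Exposure/outcome tables for each published epoch."""
    return {ep: load_fixture(ep) for ep in EPOCHS}


@pytest.fixture(scope="session")
def instrument_sets(fixture_tables):
    """Harmonised instrument sets per epoch under the strict palindromic policy."""
    return {
        ep: harmonise_set(exp, out, policy="strict", label=ep)
        for ep, (exp, out) in fixture_tables.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20220509)
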