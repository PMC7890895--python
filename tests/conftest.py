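import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from regevo.pipeline import regulomes_from_simulation
from regevo.synthetic import make_fixture, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """Small two-species simulation shared across tests."""
    return simulate(make_fixture("tiny", seed=0))


@pytest.fixture(scope="session")
def tiny_regulomes(tiny_sim):
    return regulomes_from_simulation(tiny_sim)


@pytest.fixture(scope="session")
def clean_sim():
    """Two-species simulation with zero jitter, dropout, and plain defaults."""
    cfg = make_fixture("tiny", seed=2)
    cfg.peak_jitter_sd = 0.0
    cfg.replicate_dropout = 0.0
    return simulate(cfg)
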