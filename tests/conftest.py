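import numpy as np
import pytest

from ablib import simulate as sim
from ablib.resources import (
    load_developability_map,
    load_germline_reference,
    load_primer_panel,
)


@pytest.fixture(scope="session")
def reference():
    return load_germline_reference()


@pytest.fixture(scope="session")
def dmap():
    return load_developability_map()


@pytest.fixture(scope="session")
def ighv_panel():
    return load_primer_panel(chain_prefix="IGHV")


@pytest.fixture(scope="session")
def heavy_clones(reference):
    """Moderate heavy-chain repertoire shared across tests."""
    spec = sim.chain_spec("heavy", 3000, seed=11)
    return sim.generate_repertoire(spec, reference)


@pytest.fixture(scope="session")
def clean_heavy_reads(heavy_clones):
    """Error-free reads from the shared repertoire."""
    return sim.simulate_reads(heavy_clones, 4000, sub_rate=0.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
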