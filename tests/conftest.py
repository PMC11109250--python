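import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from homomap import SimulationConfig, simulate_species_pair


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully featured two-species study: 4 types, 3 shared."""
    return SimulationConfig(
        n_genes=400,
        n_types_a=4,
        n_types_b=4,
        n_shared=3,
        cells_per_type=40,
        markers_per_type=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def species_pair(small_cfg):
    return simulate_species_pair(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
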