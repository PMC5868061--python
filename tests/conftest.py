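import numpy as np
import pytest
from hypothesis import settings

from ctenotrade import PairedSpawnReplicate, SimulationConfig, Treatment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A compact experiment: 5 blocks plus 6 sealed pairs."""
    return SimulationConfig(n_animals=25, n_sealed_pairs=6, seed=7)


def make_pairs(counts, treatment=Treatment.PERMEABLE):
    """Build paired replicates from a list of (eggs_a, eggs_b)."""
    return [
        PairedSpawnReplicate(f"R{i:02d}", treatment, a, b)
        for i, (a, b) in enumerate(counts)
    ]
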