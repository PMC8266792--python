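import numpy as np
import pytest

from clscreen import SimConfig, simulate_screen
from clscreen.counts import CountTensor


@pytest.fixture(scope="session")
def small_screen():
    """A small, fully well-amplified simulated screen with its truth."""
    cfg = SimConfig(n_strains=100, read_depth=100_000, seed=11,
                    amp_well_fraction=1.0, amp_well_efficiency=1.0)
    return simulate_screen(cfg)


@pytest.fixture
def toy_tensor():
    """2 strains x 2 envs x 1 replicate x 2 timepoints, hand-set counts."""
    counts = np.array([
        [[[30, 10]], [[5, 5]]],
        [[[70, 90]], [[95, 95]]],
    ])
    return CountTensor(counts, ["ORF-A", "ORF-B"], ["G", "H"], [1], [0.0, 7.0])
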