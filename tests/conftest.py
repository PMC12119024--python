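import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gametiq import (
    SimConfig,
    simulate_marker_matrix,
    simulate_truth_haplotypes,
)


@pytest.fixture(scope="session")
def small_pool():
    """A modest pool on one 30 Mb chromosome with light ambient noise."""
    config = SimConfig(
        chromosome_lengths={"chr1": 30_000_000},
        n_nuclei=120,
        seed=11,
        ambient_fraction=0.05,
    )
    truth = simulate_truth_haplotypes(config)
    markers = simulate_marker_matrix(truth, config)
    return config, truth, markers


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
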