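import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from circlescan.synthetic_data import (
    SimConfig,
    simulate_genome,
    simulate_long_reads,
    simulate_molecules,
)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def sim_small():
    """Scaled-down two-circle genome with planted repeats (no recombinants)."""
    cfg = SimConfig.small(seed=11)
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def sim_clean_reads():
    """Error-free reads from master circles only (zero planted recombination)."""
    cfg = SimConfig.small(seed=23, depth=12, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
    genome, truth = simulate_genome(cfg)
    molecules = simulate_molecules(genome, truth, cfg)
    paths = simulate_long_reads(molecules, genome, cfg, truth=truth)
    return cfg, genome, truth, paths
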