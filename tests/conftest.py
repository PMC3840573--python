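import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from retrotrace.simulate import SimulationConfig, simulate_dataset, simulate_parental_transcript
from retrotrace.dating import load_primate_tree, load_mammal_tree


@pytest.fixture(scope="session")
def paper_shaped_transcript():
    """A transcript with the parental mRNA geometry (376 + 618 + 2481 nt)."""
    cfg = SimulationConfig(seed=11)
    return simulate_parental_transcript(cfg, np.random.default_rng(cfg.seed))


@pytest.fixture(scope="session")
def small_config_rates0():
    """Small, mutation-free study conditions for closed-loop checks."""
    return SimulationConfig(
        seed=7, n_taxa=4, utr5_len=60, cds_len=300, utr3_len=240,
        n_polya_signals=2, chromosome_length=5000, n_chromosomes=3,
        subst_rate=0.0, indel_rate=0.0, repeat_insert_rate=0.0,
    )


@pytest.fixture(scope="session")
def sim_rates0(small_config_rates0):
    return simulate_dataset(small_config_rates0)


@pytest.fixture(scope="session")
def primate_tree():
    return load_primate_tree()


@pytest.fixture(scope="session")
def mammal_tree():
    return load_mammal_tree()
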