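import numpy as np
import pytest

import asmb
from asmb.simulate import SimulationConfig, simulate_dataset


def random_fixture(seed, max_tips=10, max_samples=6, min_tips=3, min_samples=2):
    """A small random (table, tree) pair for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n_tips = int(rng.integers(min_tips, max_tips + 1))
    n_samp = int(rng.integers(min_samples, max_samples + 1))
    tree = asmb.simulate_phylogeny(n_tips, seed=seed)
    otu_ids = [t.name for t in tree.tips()]
    counts = rng.integers(0, 20, size=(n_samp, n_tips))
    # every sample keeps at least one read
    for s in range(n_samp):
        if counts[s].sum() == 0:
            counts[s, int(rng.integers(n_tips))] = 1
    table = asmb.OtuTable([f"s{k}" for k in range(n_samp)], otu_ids, counts)
    return table, tree


@pytest.fixture
def tiny_table():
    return asmb.OtuTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C", "D"],
        np.array([[5, 3, 0, 2], [0, 4, 4, 2], [1, 1, 1, 1]]),
    )


@pytest.fixture
def cherry_tree():
    return asmb.read_newick("(A:1.0,B:1.0);")


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed-regime transect shared by read-only tests."""
    cfg = SimulationConfig(n_sites=8, n_otus=80, reads_per_sample=1000, seed=11)
    table, tree, md = simulate_dataset(cfg)
    return table, tree, md, cfg
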