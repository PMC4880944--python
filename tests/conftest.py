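import numpy as np
import pytest

import clockcv as cc
from clockcv.trees import TimeTree


@pytest.fixture
def rng():
    return np.random.default_rng(20160526)


@pytest.fixture
def two_taxon_tree():
    # A and B, both sampled at present, root at 50 years
    return TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 50.0])


@pytest.fixture
def four_taxon_tree():
    # ((A,B),(C,D)) with internal nodes at 10, 20 and root 30
    parent = [4, 4, 5, 5, 6, 6, -1]
    age = [0.0, 0.0, 0.0, 0.0, 10.0, 20.0, 30.0]
    return TimeTree(["A", "B", "C", "D"], parent, age)


def random_time_tree(n_taxa, rng, pop_size=10.0):
    demo = cc.DemographicModel(kind="CSC", pop_size=pop_size)
    return cc.simulate_coalescent_tree(n_taxa, demo, rng)


@pytest.fixture
def simulated_sc_data(rng):
    """12-taxon SC/CSC dataset: (chronogram, rates, alignment)."""
    demo = cc.DemographicModel(kind="CSC", pop_size=50.0)
    tree = cc.simulate_coalescent_tree(12, demo, rng)
    tree = cc.rescale_root_age(tree, 100.0)
    clock = cc.ClockModel(kind="SC", mean_rate=1e-3)
    rates = cc.assign_branch_rates(tree, clock, rng)
    aln = cc.simulate_alignment(
        cc.chronogram_to_phylogram(tree, rates), cc.JC(), 800, rng
    )
    return tree, rates, aln
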