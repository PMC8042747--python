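import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from paracontrast.gene_trees import read_trees
from paracontrast.synthetic_data import (SimulationConfig, random_event_tree,
                                         simulate_trait)


@pytest.fixture
def cherry():
    """Two-tip tree with unequal branch lengths."""
    return read_trees("(A:4.0,B:5.0)[&&NHX:Ev=spec];")[0]


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2) with a speciation cherry under a speciation root."""
    return read_trees("((A:1,B:1)[&&NHX:Ev=spec]:1,C:2)[&&NHX:Ev=spec];")[0]


@pytest.fixture
def mixed_tree():
    """Ultrametric 4-tip tree with one duplication and two speciations."""
    return read_trees(
        "(((A:10,B:10)[&&NHX:Ev=dup]:20,C:30)[&&NHX:Ev=spec]:20,"
        "D:50)[&&NHX:Ev=spec];")[0]


def random_tree_and_bm_trait(n_tips, seed, height=100.0, p_dup=0.3,
                             sigma2=0.01):
    """Random event-tagged ultrametric tree plus one BM trait realisation."""
    rng = np.random.default_rng(seed)
    tree = random_event_tree(n_tips, height=height, p_dup=p_dup, seed=rng)
    traits = simulate_trait(
        tree, SimulationConfig(trait_model="BM1", sigma2=sigma2), seed=rng)
    return tree, traits


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
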