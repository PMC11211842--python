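import numpy as np
import pytest

from branchscore.phylo import Tree, parse_newick
from branchscore.seqsim import (
    MSA,
    SimulationConfig,
    SubstitutionModel,
    sample_model,
    sample_tree,
    simulate_msa,
)


@pytest.fixture
def quartet():
    return parse_newick("((A:0.1,B:0.2):0.3,(C:0.1,D:0.2):0.1);")


@pytest.fixture
def caterpillar6():
    return parse_newick(
        "(((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1);"
    )


@pytest.fixture
def sim_config():
    return SimulationConfig()


def random_instance(seed, ntaxa=None, nsites=300, max_div=3.0, pinv=0.0):
    """Small simulated (tree, model, msa) triple for oracle tests."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(pinv_range=(pinv, pinv))
    if ntaxa is None:
        ntaxa = int(rng.integers(4, 7))
    tree = sample_tree(ntaxa, cfg, int(rng.integers(2**31)))
    tree.blen *= max_div / max(tree.total_divergence(), 1e-9)
    model = sample_model(cfg, int(rng.integers(2**31)))
    msa = simulate_msa(tree, model, nsites, int(rng.integers(2**31)))
    return tree, model, msa


@pytest.fixture
def two_taxon_jc():
    jc = SubstitutionModel.jc()
    tree = Tree.from_adjacency(["A", "B"], {0: [(1, 0.3)], 1: [(0, 0.3)]})
    return tree, jc
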