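import numpy as np
import pytest

from probdist import (
    TreeModelPair,
    cfn_model,
    parse_newick,
    sample_edge_lengths,
    yule_topology,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cfn():
    return cfn_model()


@pytest.fixture
def small_pair(cfn):
    """Two fixed 3-taxon CFN tree-model pairs with a moderate distance."""
    t1 = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
    t2 = parse_newick("((A:0.2,B:0.1):0.1,C:0.2);")
    return TreeModelPair(t1, cfn), TreeModelPair(t2, cfn)


def random_cfn_pair(n_taxa, seed, mean=0.1, var=0.005):
    """Two random Yule trees on shared taxa, Gamma edge lengths, CFN model."""
    rng = np.random.default_rng(seed)
    model = cfn_model()
    t1 = sample_edge_lengths(yule_topology(n_taxa, rng), mean, var, rng)
    t2 = sample_edge_lengths(yule_topology(n_taxa, rng), mean, var, rng)
    return TreeModelPair(t1, model), TreeModelPair(t2, model)
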