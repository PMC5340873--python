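import numpy as np
import pytest

from basementvirome.synthetic import make_toy_taxonomy, table1_fixture
from basementvirome.taxonomy import RANK_LADDER, TaxNode, TaxonomyTree


@pytest.fixture(scope="session")
def toy():
    """(tree, virus_host_map) for the packaged toy taxonomy."""
    return make_toy_taxonomy()


@pytest.fixture(scope="session")
def tree(toy):
    return toy[0]


@pytest.fixture(scope="session")
def virus_host_map(toy):
    return toy[1]


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def random_tree(rng: np.random.Generator, n_nodes: int = 30) -> TaxonomyTree:
    """Random taxonomy respecting the rank-monotonicity invariant."""
    nodes = [TaxNode("n0", "root", "root", None)]
    depths = {"n0": 0}
    for i in range(1, n_nodes):
        parent = f"n{rng.integers(0, i)}"
        pdepth = depths[parent]
        if pdepth >= len(RANK_LADDER) - 1:
            rank = "no_rank"
            depth = pdepth
        else:
            choices = list(range(pdepth + 1, len(RANK_LADDER)))
            if rng.random() < 0.15:
                rank, depth = "no_rank", pdepth
            else:
                depth = int(rng.choice(choices))
                rank = RANK_LADDER[depth]
        taxid = f"n{i}"
        nodes.append(TaxNode(taxid, taxid, rank, parent,
                             classified=bool(rng.random() < 0.8)))
        depths[taxid] = depth
    return TaxonomyTree(nodes)
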