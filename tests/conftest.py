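import numpy as np
import pytest

from alienphylo import parse_newick, patristic_distances
from alienphylo.simulate import simulate_yule_tree

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def toy_tree():
    """Balanced 4-tip ultrametric tree with two cherries at height 1."""
    return parse_newick(TOY_NEWICK)


@pytest.fixture
def toy_pm(toy_tree):
    return patristic_distances(toy_tree)


@pytest.fixture(scope="session")
def yule100():
    return simulate_yule_tree(100, birth_rate=1.0, seed=20240901)


@pytest.fixture(scope="session")
def yule100_pm(yule100):
    return patristic_distances(yule100)


def random_tree(rng, n_tips, ultrametric=False):
    """Random tree for oracle tests: Yule topology, then (optionally)
    branch lengths redrawn uniformly so trees are not ultrametric."""
    t = simulate_yule_tree(n_tips, seed=int(rng.integers(2**31)))
    if not ultrametric:
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.05, 2.0))
    return t


def brute_force_patristic(tree, labels):
    """Independent path-walk oracle: climb parent chains from both tips to
    the root, trim the common suffix, and sum the remaining edges."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[labels[i]], paths[labels[j]]
            si, sj = set(id(x) for x in pi), set(id(x) for x in pj)
            d = sum((x.edge.length or 0.0) for x in pi if id(x) not in sj)
            d += sum((x.edge.length or 0.0) for x in pj if id(x) not in si)
            out[i, j] = out[j, i] = d
    return out
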