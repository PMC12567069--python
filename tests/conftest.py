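"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

import radnull as rn
from radnull._treealg import TreeContext


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return rn.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_scenario(rng):
    """A 9-vs-6 two-clade tree with homogeneous BM traits."""
    tree, partition = rn.make_two_clade_tree(9, 6, rng)
    scenario = rn.SyntheticScenario(n_focal=9, n_reference=6)
    traits = rn.simulate_traits(tree, partition, scenario, rng)
    return tree, partition, traits


@pytest.fixture
def study_scenario():
    """A 34-vs-9 two-clade tree matching the study's taxon split."""
    rng = np.random.default_rng(777)
    tree, partition = rn.make_two_clade_tree(34, 9, rng)
    scenario = rn.SyntheticScenario(n_focal=34, n_reference=9)
    traits = rn.simulate_traits(tree, partition, scenario, rng)
    return tree, partition, traits


def _node_shared_path_cov(tree):
    """Shared root-path covariance over all nodes, built by direct traversal.

    C[u, v] = root-to-MRCA(u, v) path length, computed independently of the
    package's array machinery: per-node root paths are accumulated by
    walking parent pointers on the dendropy tree itself.
    """
    nodes = list(tree.preorder_node_iter())
    paths = []
    for nd in nodes:
        chain = []
        cur = nd
        while cur is not None:
            chain.append(cur)
            cur = cur.parent_node
        depth = 0.0
        anc_depths = {}
        for anc in reversed(chain):  # root first
            if anc.parent_node is not None:
                depth += anc.edge.length or 0.0
            anc_depths[id(anc)] = depth
        paths.append(anc_depths)
    m = len(nodes)
    C = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            shared = set(paths[i]) & set(paths[j])
            C[i, j] = max(paths[i][s] for s in shared)
    return nodes, C


def dense_gls_ancestral_oracle(tree, y_by_label):
    """Independent dense-matrix GLS oracle for BM ancestral states.

    Estimates the root as the GLS intercept over the tip covariance block V
    and reconstructs internal states as beta + C_IT V^-1 (y - beta).
    Returns (beta, {node_id: state}) keyed by dendropy node identity.
    """
    nodes, C = _node_shared_path_cov(tree)
    tip_rows = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
    int_rows = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    y = np.array([y_by_label[nodes[i].taxon.label] for i in tip_rows])
    V = C[np.ix_(tip_rows, tip_rows)]
    Vinv = np.linalg.inv(V)
    ones = np.ones(len(y))
    beta = float(ones @ Vinv @ y) / float(ones @ Vinv @ ones)
    anc = beta + C[np.ix_(int_rows, tip_rows)] @ Vinv @ (y - beta)
    states = {id(nodes[i]): y[k] for k, i in enumerate(tip_rows)}
    states.update({id(nodes[i]): anc[k] for k, i in enumerate(int_rows)})
    return beta, states


def dense_pgls_oracle(tree, y_by_label, divisor="reml"):
    """Independent dense-solve oracle for the intercept-only PGLS fit."""
    nodes, C = _node_shared_path_cov(tree)
    tip_rows = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
    y = np.array([y_by_label[nodes[i].taxon.label] for i in tip_rows])
    V = C[np.ix_(tip_rows, tip_rows)]
    Vinv = np.linalg.inv(V)
    ones = np.ones(len(y))
    beta = float(ones @ Vinv @ y) / float(ones @ Vinv @ ones)
    r = y - beta
    d = len(y) - 1 if divisor == "reml" else len(y)
    return beta, float(r @ Vinv @ r) / d
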