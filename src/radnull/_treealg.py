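"""Array-backed view of a rooted tree for fast repeated computation.

The null pipeline evaluates ancestral states, branch lengths in trait space
and phylogenetic GLS fits tens of thousands of times on the same few trees;
:class:`TreeContext` converts a dendropy tree once into index arrays and
cached matrix factorizations so each evaluation is a handful of small dense
solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve, lu_factor, lu_solve


@dataclass
class CladeView:
    """Index arrays describing one clade inside a :class:`TreeContext`."""

    name: str
    mrca: int                 # node index of the clade MRCA
    nodes: np.ndarray         # all node indices in the clade subtree (incl. MRCA)
    tips: np.ndarray          # tip node indices in the clade
    edge_children: np.ndarray  # child-node index per clade branch (stem excluded)
    edge_parents: np.ndarray


class TreeContext:
    """Precomputed arrays and factorizations for one rooted tree.

    Node indexing is preorder (root = 0).  ``parent[i]`` is the parent node
    index (-1 for the root) and ``elen[i]`` the length of the edge above
    node ``i`` (0 for the root).
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.elen = np.zeros(self.n_nodes)
        self.is_tip = np.zeros(self.n_nodes, dtype=bool)
        tip_labels = []
        tip_idx = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                self.is_tip[i] = True
                tip_labels.append(nd.taxon.label)
                tip_idx.append(i)
        self.tip_labels: list[str] = tip_labels
        self.tip_index = np.array(tip_idx, dtype=np.int64)
        self.internal_index = np.flatnonzero(~self.is_tip)
        self._node_of = index
        self._nodes = nodes
        self.depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # preorder: parent precedes child
            self.depth[i] = self.depth[self.parent[i]] + self.elen[i]
        self._lap = None
        self._vcv_cho = None
        self._ones_Vinv = None
        self._tip_edge_incidence = None

    # -- structure ----------------------------------------------------------

    def node_index(self, node: dendropy.Node) -> int:
        return self._node_of[id(node)]

    def subtree_nodes(self, root_idx: int) -> np.ndarray:
        """All node indices in the subtree of *root_idx* (preorder contiguity
        does not hold in general, so walk parents)."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[root_idx] = True
        for i in range(root_idx + 1, self.n_nodes):
            p = self.parent[i]
            if p >= 0 and mask[p]:
                mask[i] = True
        return np.flatnonzero(mask)

    def mrca_index(self, tip_labels: set[str]) -> int:
        want = set(tip_labels)
        have = {lb: i for lb, i in zip(self.tip_labels, self.tip_index)}
        missing = want - have.keys()
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        # intersect root paths
        paths = []
        for lb in want:
            path = []
            i = have[lb]
            while i >= 0:
                path.append(i)
                i = self.parent[i]
            paths.append(set(path))
        common = set.intersection(*paths)
        # common ancestors form a chain along which preorder rank increases
        # towards the tips, so the deepest one has the largest index
        return max(common)

    def clade_view(self, name: str, tips: set[str]) -> CladeView:
        mrca = self.mrca_index(tips)
        nodes = self.subtree_nodes(mrca)
        node_tips = nodes[self.is_tip[nodes]]
        label_of = dict(zip(self.tip_index.tolist(), self.tip_labels))
        got = {label_of[i] for i in node_tips}
        if got != set(tips):
            raise ValueError(
                f"clade {name!r} is not monophyletic; MRCA subtree also "
                f"contains {sorted(got - set(tips))}")
        edge_children = nodes[nodes != mrca]
        return CladeView(name=name, mrca=mrca, nodes=nodes, tips=node_tips,
                         edge_children=edge_children,
                         edge_parents=self.parent[edge_children])

    # -- phylogenetic covariance and GLS ------------------------------------

    @property
    def vcv(self) -> np.ndarray:
        """Tip covariance under unit-rate BM: shared root-path lengths."""
        n = len(self.tip_index)
        V = np.zeros((n, n))
        pos = {i: r for r, i in enumerate(self.tip_index)}
        # accumulate depth of every common ancestor edge-by-edge
        tips_under = [set() for _ in range(self.n_nodes)]
        for r, i in enumerate(self.tip_index):
            tips_under[i].add(r)
        for i in range(self.n_nodes - 1, 0, -1):
            p = self.parent[i]
            under = tips_under[i]
            if under:
                rows = np.fromiter(under, dtype=np.int64)
                V[np.ix_(rows, rows)] += self.elen[i]
                tips_under[p] |= under
        return V

    def _ensure_gls(self) -> None:
        if self._vcv_cho is None:
            V = self.vcv
            self._vcv_cho = cho_factor(V)
            ones = np.ones(V.shape[0])
            self._ones_Vinv = cho_solve(self._vcv_cho, ones)

    def gls_intercept(self, y: np.ndarray) -> tuple[float, float, float]:
        """Intercept-only phylogenetic GLS: (beta, rss_quadform, denom).

        beta = (1'V^-1 1)^-1 1'V^-1 y; the quadratic form
        (y-beta)'V^-1(y-beta) is returned for the caller's variance divisor.
        """
        self._ensure_gls()
        w = self._ones_Vinv
        denom = float(w.sum())
        beta = float(w @ y) / denom
        r = y - beta
        q = float(r @ cho_solve(self._vcv_cho, r))
        return beta, q, denom

    # -- ancestral states under BM ------------------------------------------

    def _ensure_laplacian(self) -> None:
        if self._lap is not None:
            return
        if np.any(self.elen[1:] <= 0):
            raise ValueError(
                "ancestral-state reconstruction requires strictly positive "
                "branch lengths")
        m = self.n_nodes
        L = np.zeros((m, m))
        for i in range(1, m):
            p = self.parent[i]
            w = 1.0 / self.elen[i]
            L[i, i] += w
            L[p, p] += w
            L[i, p] -= w
            L[p, i] -= w
        I = self.internal_index
        T = self.tip_index
        self._L_IT = L[np.ix_(I, T)]
        self._lap = lu_factor(L[np.ix_(I, I)])

    def ancestral_states(self, tip_values: np.ndarray) -> np.ndarray:
        """ML (GLS) ancestral states under BM for one trait.

        *tip_values* is ordered as ``tip_labels``; returns a vector over all
        nodes (tips carry their observed values).  The joint ML states
        minimize sum((x_child - x_parent)^2 / branch_length), a weighted
        graph-Laplacian system solved with a cached LU factorization.
        """
        self._ensure_laplacian()
        x = np.empty(self.n_nodes)
        x[self.tip_index] = tip_values
        x[self.internal_index] = lu_solve(self._lap, -self._L_IT @ tip_values)
        return x

    # -- BM simulation --------------------------------------------------------

    def _ensure_incidence(self) -> None:
        if self._tip_edge_incidence is None:
            R = np.zeros((len(self.tip_index), self.n_nodes))
            for r, i in enumerate(self.tip_index):
                j = i
                while j > 0:
                    R[r, j] = 1.0
                    j = self.parent[j]
            self._tip_edge_incidence = R

    def simulate_bm_tips(self, root_value: float, sigma2: float,
                         rng: np.random.Generator) -> np.ndarray:
        """Tip values of one BM realization (root at *root_value*)."""
        if sigma2 < 0:
            raise ValueError("BM rate must be non-negative")
        self._ensure_incidence()
        inc = rng.standard_normal(self.n_nodes) * np.sqrt(sigma2 * self.elen)
        inc[0] = 0.0
        return root_value + self._tip_edge_incidence @ inc
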