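"""Tree and trait-table input/output and preparation.

Trees are :class:`dendropy.Tree` objects throughout the package ("PhyloTree"
in the docs): rooted, with unique non-empty tip labels and non-negative
branch lengths.  This module validates those invariants on read, and provides
the preparation steps every analysis starts from — pruning to a taxon set,
ultrametricization, and monophyletic clade extraction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "CladePartition",
    "TreeError",
    "read_tree",
    "read_trees",
    "parse_tree",
    "write_tree",
    "read_traits",
    "read_clade_list",
    "prune_to_taxa",
    "ultrametricize",
    "extract_clade",
    "tip_labels",
    "tip_depths",
    "check_monophyly",
]


class TreeError(ValueError):
    """A tree violates an invariant (duplicate labels, negative lengths, ...)."""


@dataclass(frozen=True)
class CladePartition:
    """Two disjoint, non-empty tip sets defining the focal and reference clades.

    Both sets must be monophyletic on the pruned two-clade tree; use
    :func:`check_monophyly` or :func:`extract_clade` to verify.
    """

    focal: frozenset[str]
    reference: frozenset[str]

    def __post_init__(self) -> None:
        if not self.focal or not self.reference:
            raise TreeError("clade tip sets must be non-empty")
        if self.focal & self.reference:
            raise TreeError(
                f"clade tip sets overlap: {sorted(self.focal & self.reference)}"
            )

    @property
    def all_taxa(self) -> frozenset[str]:
        return self.focal | self.reference


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lb is None or not str(lb).strip() for lb in labels):
        raise TreeError("every tip must carry a non-empty label")
    if len(set(labels)) != len(labels):
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            if not np.isfinite(edge.length):
                raise TreeError("non-finite branch length")
            if edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
    # trim surrounding whitespace; exact matching afterwards
    for taxon in tree.taxon_namespace:
        taxon.label = taxon.label.strip()
    return tree


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a single Newick string into a validated rooted tree."""
    return read_tree(io.StringIO(newick), schema="newick")


def read_tree(source, schema: Literal["newick", "nexus"] = "newick") -> dendropy.Tree:
    """Read one rooted tree from a file path or handle.

    Newick input without an explicit rooting comment is treated as rooted
    (the convention for MCC and simulated trees); an explicit ``[&U]``
    unrooted annotation is rejected.
    """
    kwargs = dict(schema=schema, rooting="default-rooted",
                  suppress_internal_node_taxa=True)
    try:
        if hasattr(source, "read"):
            tree = dendropy.Tree.get(file=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(source), **kwargs)
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeError(f"tree parse failure: {exc}") from exc
    if not tree.is_rooted:
        raise TreeError("unrooted trees are not supported")
    return _validate(tree)


def read_trees(source, schema: Literal["newick", "nexus"] = "nexus") -> list[dendropy.Tree]:
    """Read a collection of trees (e.g. a posterior sample) sharing one namespace."""
    if hasattr(source, "read"):
        tl = dendropy.TreeList.get(file=source, schema=schema,
                                   rooting="default-rooted")
    else:
        tl = dendropy.TreeList.get(path=str(source), schema=schema,
                                   rooting="default-rooted")
    return [_validate(t) for t in tl]


def write_tree(tree: dendropy.Tree, path=None) -> str:
    """Serialize to Newick (with branch lengths); write to *path* if given."""
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(s)
    return s


def read_traits(source) -> pd.DataFrame:
    """Read a trait table: column 1 = taxon label, remaining columns numeric.

    Accepts CSV or TSV (sniffed).  Returns a DataFrame indexed by taxon label
    with float trait columns; missing values raise.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    df.iloc[:, 0] = df.iloc[:, 0].astype(str).str.strip()
    df = df.set_index(df.columns[0])
    df = df.astype(float)
    if df.index.duplicated().any():
        raise TreeError(f"duplicate taxa in trait table: "
                        f"{sorted(df.index[df.index.duplicated()])}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise TreeError(f"missing trait values for taxa: {bad}")
    return df


def read_clade_list(source) -> frozenset[str]:
    """Read clade membership: one label per line (or first CSV column)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    labels = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        labels.append(line.split(",")[0].strip())
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate labels in clade list")
    return frozenset(labels)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path lengths, keyed by tip label."""
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depth[id(node)]
    return out


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict the tree to *keep*, suppressing degree-2 nodes.

    Path lengths between retained tips are preserved: suppressed unifurcation
    edges have their lengths summed.
    """
    keep = {str(k).strip() for k in keep}
    present = set(tip_labels(tree))
    unknown = keep - present
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 taxa to prune to")
    sub = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True)
    sub.seed_node.edge.length = None  # no stem on a pruned analysis tree
    sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return _validate(sub)


def check_monophyly(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Node:
    """Return the MRCA of *tips* if they form a monophyletic group, else raise."""
    tips = {str(t).strip() for t in tips}
    unknown = tips - set(tip_labels(tree))
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    mrca = tree.mrca(taxon_labels=tips)
    descend = {lf.taxon.label for lf in mrca.leaf_iter()}
    if descend != tips:
        raise TreeError(
            f"tip set is not monophyletic: MRCA also contains "
            f"{sorted(descend - tips)}")
    return mrca


def extract_clade(tree: dendropy.Tree, tips: Iterable[str],
                  include_stem: bool = False) -> dendropy.Tree:
    """Return the subtree rooted at the MRCA of *tips*.

    By default the stem edge above the MRCA is dropped, so the result
    describes the clade's own diversification history; ``include_stem=True``
    retains the stem length on the new root edge.
    """
    tips = {str(t).strip() for t in tips}
    mrca = check_monophyly(tree, tips)
    stem_len = mrca.edge.length
    sub = tree.extract_tree_with_taxa_labels(labels=tips,
                                             suppress_unifurcations=True)
    sub.seed_node.edge.length = stem_len if include_stem else None
    sub.is_rooted = True
    sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return _validate(sub)


def ultrametricize(tree: dendropy.Tree,
                   method: Literal["extend", "nnls"] = "extend",
                   tol: float = 1e-8) -> dendropy.Tree:
    """Make all root-to-tip depths equal without changing the topology.

    ``extend`` lengthens only terminal branches up to the maximum depth — the
    usual correction for MCC trees that are non-ultrametric only through
    numerical summary noise.  ``nnls`` finds the non-negative edge lengths
    minimizing the sum of squared adjustments subject to equal depths.
    """
    depths = tip_depths(tree)
    if not depths or max(depths.values()) <= 0:
        raise TreeError("tree has non-positive total depth")
    for v in depths.values():
        if not np.isfinite(v):
            raise TreeError("non-finite branch lengths")
    if max(depths.values()) - min(depths.values()) <= tol:
        return tree
    out = tree.clone(depth=1)
    if method == "extend":
        target = max(depths.values())
        d2 = tip_depths(out)
        for lf in out.leaf_node_iter():
            lf.edge.length = (lf.edge.length or 0.0) + (target - d2[lf.taxon.label])
    elif method == "nnls":
        _ultrametricize_nnls(out)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _validate(out)


def _ultrametricize_nnls(tree: dendropy.Tree) -> None:
    """In-place least-squares ultrametricization with non-negative lengths.

    Variables are the edge lengths plus the common depth T; minimizes
    sum((l' - l)^2) subject to (path sums == T, l' >= 0), via SLSQP started
    from the observed lengths.
    """
    edges = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
    eidx = {id(nd): i for i, nd in enumerate(edges)}
    l0 = np.array([nd.edge.length or 0.0 for nd in edges])
    tips = [lf for lf in tree.leaf_node_iter()]
    # incidence: rows tips, cols edges, 1 if edge on root path of tip
    A = np.zeros((len(tips), len(edges)))
    for r, lf in enumerate(tips):
        nd = lf
        while nd is not tree.seed_node:
            A[r, eidx[id(nd)]] = 1.0
            nd = nd.parent_node
    n_e = len(edges)
    x0 = np.append(l0, (A @ l0).mean())

    def objective(x):
        d = x[:n_e] - l0
        return d @ d

    def grad(x):
        g = np.zeros(n_e + 1)
        g[:n_e] = 2 * (x[:n_e] - l0)
        return g

    cons = {"type": "eq",
            "fun": lambda x: A @ x[:n_e] - x[n_e],
            "jac": lambda x: np.hstack([A, -np.ones((len(tips), 1))])}
    bounds = [(0.0, None)] * n_e + [(1e-12, None)]
    res = minimize(objective, x0, jac=grad, method="SLSQP", bounds=bounds,
                   constraints=[cons], options={"maxiter": 500, "ftol": 1e-14})
    if not res.success:
        raise TreeError(f"NNLS ultrametricization failed: {res.message}")
    for nd, li in zip(edges, res.x[:n_e]):
        nd.edge.length = max(0.0, float(li))
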