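"""Synthetic two-clade trees and trait data with the structure the tests assume.

The generators emulate the shape of the sea-snake analysis inputs — an
ultrametric tree whose root splits into a small reference clade and a large
focal clade (default 9 vs 34 tips, the split reported for the study's main
phylogeny), with two continuous traits evolving along the branches — without
imitating any real taxonomy or measurement scale.

Trait scenarios:

* ``bm``             — homogeneous Brownian motion in both clades (the null);
* ``rate-shift``     — BM with the focal clade's rate multiplied by ``r**2``,
  so morphometric branch lengths scale by ``r`` (unequal *magnitude*);
* ``ou-constrained`` — the reference clade evolves under a mean-reverting
  Ornstein–Uhlenbeck process (constrained), the focal clade under BM
  (unequal *mode*).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .balance import simulate_yule_tree
from .tree_io import CladePartition, write_tree

__all__ = [
    "SyntheticScenario",
    "make_two_clade_tree",
    "simulate_traits",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic dataset."""

    n_focal: int = 34
    n_reference: int = 9
    trait_model: str = "bm"       # bm | rate-shift | ou-constrained
    sigma2: float = 1.0           # BM rate (trait units^2 per unit depth)
    rate_multiplier: float = 2.0  # r: focal-clade rate is sigma2 * r**2
    alpha_ou: float = 5.0         # OU mean reversion (per unit depth)
    root_values: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_focal < 3 or self.n_reference < 3:
            raise ValueError("both clades need at least 3 tips")
        if self.sigma2 <= 0 or self.rate_multiplier <= 0 or self.alpha_ou < 0:
            raise ValueError("invalid scenario parameters")
        if self.trait_model not in ("bm", "rate-shift", "ou-constrained"):
            raise ValueError(f"unknown trait model {self.trait_model!r}")


def _scale_depth(tree: dendropy.Tree, target: float) -> float:
    """Scale all branch lengths so the maximum root-to-tip depth is *target*."""
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    f = target / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
    return f


def make_two_clade_tree(
    n_focal: int = 34,
    n_reference: int = 9,
    rng: np.random.Generator | int | None = None,
) -> tuple[dendropy.Tree, CladePartition]:
    """Ultrametric pure-birth tree whose root splits into the two clades.

    Each clade is an independent Yule tree scaled to a common crown depth
    (0.8), joined by stem branches of 0.2, so the total depth is 1.0.  Focal
    tips are labelled ``F1..Fn``, reference tips ``R1..Rn``.
    """
    if n_focal < 3 or n_reference < 3:
        raise ValueError("both clades need at least 3 tips")
    rng = np.random.default_rng(rng)
    crown, stem = 0.8, 0.2
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    for prefix, n_tips in (("F", n_focal), ("R", n_reference)):
        sub = simulate_yule_tree(n_tips, rng)
        _scale_depth(sub, crown)
        node = sub.seed_node
        node.edge.length = stem
        for j, lf in enumerate(node.leaf_iter()):
            lf.taxon = tns.require_taxon(label=f"{prefix}{j + 1}")
        tree.seed_node.add_child(node)
    tree.update_taxon_namespace()
    partition = CladePartition(
        focal=frozenset(f"F{i + 1}" for i in range(n_focal)),
        reference=frozenset(f"R{i + 1}" for i in range(n_reference)))
    return tree, partition


def _branch_step(x0: np.ndarray, length: float, model: str, sigma2: float,
                 alpha: float, theta: float,
                 rng: np.random.Generator) -> np.ndarray:
    if model == "bm" or alpha == 0.0:
        return x0 + rng.standard_normal(x0.shape) * np.sqrt(sigma2 * length)
    # exact OU transition
    decay = np.exp(-alpha * length)
    var = sigma2 * (1.0 - np.exp(-2.0 * alpha * length)) / (2.0 * alpha)
    mean = theta + (x0 - theta) * decay
    return mean + rng.standard_normal(x0.shape) * np.sqrt(var)


def simulate_traits(
    tree: dendropy.Tree,
    partition: CladePartition,
    scenario: SyntheticScenario,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate the scenario's two traits along the tree.

    The clade-specific process applies to every branch inside a clade
    including its stem; branches ancestral to both clades (none, for trees
    from :func:`make_two_clade_tree`) evolve under baseline BM.  The OU
    optimum is the root value of each trait.
    """
    rng = np.random.default_rng(rng)
    focal, ref = set(partition.focal), set(partition.reference)
    values: dict[int, np.ndarray] = {}
    root = tree.seed_node
    values[id(root)] = np.asarray(scenario.root_values, dtype=float)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        tips_below = {lf.taxon.label for lf in node.leaf_iter()}
        if tips_below <= focal:
            if scenario.trait_model == "rate-shift":
                model, s2, a = "bm", scenario.sigma2 * scenario.rate_multiplier**2, 0.0
            else:
                model, s2, a = "bm", scenario.sigma2, 0.0
        elif tips_below <= ref:
            if scenario.trait_model == "ou-constrained":
                model, s2, a = "ou", scenario.sigma2, scenario.alpha_ou
            else:
                model, s2, a = "bm", scenario.sigma2, 0.0
        else:
            model, s2, a = "bm", scenario.sigma2, 0.0
        x = np.empty(2)
        for j in range(2):
            x[j] = _branch_step(values[id(node.parent_node)][j:j + 1],
                                node.edge.length or 0.0, model, s2, a,
                                scenario.root_values[j], rng)[0]
        values[id(node)] = x
    rows = {lf.taxon.label: values[id(lf)] for lf in tree.leaf_node_iter()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["body_shape", "body_size"])
    return df.sort_index()


def write_fixture_bundle(
    path,
    scenario: SyntheticScenario | None = None,
    n_sample_trees: int = 20,
) -> dict[str, Path]:
    """Write a self-describing synthetic dataset to *path*.

    Files: ``tree.nwk`` (the main tree), ``trees_sample.nex``
    (*n_sample_trees* independent pure-birth trees on the same taxa, the
    stand-in for a posterior sample), ``traits.csv``, ``clade_focal.txt``,
    ``clade_reference.txt`` and ``scenario.json`` (full provenance including
    the seed; regenerating from it is bit-identical).
    """
    if scenario is None:
        scenario = SyntheticScenario()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    tree, partition = make_two_clade_tree(scenario.n_focal,
                                          scenario.n_reference, rng)
    traits = simulate_traits(tree, partition, scenario, rng)
    sample = dendropy.TreeList(taxon_namespace=dendropy.TaxonNamespace())
    for _ in range(n_sample_trees):
        t, _p = make_two_clade_tree(scenario.n_focal, scenario.n_reference,
                                    rng)
        sample.append(dendropy.Tree.get(
            data=write_tree(t), schema="newick", rooting="default-rooted",
            taxon_namespace=sample.taxon_namespace))
    files = {
        "tree": out / "tree.nwk",
        "trees_sample": out / "trees_sample.nex",
        "traits": out / "traits.csv",
        "clade_focal": out / "clade_focal.txt",
        "clade_reference": out / "clade_reference.txt",
        "scenario": out / "scenario.json",
    }
    write_tree(tree, files["tree"])
    sample.write(path=str(files["trees_sample"]), schema="nexus")
    traits.to_csv(files["traits"], index_label="taxon")
    files["clade_focal"].write_text(
        "\n".join(sorted(partition.focal)) + "\n")
    files["clade_reference"].write_text(
        "\n".join(sorted(partition.reference)) + "\n")
    files["scenario"].write_text(
        json.dumps({"n_sample_trees": n_sample_trees, **asdict(scenario)},
                   indent=2) + "\n")
    return files
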