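"""Topological diversification-rate test on the root split of a clade pair.

Under the equal-rates-Markov (ERM) null — every extant lineage equally
likely to speciate next, no extinction — the size of one root clade of an
n-tip tree is uniform on {1, ..., n-1}.  The test asks how often a simulated
tree is at least as lopsided at the root as the observed pair of sister
clades, i.e. P(min root clade <= k_small).

Two simulation engines are provided for each model:

* explicit tree simulators (:func:`simulate_yule_tree`,
  :func:`simulate_bd_tree_conditioned`) returning dendropy trees, and
* vectorized count-only engines used by :func:`balance_test` for large
  simulation counts; they follow the identical stochastic process but track
  only per-side tip counts.

The birth–death test is run by default on *complete* trees (extinct lineages
retained and counted in the balance): with reconstructed trees the topology
collapses to the ERM distribution and the test would be identical to the
pure-birth one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import dendropy
import numpy as np

__all__ = [
    "BalanceObservation",
    "DiversificationParams",
    "BalanceTestResult",
    "simulate_yule_tree",
    "simulate_bd_tree_conditioned",
    "root_balance",
    "erm_pvalue_analytic",
    "balance_test",
]


@dataclass(frozen=True)
class BalanceObservation:
    """An observed sister-clade species-number split: N = k_small + k_large."""

    n_total: int
    k_small: int

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("need at least 2 species in total")
        if not (1 <= self.k_small <= self.n_total - self.k_small):
            raise ValueError(
                f"k_small={self.k_small} must satisfy 1 <= k_small <= N/2 "
                f"(N={self.n_total})")

    @property
    def k_large(self) -> int:
        return self.n_total - self.k_small


@dataclass(frozen=True)
class DiversificationParams:
    """Per-lineage speciation/extinction rates for the simulated null."""

    birth: float = 1.0
    death: float = 0.0
    complete: bool = True  # retain extinct lineages as tips

    def __post_init__(self) -> None:
        if self.birth <= 0:
            raise ValueError("speciation rate must be positive")
        if self.death < 0:
            raise ValueError("extinction rate must be non-negative")
        if self.death >= self.birth:
            raise ValueError(
                f"death={self.death} must be < birth={self.birth} for a "
                "supercritical process conditioned on n extant tips")


@dataclass(frozen=True)
class BalanceTestResult:
    observation: BalanceObservation
    params: DiversificationParams
    n_sims: int
    p_empirical: float
    p_analytic: float | None  # ERM only
    se: float
    seed: int | None
    count_mode: str
    tail: str

    def to_dict(self) -> dict:
        return {
            "N": self.observation.n_total,
            "k_small": self.observation.k_small,
            "k_large": self.observation.k_large,
            "birth": self.params.birth,
            "death": self.params.death,
            "complete": self.params.complete,
            "count_mode": self.count_mode,
            "tail": self.tail,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "p_empirical": self.p_empirical,
            "p_analytic": self.p_analytic,
            "se": self.se,
        }


# ---------------------------------------------------------------------------
# explicit tree simulators


def simulate_yule_tree(n_tips: int, rng: np.random.Generator,
                       birth: float = 1.0) -> dendropy.Tree:
    """Simulate a pure-birth tree with exactly *n_tips* extant tips.

    Waiting times between speciations are Exp(k * birth) with k the current
    lineage count; the splitting lineage is uniform among extant lineages.
    Pendant branches are extended past the final speciation by one further
    Exp(n * birth) draw, so the tree is ultrametric with positive terminal
    branches.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    left, right = dendropy.Node(), dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    extant = [left, right]
    birth_times = {id(left): 0.0, id(right): 0.0}
    t = 0.0
    while len(extant) < n_tips:
        t += rng.exponential(1.0 / (len(extant) * birth))
        i = rng.integers(len(extant))
        parent = extant[i]
        parent.edge.length = t - birth_times[id(parent)]
        c1, c2 = dendropy.Node(), dendropy.Node()
        parent.add_child(c1)
        parent.add_child(c2)
        birth_times[id(c1)] = birth_times[id(c2)] = t
        extant[i] = c1
        extant.append(c2)
    t += rng.exponential(1.0 / (len(extant) * birth))
    for j, node in enumerate(extant):
        node.edge.length = t - birth_times[id(node)]
        node.taxon = tns.require_taxon(label=f"T{j + 1}")
    return tree


def simulate_bd_tree_conditioned(
    n_extant: int,
    params: DiversificationParams,
    rng: np.random.Generator,
    max_restarts: int = 10_000,
) -> dendropy.Tree:
    """Simulate a birth–death tree conditioned on reaching *n_extant* tips.

    Forward simulation from two crown lineages until the extant count first
    reaches *n_extant*; runs that go fully extinct are discarded and
    restarted (up to *max_restarts*).  With ``params.complete`` extinct
    lineages are retained as tips (labelled ``X*``); otherwise the tree is
    pruned to the extant survivors (the reconstructed tree).
    """
    if n_extant < 2:
        raise ValueError("need n_extant >= 2")
    birth, death = params.birth, params.death
    total_rate_per_lineage = birth + death
    for _attempt in range(max_restarts):
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = True
        left, right = dendropy.Node(), dendropy.Node()
        tree.seed_node.add_child(left)
        tree.seed_node.add_child(right)
        extant = [left, right]
        extinct: list[dendropy.Node] = []
        birth_times = {id(left): 0.0, id(right): 0.0}
        t = 0.0
        while 0 < len(extant) < n_extant:
            t += rng.exponential(1.0 / (len(extant) * total_rate_per_lineage))
            i = rng.integers(len(extant))
            node = extant[i]
            node.edge.length = t - birth_times[id(node)]
            if rng.random() < birth / total_rate_per_lineage:
                c1, c2 = dendropy.Node(), dendropy.Node()
                node.add_child(c1)
                node.add_child(c2)
                birth_times[id(c1)] = birth_times[id(c2)] = t
                extant[i] = c1
                extant.append(c2)
            else:
                extinct.append(node)
                extant.pop(i)
        if not extant:
            continue
        for j, node in enumerate(extant):
            node.edge.length = t - birth_times[id(node)]
            node.taxon = tns.require_taxon(label=f"T{j + 1}")
            node.annotations.add_new("extinct", False)
        for j, node in enumerate(extinct):
            node.taxon = tns.require_taxon(label=f"X{j + 1}")
            node.annotations.add_new("extinct", True)
        if not params.complete and extinct:
            keep = [nd.taxon for nd in extant]
            tree.retain_taxa(keep)
            tree.suppress_unifurcations()
        return tree
    raise RuntimeError(
        f"birth-death simulation failed to reach {n_extant} extant lineages "
        f"in {max_restarts} attempts")


def root_balance(tree: dendropy.Tree,
                 count: Literal["all_tips", "extant_only"] = "all_tips",
                 ) -> tuple[int, int]:
    """Tip counts descending from the two children of the root.

    ``extant_only`` skips tips flagged extinct by the birth–death simulator
    (tips without the flag count as extant).
    """
    children = tree.seed_node.child_nodes()
    if len(children) != 2:
        raise ValueError(
            f"root balance undefined: root has {len(children)} children")

    def _count(node: dendropy.Node) -> int:
        n = 0
        for lf in node.leaf_iter():
            if count == "extant_only":
                flag = lf.annotations.get_value("extinct", False)
                if flag in (True, "True"):
                    continue
            n += 1
        return n

    return _count(children[0]), _count(children[1])


# ---------------------------------------------------------------------------
# vectorized count-only engines


def _erm_root_sides(n_tips: int, n_sims: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-side root-clade sizes of n_sims ERM trees (Polya-urn recursion).

    Start with one lineage on each side of the root; at each of the n-2
    subsequent speciations the splitting lineage is uniform among extant
    lineages, so the left side gains a tip with probability left/total.
    """
    left = np.ones(n_sims, dtype=np.int64)
    for total in range(2, n_tips):
        left += rng.random(n_sims) * total < left
    return left, n_tips - left


def _bd_root_sides(n_extant: int, params: DiversificationParams,
                   n_sims: int, rng: np.random.Generator,
                   count_mode: str = "all_tips",
                   max_restarts: int = 10_000
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-side root-clade tip counts for conditioned birth–death trees.

    Tracks, per simulation, the extant and extinct tip counts on each side
    of the root; the continuous waiting times are irrelevant to the counts
    and are not generated.  Fully extinct runs restart (same conditioning as
    :func:`simulate_bd_tree_conditioned`).
    """
    p_birth = params.birth / (params.birth + params.death)
    a = np.ones(n_sims, dtype=np.int64)       # extant, side A
    b = np.ones(n_sims, dtype=np.int64)       # extant, side B
    da = np.zeros(n_sims, dtype=np.int64)     # extinct tips, side A
    db = np.zeros(n_sims, dtype=np.int64)
    restarts = np.zeros(n_sims, dtype=np.int64)
    active = np.ones(n_sims, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        tot = a[idx] + b[idx]
        pick_a = rng.random(idx.size) * tot < a[idx]
        is_birth = rng.random(idx.size) < p_birth
        a[idx] += (pick_a & is_birth)
        b[idx] += (~pick_a & is_birth)
        died_a = pick_a & ~is_birth
        died_b = ~pick_a & ~is_birth
        a[idx] -= died_a
        da[idx] += died_a
        b[idx] -= died_b
        db[idx] += died_b
        tot = a[idx] + b[idx]
        dead = idx[tot == 0]
        restarts[dead] += 1
        if restarts.max(initial=0) > max_restarts:
            raise RuntimeError("restart cap exceeded in birth-death engine")
        a[dead] = 1
        b[dead] = 1
        da[dead] = 0
        db[dead] = 0
        active[idx[tot >= n_extant]] = False
    if count_mode == "all_tips":
        return a + da, b + db
    return a, b


def erm_pvalue_analytic(obs: BalanceObservation,
                        tail: Literal["min_clade", "left"] = "min_clade",
                        ) -> float:
    """Closed-form ERM tail probability of a root split as extreme as *obs*.

    The root-clade size is uniform on {1, ..., N-1}, so
    P(min clade <= k) = min(1, 2k/(N-1)); the one-sided ``left`` variant
    P(left <= k) = k/(N-1) is exposed for completeness.
    """
    n, k = obs.n_total, obs.k_small
    if tail == "min_clade":
        return min(1.0, 2.0 * k / (n - 1))
    if tail == "left":
        return k / (n - 1)
    raise ValueError(f"unknown tail {tail!r}")


def balance_test(
    obs: BalanceObservation,
    params: DiversificationParams | None = None,
    n_sims: int = 100_000,
    rng: np.random.Generator | int | None = None,
    count_mode: Literal["all_tips", "extant_only"] = "all_tips",
    tail: Literal["min_clade", "left"] = "min_clade",
) -> BalanceTestResult:
    """Monte-Carlo root-balance test of the observed split against the null.

    Simulates *n_sims* trees with ``obs.n_total`` (extant) tips under the
    given diversification parameters and reports the fraction whose smaller
    root clade is at most ``obs.k_small`` tips.  Under the pure-birth ERM
    null the analytic tail probability is reported alongside.
    """
    if params is None:
        params = DiversificationParams()
    if n_sims < 1:
        raise ValueError("need n_sims >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    is_erm = params.death == 0.0
    if is_erm:
        # pure birth: no extinct tips; the split is rate-free (ERM)
        sides = _erm_root_sides(obs.n_total, n_sims, rng)
    else:
        eff_mode = ("all_tips" if params.complete and count_mode == "all_tips"
                    else "extant_only")
        sides = _bd_root_sides(obs.n_total, params, n_sims, rng,
                               count_mode=eff_mode)
    if tail == "min_clade":
        hits = np.minimum(*sides) <= obs.k_small
    else:
        # "left" is one side of the root; by symmetry of the simulation the
        # first side is an exchangeable choice
        hits = sides[0] <= obs.k_small
    p = float(np.mean(hits))
    se = float(np.sqrt(max(p * (1 - p), 1e-300) / n_sims))
    p_analytic = erm_pvalue_analytic(obs, tail) if is_erm else None
    return BalanceTestResult(
        observation=obs, params=params, n_sims=n_sims, p_empirical=p,
        p_analytic=p_analytic, se=se, seed=seed, count_mode=count_mode,
        tail=tail)
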