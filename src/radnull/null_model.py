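"""Permutation + PGLS + Brownian-motion null for the disparity ratios.

The null asks what M- and D-ratios look like when the trait data carry no
clade structure at all and evolve by homogeneous Brownian motion.  Each
iteration:

1. draws one tree uniformly (with replacement) from the supplied tree set
   (a posterior sample, pruned and ultrametricized beforehand);
2. permutes each observed trait column independently across all taxa,
   destroying any phylogenetic and clade signal while keeping the empirical
   trait distribution;
3. fits an intercept-only phylogenetic GLS to each permuted trait to obtain
   a root state and a BM rate;
4. simulates new tip values under BM with the fitted (root, rate);
5. recomputes the M- and D-ratios exactly as for the observed data.

Empirical p-values use a +1 pseudo-count, p = (1 + #{null >= obs})/(1 + n),
so a finite null sample never reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._treealg import TreeContext
from .morphospace import (DegenerateMorphospaceError, _clade_stats,
                          _project_array, disparity_ratios)
from .tree_io import CladePartition, TreeError

__all__ = [
    "PGLSFit",
    "NullDistribution",
    "permute_traits",
    "fit_pgls_intercept",
    "simulate_bm",
    "build_null",
    "ratio_pvalue",
]


@dataclass(frozen=True)
class PGLSFit:
    """Intercept-only phylogenetic GLS fit: root state and BM rate."""

    beta: float    # root (ancestral mean) estimate, trait units
    sigma2: float  # BM rate, trait units^2 per branch-length unit
    n: int
    divisor: str   # "reml" (n-1) or "ml" (n)


@dataclass
class NullDistribution:
    """Simulated null samples of both ratios with observed values and p-values."""

    m_ratios: np.ndarray
    d_ratios: np.ndarray
    observed_m: float
    observed_d: float
    p_m: float
    p_d: float
    n_iter: int
    n_skipped: int
    seed: int | None
    tail: str
    alpha: float = 0.05
    settings: dict = field(default_factory=dict)

    @property
    def significant_m(self) -> bool:
        return self.p_m <= self.alpha

    @property
    def significant_d(self) -> bool:
        return self.p_d <= self.alpha


def permute_traits(traits: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Independently permute each trait column across taxa (labels fixed)."""
    if len(traits) < 2:
        raise ValueError("need at least 2 taxa")
    out = traits.copy()
    for col in out.columns:
        out[col] = rng.permutation(out[col].to_numpy())
    return out


def fit_pgls_intercept(tree_or_ctx, y,
                       divisor: Literal["reml", "ml"] = "reml") -> PGLSFit:
    """Fit an intercept-only PGLS under BM to one trait column.

    With V the matrix of shared root-to-tip path lengths,
    beta = (1'V^-1 1)^-1 1'V^-1 y and
    sigma2 = (y - beta)'V^-1(y - beta) / d, d = n-1 (reml, default) or n (ml).
    *y* may be a pandas Series (aligned by taxon label) or an array ordered
    as the tree's tips.
    """
    ctx = tree_or_ctx if isinstance(tree_or_ctx, TreeContext) \
        else TreeContext(tree_or_ctx)
    n = len(ctx.tip_index)
    if n < 3:
        raise ValueError("need at least 3 tips for a PGLS fit")
    if isinstance(y, pd.Series):
        y = y.loc[list(ctx.tip_labels)].to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape != (n,):
            raise ValueError("trait vector length must match tip count")
    beta, q, _ = ctx.gls_intercept(y)
    d = n - 1 if divisor == "reml" else n
    if divisor not in ("reml", "ml"):
        raise ValueError(f"unknown divisor {divisor!r}")
    return PGLSFit(beta=beta, sigma2=max(q / d, 0.0), n=n, divisor=divisor)


def simulate_bm(tree_or_ctx, beta: float, sigma2: float,
                rng: np.random.Generator) -> pd.Series:
    """Simulate one BM trait on the tree: tip = beta + sum of branch increments.

    Each branch contributes an independent Normal(0, sigma2 * length)
    increment.  Returns a Series indexed by tip label.
    """
    ctx = tree_or_ctx if isinstance(tree_or_ctx, TreeContext) \
        else TreeContext(tree_or_ctx)
    vals = ctx.simulate_bm_tips(beta, sigma2, rng)
    return pd.Series(vals, index=list(ctx.tip_labels))


@dataclass
class _CtxCache:
    """Per-tree precomputation for the null loop."""

    ctx: TreeContext
    focal_view: object
    ref_view: object


def _prepare_contexts(trees: Sequence[dendropy.Tree],
                      partition: CladePartition) -> list[_CtxCache]:
    caches = []
    want = set(partition.all_taxa)
    for t in trees:
        ctx = TreeContext(t)
        if set(ctx.tip_labels) != want:
            raise TreeError(
                "every tree must be pruned to the two-clade taxon set")
        caches.append(_CtxCache(
            ctx=ctx,
            focal_view=ctx.clade_view("focal", set(partition.focal)),
            ref_view=ctx.clade_view("reference", set(partition.reference))))
    return caches


def build_null(
    trees: Sequence[dendropy.Tree],
    traits: pd.DataFrame,
    partition: CladePartition,
    n_iter: int = 100_000,
    rng: np.random.Generator | int | None = None,
    transform: Literal["raw", "log10"] = "raw",
    tail: Literal["upper", "two_sided"] = "upper",
    ellipse_points: Literal["all", "tips"] = "all",
    ellipse_tol: float = 1e-7,
    divisor: Literal["reml", "ml"] = "reml",
    alpha: float = 0.05,
    max_skip_fraction: float = 0.01,
) -> NullDistribution:
    """Simulate the null distribution of M- and D-ratios and test the observed.

    The observed ratios are computed on the first tree in *trees* (by
    convention the MCC tree); the null iterates permutation -> PGLS -> BM
    simulation -> ratios as described in the module docstring.  Iterations
    with a degenerate (zero-area) morphospace are retried once with fresh
    randomness, then skipped and counted; if more than
    ``max_skip_fraction`` of iterations are skipped the run aborts, since
    silent skipping would bias the null.
    """
    if n_iter < 1:
        raise ValueError("need n_iter >= 1")
    if not trees:
        raise ValueError("need at least one tree")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    caches = _prepare_contexts(trees, partition)

    labels = list(caches[0].ctx.tip_labels)
    traits = traits.loc[labels].iloc[:, :2].astype(float)
    if transform == "log10":
        if (traits.to_numpy() <= 0).any():
            raise ValueError("log10 transform requires positive trait values")
        traits = np.log10(traits)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")

    trait_names = tuple(traits.columns[:2])

    def _ratios_for(cache: _CtxCache, tip_xy: np.ndarray):
        proj = _project_array(cache.ctx, tip_xy, trait_names)
        focal = _clade_stats(proj, cache.focal_view, ellipse_points,
                             ellipse_tol)
        ref = _clade_stats(proj, cache.ref_view, ellipse_points, ellipse_tol)
        r = disparity_ratios(focal, ref, transform=transform)
        return r.M_ratio, r.D_ratio

    obs_vals = traits.loc[list(caches[0].ctx.tip_labels)].to_numpy()
    observed_m, observed_d = _ratios_for(caches[0], obs_vals)

    perm_vals = traits.to_numpy()  # rows ordered as caches[0] tips
    order_of = {lb: i for i, lb in enumerate(labels)}
    row_orders = [np.array([order_of[lb] for lb in c.ctx.tip_labels])
                  for c in caches]
    m_null = np.empty(n_iter)
    d_null = np.empty(n_iter)
    n = len(labels)
    n_ok = 0
    n_skipped = 0
    for _ in range(n_iter):
        done = False
        for _retry in range(2):
            t = int(rng.integers(len(caches)))
            cache = caches[t]
            ctx = cache.ctx
            # independent permutation of each trait column across taxa
            y = np.column_stack([
                perm_vals[rng.permutation(n), j] for j in (0, 1)
            ])[row_orders[t]]
            sim = np.empty_like(y)
            try:
                for j in range(2):
                    fit = fit_pgls_intercept(ctx, y[:, j], divisor=divisor)
                    sim[:, j] = ctx.simulate_bm_tips(fit.beta, fit.sigma2, rng)
                m, dr = _ratios_for(cache, sim)
            except (DegenerateMorphospaceError, ZeroDivisionError):
                continue
            m_null[n_ok] = m
            d_null[n_ok] = dr
            n_ok += 1
            done = True
            break
        if not done:
            n_skipped += 1
    if n_skipped > max_skip_fraction * n_iter:
        raise RuntimeError(
            f"{n_skipped}/{n_iter} null iterations degenerate; the null "
            "would be biased (check trait variation and tree branch lengths)")
    m_null = m_null[:n_ok]
    d_null = d_null[:n_ok]
    return NullDistribution(
        m_ratios=m_null, d_ratios=d_null,
        observed_m=observed_m, observed_d=observed_d,
        p_m=ratio_pvalue(observed_m, m_null, tail=tail),
        p_d=ratio_pvalue(observed_d, d_null, tail=tail),
        n_iter=n_iter, n_skipped=n_skipped, seed=seed, tail=tail, alpha=alpha,
        settings={"transform": transform, "ellipse_points": ellipse_points,
                  "divisor": divisor, "n_trees": len(trees)})


def ratio_pvalue(observed: float, null: np.ndarray,
                 tail: Literal["upper", "two_sided"] = "upper") -> float:
    """Empirical p-value of *observed* against the simulated *null* sample.

    Upper tail: p = (1 + #{null >= observed}) / (1 + n).  Two-sided doubles
    the smaller of the two tails, capped at 1.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n = null.size
    p_up = (1.0 + np.sum(null >= observed)) / (1.0 + n)
    if tail == "upper":
        return float(p_up)
    if tail == "two_sided":
        p_lo = (1.0 + np.sum(null <= observed)) / (1.0 + n)
        return float(min(1.0, 2.0 * min(p_up, p_lo)))
    raise ValueError(f"unknown tail {tail!r}")
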