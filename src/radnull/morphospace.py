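"""Phylomorphospace projection and clade disparity statistics.

A phylogeny is projected into a 2-D trait space by placing each tip at its
observed trait values and each internal node at its maximum-likelihood
ancestral state under Brownian motion.  Each branch then has a
*morphometric length*: the Euclidean distance in trait space between its
endpoints.  Per clade we compute

* ``M``  — mean morphometric branch length (magnitude of morphological
  change per branch),
* the minimum-volume enclosing (Löwner) ellipse of the clade's point cloud
  and its area, and
* ``D1`` — lineage density, total morphometric branch length divided by the
  ellipse area (high density = tightly packed, constrained evolution).

Two clades are compared through ``M-ratio = M_focal / M_reference`` and
``D-ratio = D1_reference / D1_focal`` (inverted so that a ratio > 1 means
the focal clade is more dispersed through morphospace).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from ._treealg import CladeView, TreeContext
from .tree_io import CladePartition, TreeError

__all__ = [
    "MorphospaceProjection",
    "Ellipse",
    "CladeDisparity",
    "DisparityRatios",
    "DegenerateMorphospaceError",
    "ancestral_states_bm",
    "mean_morph_branch_length",
    "min_volume_ellipse",
    "lineage_density_D1",
    "disparity_ratios",
    "clade_disparity",
]


class DegenerateMorphospaceError(ValueError):
    """The point cloud has zero area (collinear or coincident points)."""


@dataclass
class MorphospaceProjection:
    """Trait-space coordinates of every node plus per-branch lengths."""

    context: TreeContext
    trait_names: tuple[str, str]
    coords: np.ndarray          # (n_nodes, 2); preorder node indexing
    branch_lengths: np.ndarray  # (n_nodes,); entry i = morphometric length of
                                # the edge above node i (0 for the root)

    def node_table(self) -> pd.DataFrame:
        """Plot-ready table of node coordinates (tips carry their labels)."""
        ctx = self.context
        label = np.array([""] * ctx.n_nodes, dtype=object)
        label[ctx.tip_index] = ctx.tip_labels
        return pd.DataFrame({
            "node": np.arange(ctx.n_nodes),
            "parent": ctx.parent,
            "is_tip": ctx.is_tip,
            "label": label,
            self.trait_names[0]: self.coords[:, 0],
            self.trait_names[1]: self.coords[:, 1],
            "morphometric_length": self.branch_lengths,
        })


@dataclass(frozen=True)
class Ellipse:
    """Ellipse {x : (x-center)' shape (x-center) <= 1}."""

    center: np.ndarray
    shape: np.ndarray  # 2x2 positive definite
    area: float


@dataclass(frozen=True)
class CladeDisparity:
    clade: str
    n_branches: int
    M: float
    sum_L: float
    ellipse: Ellipse

    @property
    def D1(self) -> float:
        return self.sum_L / self.ellipse.area


@dataclass(frozen=True)
class DisparityRatios:
    M_ratio: float
    D_ratio: float
    transform: str = "raw"


def _project_array(ctx: TreeContext, tip_xy: np.ndarray,
                   names: tuple[str, str] = ("trait1", "trait2"),
                   ) -> MorphospaceProjection:
    """Projection from an (n_tips, 2) array already ordered as ctx.tip_labels."""
    coords = np.column_stack(
        [ctx.ancestral_states(tip_xy[:, j]) for j in (0, 1)])
    diffs = coords - coords[np.maximum(ctx.parent, 0)]
    blen = np.sqrt((diffs * diffs).sum(axis=1))
    blen[0] = 0.0
    return MorphospaceProjection(context=ctx, trait_names=tuple(names),
                                 coords=coords, branch_lengths=blen)


def _project(ctx: TreeContext, traits: pd.DataFrame) -> MorphospaceProjection:
    if traits.shape[1] != 2:
        raise ValueError("morphospace requires exactly 2 trait columns")
    missing = set(ctx.tip_labels) - set(traits.index)
    if missing:
        raise TreeError(f"traits missing for taxa: {sorted(missing)}")
    y = traits.loc[list(ctx.tip_labels)].to_numpy(dtype=float)
    return _project_array(ctx, y, tuple(traits.columns[:2]))


def ancestral_states_bm(tree: dendropy.Tree,
                        traits: pd.DataFrame) -> MorphospaceProjection:
    """Project *tree* into trait space via BM maximum-likelihood ancestors.

    Ancestral states are computed independently per trait by generalized
    least squares; the root state equals the intercept-only phylogenetic GLS
    estimate.  Requires strictly positive branch lengths and >= 3 tips.
    """
    ctx = TreeContext(tree)
    if len(ctx.tip_index) < 2:
        raise ValueError("need at least 2 tips")
    return _project(ctx, traits)


def mean_morph_branch_length(proj: MorphospaceProjection,
                             clade_tips: set[str] | None = None,
                             ) -> tuple[float, float, int]:
    """(M, sum_L, n_branches) over the clade's branches (stem excluded).

    With ``clade_tips=None`` all branches of the projected tree are used;
    otherwise the tips must form a monophyletic clade.
    """
    ctx = proj.context
    if clade_tips is None:
        children = np.arange(1, ctx.n_nodes)
    else:
        view = ctx.clade_view("clade", set(clade_tips))
        children = view.edge_children
    if children.size == 0:
        raise ValueError("clade has no branches")
    lens = proj.branch_lengths[children]
    return float(lens.mean()), float(lens.sum()), int(children.size)


def min_volume_ellipse(points: np.ndarray, tol: float = 1e-7,
                       max_iter: int = 10_000) -> Ellipse:
    """Minimum-volume enclosing ellipse of 2-D *points* (Khachiyan algorithm).

    Points are first reduced to their convex hull (the ellipse depends only
    on hull vertices), then the Khachiyan/Titterington multiplicative-update
    iteration runs to relative tolerance *tol*.  The ellipse is
    {x : (x-c)'A(x-c) <= 1} with area pi/sqrt(det A); every input point is
    inside up to slack of order *tol*.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if P.shape[0] < 3:
        raise DegenerateMorphospaceError("need at least 3 points")
    try:
        hull = ConvexHull(P)
        H = P[hull.vertices]
    except QhullError as exc:
        raise DegenerateMorphospaceError(
            f"degenerate point set (zero area): {exc}") from exc
    n, d = H.shape
    Q = np.column_stack([H, np.ones(n)])  # lift to homogeneous coords
    u = np.full(n, 1.0 / n)
    X = Q.T @ (Q * u[:, None])
    dp1 = d + 1.0
    # Frank-Wolfe with away steps (Todd & Yildirim): linear convergence,
    # unlike the plain add-step Khachiyan update
    for _ in range(max_iter):
        invX = np.linalg.inv(X)
        M = ((Q @ invX) * Q).sum(axis=1)
        j_add = int(np.argmax(M))
        eps_add = M[j_add] / dp1 - 1.0
        support = u > 1e-14
        masked = np.where(support, M, np.inf)
        j_away = int(np.argmin(masked))
        eps_away = 1.0 - M[j_away] / dp1
        if max(eps_add, eps_away) <= tol:
            break
        if eps_add >= eps_away:
            j, kappa = j_add, M[j_add]
        else:
            j, kappa = j_away, M[j_away]
        if abs(kappa - 1.0) < 1e-300:
            break
        step = (kappa / dp1 - 1.0) / (kappa - 1.0)
        if step < 0.0:  # away step: cannot remove more weight than u[j] has
            step = max(step, -u[j] / (1.0 - u[j]))
        u *= 1.0 - step
        u[j] += step
        q = Q[j]
        X = (1.0 - step) * X + step * np.outer(q, q)
    center = H.T @ u
    cov = H.T @ (H * u[:, None]) - np.outer(center, center)
    det = np.linalg.det(cov)
    if det <= 0 or not np.isfinite(det):
        raise DegenerateMorphospaceError("degenerate point set (zero area)")
    A = np.linalg.inv(cov) / d
    area = float(np.pi / np.sqrt(np.linalg.det(A)))
    return Ellipse(center=center, shape=A, area=area)


def lineage_density_D1(sum_L: float, area: float) -> float:
    """Lineage density: total morphometric branch length per unit area."""
    if area <= 0:
        raise DegenerateMorphospaceError("ellipse area must be positive")
    return sum_L / area


def disparity_ratios(focal: CladeDisparity,
                     reference: CladeDisparity,
                     transform: str = "raw") -> DisparityRatios:
    """M-ratio = M_focal/M_reference; D-ratio = D1_reference/D1_focal."""
    if reference.M <= 0:
        raise ZeroDivisionError("reference clade has zero mean branch length")
    if focal.D1 <= 0:
        raise ZeroDivisionError("focal clade has zero lineage density")
    return DisparityRatios(M_ratio=focal.M / reference.M,
                           D_ratio=reference.D1 / focal.D1,
                           transform=transform)


def _clade_stats(proj: MorphospaceProjection, view: CladeView,
                 ellipse_points: str, tol: float) -> CladeDisparity:
    lens = proj.branch_lengths[view.edge_children]
    if ellipse_points == "all":
        pts = proj.coords[view.nodes]
    elif ellipse_points == "tips":
        pts = proj.coords[view.tips]
    else:
        raise ValueError(f"unknown ellipse_points {ellipse_points!r}")
    ell = min_volume_ellipse(pts, tol=tol)
    return CladeDisparity(clade=view.name, n_branches=int(lens.size),
                          M=float(lens.mean()), sum_L=float(lens.sum()),
                          ellipse=ell)


def clade_disparity(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    partition: CladePartition,
    transform: Literal["raw", "log10"] = "raw",
    ellipse_points: Literal["all", "tips"] = "all",
    ellipse_tol: float = 1e-7,
) -> tuple[CladeDisparity, CladeDisparity, DisparityRatios]:
    """Full observed-disparity computation for a two-clade tree.

    Reconstructs ancestral states once on the shared tree, then reads
    per-clade M, minimum ellipse and D1 from the corresponding subtrees.
    The ellipse covers tip *and* internal-node coordinates by default (the
    full phylomorphospace cloud); ``ellipse_points="tips"`` restricts it to
    observed taxa.  ``transform="log10"`` is applied to the trait values
    before projection and requires them positive.
    """
    ctx = TreeContext(tree)
    have = set(ctx.tip_labels)
    if have != set(partition.all_taxa):
        raise TreeError(
            "tree tips must equal the union of the two clades; prune first "
            f"(extra: {sorted(have - partition.all_taxa)}, "
            f"missing: {sorted(partition.all_taxa - have)})")
    traits = traits.loc[list(ctx.tip_labels)].iloc[:, :2]
    if transform == "log10":
        if (traits.to_numpy() <= 0).any():
            raise ValueError("log10 transform requires positive trait values")
        traits = np.log10(traits)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    proj = _project(ctx, traits)
    focal_view = ctx.clade_view("focal", set(partition.focal))
    ref_view = ctx.clade_view("reference", set(partition.reference))
    focal = _clade_stats(proj, focal_view, ellipse_points, ellipse_tol)
    ref = _clade_stats(proj, ref_view, ellipse_points, ellipse_tol)
    return focal, ref, disparity_ratios(focal, ref, transform=transform)
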