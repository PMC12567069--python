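# Methods

This note records the models the package implements, the numerical choices
behind them, and what the synthetic-data experiments do and do not
demonstrate.

## Root-balance test

**Model.** The equal-rates-Markov (ERM) null grows a tree lineage by
lineage: at every step each extant lineage is equally likely to speciate
next. Conditioned on *N* tips, the number of tips descending from one root
child is uniform on {1, …, N−1}; the two-sided ("min-clade") tail is
therefore P(min ≤ k) = min(1, 2k/(N−1)). The package reports this closed
form alongside the Monte-Carlo estimate whenever the null is pure-birth.
The one-sided tail k/(N−1) is exposed (`tail="left"`), but the min-clade
tail is the default: an observed split is "extreme" regardless of which
side happens to be smaller.

**Engines.** Two implementations exist on purpose. The explicit simulators
(`simulate_yule_tree`, `simulate_bd_tree_conditioned`) build real trees
with exponential waiting times — pendant branches are extended past the
final speciation by one extra Exp(nλ) draw, so Yule trees are ultrametric
with positive terminal branches. The count-only engines used by
`balance_test` track just the per-side tip counts (a Pólya-urn recursion
for ERM; a per-side extant/extinct bookkeeping chain for birth–death) and
are vectorized across 10⁵ simulations. Both follow the same stochastic
process; the suite checks their root-split distributions against each other
and against the exact law.

**Birth–death conditioning.** Trees are grown forward from two crown
lineages until the extant count first reaches *N*; runs that die out
completely are discarded and restarted (cap: 10,000 attempts). This
first-passage scheme is recorded in results because other conditionings
exist. The default analysis keeps *complete* trees and counts extinct tips
in the balance. This is deliberate: pruning extinct lineages provably
returns the topology law to ERM (verified as a control test), so a
birth–death column that differs from the ERM column is only obtainable
when extinct lineages participate. With λ = 0.146, μ = 0.046 this raises
the tail probabilities from ≈ 0.37–0.60 to ≈ 0.59–0.67 — lopsided splits
become *more* probable, because one root side can be padded with extinct
side branches.

## Phylomorphospace disparity

**Projection.** Internal nodes are placed at the maximum-likelihood
ancestral states under Brownian motion, computed per trait. The joint ML
states minimize Σ (x_child − x_parent)²/branch-length, a weighted
graph-Laplacian linear system; its root equals the intercept-only
phylogenetic GLS estimate. The implementation solves the Laplacian with a
cached LU factorization (the null loop revisits the same few trees tens of
thousands of times); tests verify exact agreement (1e-8) with an
independent dense-covariance GLS solve. Branch lengths must be strictly
positive — a zero-length pendant edge makes the system singular and is
rejected rather than fudged.

**Minimum-volume ellipse.** The Löwner ellipse of the clade's point cloud
is computed by first reducing the points to their convex hull (the ellipse
depends only on hull vertices) and then running a Frank–Wolfe iteration
with away steps (Todd–Yıldırım variant of Khachiyan's algorithm), which
converges linearly; the plain add-step update needs ~10⁴ iterations at
tight tolerances and was measurably the pipeline bottleneck. Default
relative tolerance 1e-7, cap 10,000 iterations; areas on ≤ 100-point clouds
are stable to at least six significant digits, and every input point
satisfies (x−c)ᵀA(x−c) ≤ 1 + O(tol). Degenerate clouds (collinear or
coincident, zero area) raise a dedicated error. Areas are cross-checked in
the suite against R's `cluster::ellipsoidhull`.

**Which points enter the ellipse.** By default the full phylomorphospace
cloud of the clade — tips *and* reconstructed internal nodes — because
lineage density relates branch paths to the space they traverse and the
internal nodes bound those paths. `ellipse_points="tips"` restricts to
observed taxa; the choice is echoed into all outputs.

**Per-clade branch sets.** The stem edge above a clade's MRCA is excluded
from its branch set (and, equivalently, `extract_clade` drops the stem by
default): the statistics describe the clade's own diversification history.
A flag includes the stem for sensitivity analysis.

**Statistics.** M = mean morphometric branch length; D₁ = Σ lengths /
ellipse area; M-ratio = M_focal/M_ref; D-ratio = D₁_ref/D₁_focal (inverted
so that values > 1 mean the focal clade disperses more). Translation
invariance, the scale laws (M ∝ c, area ∝ c², D₁ ∝ 1/c, ratios invariant)
and the ratio arithmetic of the published component values are all asserted
in tests.

## The permutation + PGLS + BM null

Each of *n_iter* iterations: (1) draw one tree uniformly **with
replacement** from the supplied sample (large iteration counts force
reuse of a finite posterior sample); (2) permute each trait column
independently across all taxa — this destroys clade structure while
keeping the empirical trait distribution; (3) fit an intercept-only PGLS
per trait, giving a root state β = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y and rate
σ² = (y−β)ᵀV⁻¹(y−β)/(n−1), where V is the shared root-path covariance;
(4) simulate BM tip values with (β, σ²); (5) recompute both ratios exactly
as for the observed data. The n−1 (REML-style) divisor is the default for
its unbiasedness at the ~40-taxon sizes in play; `divisor="ml"` switches to
n, and the choice is recorded in the output.

p-values use a +1 pseudo-count, p = (1 + #{null ≥ obs})/(1 + n_iter), upper
tail by default (the scientific claims are directional: *greater* magnitude,
*greater* dispersion); a two-sided option doubles the smaller tail.

**Degeneracies.** An iteration whose simulated morphospace has zero area
(possible only with zero fitted rate or pathological trees) is retried once
with fresh randomness, then skipped and counted; if more than 1% of
iterations skip, the run aborts — silently dropping degenerate draws would
bias the null. Observed data whose own morphospace is degenerate (constant
traits) raise immediately: the statistic is undefined, not zero.

**Determinism.** Every public entry point takes either a seed or a numpy
`Generator`; a seed fully determines the run (tree draws, permutations, BM
noise). Results echo seed and all settings.

## Synthetic data

`make_two_clade_tree` joins two independent Yule crowns (default 34 focal
vs 9 reference tips — the taxon split of the study system) at depth 0.8
with stems of 0.2, giving an ultrametric tree of depth 1. Traits evolve
with unit BM rate by default; scenarios add a focal-clade rate multiplier
r² (`rate-shift`) or an Ornstein–Uhlenbeck reference clade with reversion
α = 5 per unit depth (`ou-constrained`), using the exact OU transition.
The clade-specific process applies to every branch inside the clade,
including its stem.

What this emulates: the two-clade shape, ultrametry, and trait dimensions
of the real analysis. What it does not: real measurement scales (girth
ratios, log lengths), tree-shape imbalance within clades, posterior
uncertainty structure (the "posterior sample" stand-in is independent Yule
draws, not correlated posterior trees), and trait covariance. Passing
calibration/power tests therefore demonstrate correctness of the machinery
under the stated models, not claims about any real dataset.

**A centering subtlety.** Under homogeneous BM the M-ratio is *not*
centered at 1 when the clades differ in size: the 34-tip clade packs more,
shorter branches into the same crown depth, and per-branch displacement
scales with √(branch length), so the median M-ratio at 34-vs-9 is ≈ 0.76.
The exact distributional laws — median ratio 1 for exchangeable equal-size
clades, and a rate multiplier r² scaling the whole M-ratio distribution by
r — are what the tests assert; the power experiment accordingly checks the
shifted-vs-baseline median ratio (≈ 2 for r = 2) rather than a raw
"median = 2".

## Experiment sizes

The suite's calibration experiment uses 200 replicate datasets × 500 null
iterations at the 34-vs-9 size (rejection counts compared to the exact
binomial 99% interval at α = 0.05); the power experiments use 60 replicates
× 300 iterations. The acceptance script simulates 100,000 trees per
balance-test configuration, matching the published simulation count; these
sizes keep a full run in the minutes range on one core while leaving
Monte-Carlo error well below the decision thresholds.

## Known limitations

- Ultrametricization offers terminal-branch extension (default; appropriate
  for numerically non-ultrametric MCC summaries) and a least-squares NNLS
  adjustment; which method produced any result is recorded. Neither is a
  substitute for proper time calibration of genuinely non-clock trees.
- The birth–death balance column depends on unstated simulator semantics
  (conditioning scheme, which tips count); the implemented complete-tree /
  all-tips default reproduces the published values, and both switches are
  exposed, but agreement there is empirical, not forced by the model.
- Traits are treated as evolving independently (matching the per-trait
  permutation and simulation of the null); no multivariate BM covariance is
  estimated.
- Only 2-D morphospaces are supported end to end; D₂-style higher-order
  volume corrections are intentionally absent.
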