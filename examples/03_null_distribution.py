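"""Testing disparity ratios against the permutation + PGLS + BM null.

Generates a synthetic dataset in which the focal clade's traits evolve at
9x the reference rate (rate-shift scenario), then builds the null
distribution of M- and D-ratios: permute traits across taxa, refit root and
rate by phylogenetic GLS, re-simulate under Brownian motion, recompute the
ratios.  The observed M-ratio should sit in the upper tail.
"""

import numpy as np

from radnull import (SyntheticScenario, build_null, make_two_clade_tree,
                     simulate_traits, summarize_null)

rng = np.random.default_rng(7)
tree, partition = make_two_clade_tree(34, 9, rng)
scenario = SyntheticScenario(n_focal=34, n_reference=9,
                             trait_model="rate-shift", rate_multiplier=3.0)
traits = simulate_traits(tree, partition, scenario, rng)

null = build_null([tree], traits, partition, n_iter=2000, rng=11)

print(f"observed M-ratio = {null.observed_m:.3f}   p = {null.p_m:.4f}")
print(f"observed D-ratio = {null.observed_d:.3f}   p = {null.p_d:.4f}")
print(f"null iterations: {null.n_iter} (skipped {null.n_skipped})")

summary = summarize_null(null.m_ratios, null.observed_m, n_bins=12)
print(f"\nobserved M-ratio sits at the {summary['quantile']:.1%} quantile "
      "of its null; histogram of null M-ratios:")
for lo, hi, c in zip(summary["bin_edges"][:-1], summary["bin_edges"][1:],
                     summary["bin_counts"]):
    print(f"  [{lo:5.2f}, {hi:5.2f})  {'#' * (c // 20)}{c:5d}")
print("\nA small p for the M-test correctly flags the simulated rate shift;")
print("the D-test asks the separate question of whether the focal clade")
print("fills morphospace more efficiently than Brownian motion would.")
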