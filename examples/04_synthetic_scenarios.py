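"""What the three trait-evolution scenarios do to the disparity ratios.

Simulates replicate datasets under (i) homogeneous Brownian motion, (ii) a
4x focal-clade rate shift, and (iii) an Ornstein-Uhlenbeck-constrained
reference clade, and prints the median M- and D-ratios for each: the rate
shift moves the M-ratio (magnitude), the OU constraint moves the D-ratio
(mode).
"""

import numpy as np

from radnull import (SyntheticScenario, clade_disparity, make_two_clade_tree,
                     simulate_traits)

SCENARIOS = {
    "homogeneous BM": SyntheticScenario(n_focal=34, n_reference=9),
    "focal rate x4": SyntheticScenario(n_focal=34, n_reference=9,
                                       trait_model="rate-shift",
                                       rate_multiplier=2.0),
    "OU-constrained ref": SyntheticScenario(n_focal=34, n_reference=9,
                                            trait_model="ou-constrained",
                                            alpha_ou=5.0),
}

rng = np.random.default_rng(1)
print(f"{'scenario':20s} {'median M-ratio':>15s} {'median D-ratio':>15s}")
for name, sc in SCENARIOS.items():
    m, d = [], []
    for _ in range(80):
        tree, part = make_two_clade_tree(34, 9, rng)
        traits = simulate_traits(tree, part, sc, rng)
        _f, _r, q = clade_disparity(tree, traits, part)
        m.append(q.M_ratio)
        d.append(q.D_ratio)
    print(f"{name:20s} {np.median(m):15.3f} {np.median(d):15.3f}")

print()
print("Under homogeneous BM the M-ratio sits below 1 here because the larger")
print("clade packs more, shorter branches into the same crown depth. The")
print("rate shift doubles it. The OU constraint shortens the reference")
print("clade's steps in trait space, which raises both ratios, but it is the")
print("D-ratio - occupied area per unit of path - that responds the most.")
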