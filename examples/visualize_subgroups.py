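"""Render the per-terminal-node subgroup grid.

Each panel shows one subgroup: the outcome histogram with per-bin means,
the subgroup mean and size in the title, and one colored bar per defining
covariate whose endpoints are the rule interval mapped to full-sample
percentiles (a bar [0, 39] means "below the 39th population percentile").
"""

import numpy as np

from epitree import gen_tree_dgp, grow_ctree, render_grid

rng = np.random.default_rng(4)
data = gen_tree_dgp(500, rng)
tree = grow_ctree(data, "y")

panels = render_grid(tree, data, "y", "subgroup_grid.svg")
print(f"wrote subgroup_grid.svg with {len(panels)} panels\n")
for p in panels:
    bars = ", ".join(f"{var} [{s:.0f}, {e:.0f}]" for var, s, e, _ in p.bars)
    print(f"node {p.leaf_id}: mean={p.mean:+.2f} n={p.n}  bars: {bars or '(root)'}")
print(
    "\nEach line is one population subgroup: its mean outcome, size, and the "
    "percentile ranges of the covariates that define membership."
)
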