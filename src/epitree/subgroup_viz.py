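"""Per-terminal-node subgroup visualization.

A fitted tree's terminal nodes are rendered as a grid of panels, one per
subgroup.  Each panel shows, in the background, a histogram of the outcome
within the subgroup annotated with each bin's mean outcome; a vertical line
at the subgroup mean, with the mean and subgroup size in the title; and,
overlaid, one colored horizontal bar per covariate constraining the
subgroup, whose endpoints are the constraint interval's bounds mapped onto
the *full-sample* percentile scale.  A bar from 0 to 39 for "liking", say,
reads as "this subgroup holds individuals below the 39th population
percentile of liking" — useful when a covariate has no established unit.

Percentiles use the empirical CDF (percentage of reference values <= v);
±inf endpoints map to 0 and 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .tree_core import DecisionTree

__all__ = ["PanelSpec", "percentile_of", "build_panel", "render_grid", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = (".png", ".svg", ".pdf")

_BAR_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


@dataclass
class PanelSpec:
    """Everything needed to draw one terminal node's panel."""

    leaf_id: int
    n: int
    mean: float
    histogram: list[tuple[tuple[float, float], int, float | None]]
    bars: list[tuple[str, float, float, int]]

    def to_dict(self) -> dict:
        return {
            "leaf_id": self.leaf_id,
            "n": self.n,
            "mean": self.mean,
            "histogram": [
                {"bin": list(interval), "count": count, "bin_mean": bin_mean}
                for interval, count, bin_mean in self.histogram
            ],
            "bars": [
                {"covariate": c, "start": s, "end": e, "color": k}
                for c, s, e, k in self.bars
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "PanelSpec":
        return PanelSpec(
            leaf_id=d["leaf_id"],
            n=d["n"],
            mean=d["mean"],
            histogram=[
                (tuple(h["bin"]), h["count"], h["bin_mean"]) for h in d["histogram"]
            ],
            bars=[(b["covariate"], b["start"], b["end"], b["color"]) for b in d["bars"]],
        )


def percentile_of(value: float, reference: np.ndarray) -> float:
    """Empirical-CDF percentile: 100 x (fraction of reference values <= value)."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty reference sample")
    if value == -math.inf:
        return 0.0
    if value == math.inf:
        return 100.0
    return 100.0 * float(np.mean(reference <= value))


def build_panel(
    tree: DecisionTree,
    leaf_id: int,
    data: pd.DataFrame,
    outcome: str,
    n_bins: int = 10,
) -> PanelSpec:
    """Compute one terminal node's panel from the training data.

    The histogram covers the leaf's own outcome values (equal-width bins
    over the leaf range); bar endpoints map the leaf's subgroup-rule
    interval bounds through the full-sample empirical percentile scale.
    """
    leaf = tree.find(leaf_id)
    if not leaf.is_leaf:
        raise ValueError(f"node {leaf_id} is not a terminal node")
    if leaf.indices is None or len(leaf.indices) == 0:
        raise ValueError(f"node {leaf_id} carries no training observations")
    y_leaf = data[outcome].to_numpy(dtype=float)[leaf.indices]
    counts, edges = np.histogram(y_leaf, bins=n_bins)
    which = np.clip(np.digitize(y_leaf, edges[1:-1], right=False), 0, n_bins - 1)
    histogram = []
    for b in range(n_bins):
        inside = y_leaf[which == b]
        bin_mean = float(inside.mean()) if inside.size else None
        histogram.append(((float(edges[b]), float(edges[b + 1])), int(counts[b]), bin_mean))
    rule = tree.subgroup_rule(leaf_id)
    bars = []
    for var, (lo, hi) in rule.intervals.items():
        ref = data[var].to_numpy(dtype=float)
        bars.append(
            (
                var,
                percentile_of(lo, ref),
                percentile_of(hi, ref),
                tree.covariate_names.index(var),
            )
        )
    return PanelSpec(
        leaf_id=leaf_id,
        n=int(leaf.n_obs),
        mean=float(leaf.node_mean),
        histogram=histogram,
        bars=bars,
    )


def _draw_panel(ax: plt.Axes, panel: PanelSpec) -> None:
    edges = [iv[0] for iv, _, _ in panel.histogram] + [panel.histogram[-1][0][1]]
    counts = [c for _, c, _ in panel.histogram]
    ax.stairs(counts, edges, fill=True, color="0.85", edgecolor="0.6")
    for (lo, hi), count, bin_mean in panel.histogram:
        if bin_mean is not None:
            ax.annotate(
                f"{bin_mean:.2f}",
                ((lo + hi) / 2, 0),
                xytext=(0, -12),
                textcoords="offset points",
                ha="center",
                fontsize=6,
                annotation_clip=False,
            )
    ax.axvline(panel.mean, color="black", lw=1.2)
    # covariate bars on a 0-100 percentile axis overlaid on top
    top = ax.twiny()
    top.set_xlim(0, 100)
    ymax = max(max(counts), 1)
    for row, (var, start, end, color_idx) in enumerate(panel.bars):
        ypos = ymax * (0.92 - 0.12 * row)
        top.plot(
            [start, end],
            [ypos, ypos],
            lw=6,
            solid_capstyle="butt",
            color=_BAR_COLORS[color_idx % len(_BAR_COLORS)],
        )
        top.annotate(
            f"{var} [{start:.0f}, {end:.0f}]",
            (min(start + 1, 99), ypos),
            xytext=(0, 4),
            textcoords="offset points",
            fontsize=6,
        )
    top.set_xticks([])
    ax.set_ylim(0, ymax * 1.05)
    ax.set_title(f"node {panel.leaf_id}: {panel.mean:.2f} (n={panel.n})", fontsize=8)
    ax.tick_params(labelsize=6)


def render_grid(
    tree: DecisionTree,
    data: pd.DataFrame,
    outcome: str,
    outfile: str,
    n_bins: int = 10,
) -> list[PanelSpec]:
    """Render the grid of subgroup panels, one per terminal node.

    The grid has ceil(sqrt(L)) columns for L leaves.  Supported output
    formats: PNG, SVG, PDF.  For SVG output the panel specifications are
    embedded as JSON in the document metadata (Description field), so the
    rendered numbers can be recovered programmatically.  Returns the panel
    specs in leaf preorder.
    """
    suffix = "." + outfile.rsplit(".", 1)[-1].lower() if "." in outfile else ""
    if suffix not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported image extension {suffix!r}; supported: "
            + ", ".join(SUPPORTED_FORMATS)
        )
    leaf_ids = [leaf.node_id for leaf in tree.root.leaves()]
    panels = [build_panel(tree, lid, data, outcome, n_bins) for lid in leaf_ids]
    L = len(panels)
    ncols = math.ceil(math.sqrt(L))
    nrows = math.ceil(L / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax in axes.ravel():
        ax.set_visible(False)
    for ax, panel in zip(axes.ravel(), panels):
        ax.set_visible(True)
        _draw_panel(ax, panel)
    fig.tight_layout()
    metadata = None
    if suffix == ".svg":
        metadata = {"Description": json.dumps([p.to_dict() for p in panels])}
    fig.savefig(outfile, metadata=metadata)
    plt.close(fig)
    return panels
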