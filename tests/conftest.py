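"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epitree.tree_core import (
    CONTINUOUS,
    DecisionTree,
    FitParams,
    TreeNode,
    assign_preorder_ids,
)


def sse(y: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    return float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0


def brute_force_best_split(x, y, minbucket):
    """Exhaustive SSE-split search over all midpoints; independent oracle.

    Returns (threshold, reduction) for the feasible midpoint maximising the
    SSE reduction (smallest threshold on ties), or None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    parent = sse(y)
    best = None
    for v in sorted(set(x))[:-1]:
        larger = min(u for u in set(x) if u > v)
        thr = (v + larger) / 2.0
        left, right = y[x <= thr], y[x > thr]
        if len(left) < minbucket or len(right) < minbucket:
            continue
        red = parent - sse(left) - sse(right)
        if best is None or red > best[1] + 1e-12:
            best = (thr, red)
    if best is None or best[1] <= 1e-9:
        return None
    return best


def make_leaf(mean, n=10, sse_val=0.0):
    return TreeNode(node_id=0, n_obs=n, node_mean=mean, sse=sse_val)


def make_split(var, point, left, right, p_value=None):
    node = TreeNode(
        node_id=0,
        n_obs=left.n_obs + right.n_obs,
        node_mean=(left.node_mean * left.n_obs + right.node_mean * right.n_obs)
        / (left.n_obs + right.n_obs),
        sse=left.sse + right.sse + 1.0,
        split_var=var,
        split_point=point,
        left=left,
        right=right,
        p_value=p_value,
    )
    return node


@pytest.fixture
def fig1_like_tree():
    """Depth-3 tree shaped like the introductory example: splits on hunger,
    liking and rrvf; terminal nodes get preorder ids 3, 5, 6, 7."""
    root = make_split(
        "hunger",
        1.69,
        make_split(
            "liking",
            -0.28,
            make_leaf(-0.46, n=86),
            make_split("rrvf", -1.26, make_leaf(-0.50, n=22), make_leaf(0.26, n=104)),
        ),
        make_leaf(1.20, n=14),
    )
    assign_preorder_ids(root)
    return DecisionTree(
        root=root,
        covariate_names=["hunger", "liking", "rrvf"],
        covariate_kinds={c: CONTINUOUS for c in ("hunger", "liking", "rrvf")},
        method="ctree",
        params=FitParams(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def step_data(n=40, effect=5.0):
    """Deterministic one-split dataset: y steps at x = 20.5."""
    x = np.arange(1, n + 1, dtype=float)
    y = np.where(x <= n / 2, 0.0, effect)
    return pd.DataFrame({"x": x, "y": y})
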