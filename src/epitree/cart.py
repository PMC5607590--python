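"""CART regression-tree induction with cost-complexity pruning.

The splitting criterion is the classical greedy one: at each node the split
minimising the pooled within-child sum of squared errors (equivalently,
maximising the SSE reduction) is sought over every covariate and every
candidate threshold.  Candidate thresholds are the midpoints between
consecutive distinct sorted values, which makes the search exact and lets a
brute-force enumeration serve as an independent oracle; a binary covariate
contributes the single candidate 0.5.

Stopping: a node is split only if it contains at least ``minsplit``
observations, both children would contain at least ``minbucket``, and the
SSE reduction is at least ``cp`` times the root SSE — so ``cp = 0.01``
means "a split must improve model fit by at least 1%".

Pruning follows weakest-link cost-complexity pruning: internal nodes are
collapsed in order of their per-split error increase, producing a nested
subtree sequence indexed by critical cp values.  K-fold cross-validation
over that sequence supports the minimum-error rule and the more
conservative 1-SE rule (smallest subtree within one standard error of the
minimum cross-validated error).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree_core import (
    DecisionTree,
    FitParams,
    TreeNode,
    assign_preorder_ids,
    detect_covariate_kinds,
)

__all__ = [
    "best_split",
    "grow_cart",
    "cost_complexity_path",
    "prune_at",
    "select_cp",
    "PruneSequence",
    "PruneEntry",
]

_EPS = 1e-12


def _sse(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    return float(np.sum((y - y.mean()) ** 2))


def best_split(
    x: np.ndarray, y: np.ndarray, minbucket: int
) -> tuple[float, float] | None:
    """Best SSE-reducing threshold on one covariate.

    Returns ``(threshold, sse_reduction)`` maximising
    ``SSE(parent) − [SSE(left) + SSE(right)]`` over all midpoints between
    consecutive distinct sorted values of ``x`` that leave at least
    ``minbucket`` observations on each side, or ``None`` when no candidate
    is feasible or no candidate reduces the SSE (e.g. constant ``y`` or
    constant ``x``).  Ties are broken toward the smallest threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * minbucket:
        return None
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cum = np.cumsum(ys)
    cum2 = np.cumsum(ys * ys)
    total, total2 = cum[-1], cum2[-1]
    k = np.arange(1, n)  # left-side sizes
    sse_left = cum2[:-1] - cum[:-1] ** 2 / k
    sse_right = (total2 - cum2[:-1]) - (total - cum[:-1]) ** 2 / (n - k)
    parent = total2 - total**2 / n
    reduction = parent - (sse_left + sse_right)
    feasible = (xs[1:] != xs[:-1]) & (k >= minbucket) & (n - k >= minbucket)
    if not feasible.any():
        return None
    reduction = np.where(feasible, reduction, -np.inf)
    j = int(np.argmax(reduction))  # first (smallest-threshold) maximiser
    best = float(reduction[j])
    if best <= _EPS * max(parent, 1.0):
        return None
    threshold = float((xs[j] + xs[j + 1]) / 2.0)
    return threshold, best


def _check_data(data: pd.DataFrame, outcome: str, covariates: list[str] | None):
    if len(data) == 0:
        raise ValueError("empty data")
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not in data")
    if covariates is None:
        covariates = [c for c in data.columns if c != outcome]
    if not covariates:
        raise ValueError("at least one covariate is required")
    sub = data[covariates + [outcome]]
    if sub.isna().to_numpy().any():
        raise ValueError("missing values are not supported; complete inputs required")
    return covariates


def grow_cart(
    data: pd.DataFrame,
    outcome: str,
    params: FitParams | None = None,
    covariates: list[str] | None = None,
) -> DecisionTree:
    """Grow a CART regression tree by greedy SSE-minimising splits.

    Ties between covariates are broken by covariate (column) order, and
    within a covariate by the smallest threshold, so the fit is fully
    deterministic.
    """
    params = params or FitParams()
    covariates = _check_data(data, outcome, covariates)
    X = data[covariates].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)
    root_sse = _sse(y)
    min_gain = params.cp * root_sse

    def build(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        node = TreeNode(
            node_id=0,
            n_obs=len(idx),
            node_mean=float(yi.mean()),
            sse=_sse(yi),
            indices=idx,
        )
        if len(idx) < params.minsplit:
            return node
        best: tuple[float, float, int] | None = None  # (reduction, threshold, col)
        for j in range(X.shape[1]):
            cand = best_split(X[idx, j], yi, params.minbucket)
            if cand is None:
                continue
            thr, red = cand
            if best is None or red > best[0] + _EPS * max(root_sse, 1.0):
                best = (red, thr, j)
        if best is None or best[0] < min_gain - _EPS * max(root_sse, 1.0):
            return node
        red, thr, j = best
        node.split_var = covariates[j]
        node.split_point = thr
        go_left = X[idx, j] <= thr
        node.left = build(idx[go_left])
        node.right = build(idx[~go_left])
        return node

    root = build(np.arange(n))
    assign_preorder_ids(root)
    return DecisionTree(
        root=root,
        covariate_names=list(covariates),
        covariate_kinds=detect_covariate_kinds(data[covariates]),
        method="cart",
        params=params,
    )


# ----------------------------------------------------------------------
# cost-complexity pruning
# ----------------------------------------------------------------------


@dataclass
class PruneEntry:
    cp: float
    tree: DecisionTree
    cv_error_mean: float | None = None
    cv_error_se: float | None = None


@dataclass
class PruneSequence:
    """Nested subtree sequence from weakest-link pruning.

    Entries are ordered from the full tree (smallest critical cp) to the
    root-only tree (largest); each subtree is obtained from the previous by
    collapsing the internal node(s) with minimal per-split error increase.
    """

    entries: list[PruneEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _branch_stats(node: TreeNode) -> tuple[float, int]:
    """Sum of leaf SSEs and leaf count under ``node``."""
    if node.is_leaf:
        return node.sse, 1
    ls, lc = _branch_stats(node.left)  # type: ignore[arg-type]
    rs, rc = _branch_stats(node.right)  # type: ignore[arg-type]
    return ls + rs, lc + rc


def cost_complexity_path(tree: DecisionTree) -> PruneSequence:
    """Weakest-link pruning sequence with critical cp values.

    The per-split error increase of collapsing the branch rooted at an
    internal node t is ``g(t) = [SSE(t) − Σ_leaves SSE] / (leaves(t) − 1)``,
    normalised by the root SSE so critical values live on the cp scale.
    """
    root_sse = max(tree.root.sse, _EPS)
    seq = PruneSequence()
    seq.entries.append(PruneEntry(cp=tree.params.cp, tree=copy.deepcopy(tree)))
    current = copy.deepcopy(tree)
    while not current.root.is_leaf:
        gs: list[tuple[TreeNode, float]] = []
        for node in current.nodes():
            if not node.is_leaf:
                leaf_sse, n_leaves = _branch_stats(node)
                gs.append((node, (node.sse - leaf_sse) / (n_leaves - 1) / root_sse))
        gmin = min(g for _, g in gs)
        tol = 1e-10 * max(1.0, abs(gmin))
        # collapse every weakest link; collapsing an ancestor removes its
        # descendants, which the preorder walk handles naturally
        def collapse(node: TreeNode) -> None:
            if node.is_leaf:
                return
            leaf_sse, n_leaves = _branch_stats(node)
            g = (node.sse - leaf_sse) / (n_leaves - 1) / root_sse
            if g <= gmin + tol:
                node.split_var = None
                node.split_point = None
                node.left = None
                node.right = None
            else:
                collapse(node.left)  # type: ignore[arg-type]
                collapse(node.right)  # type: ignore[arg-type]

        collapse(current.root)
        assign_preorder_ids(current.root)
        seq.entries.append(PruneEntry(cp=gmin, tree=copy.deepcopy(current)))
    return seq


def prune_at(seq: PruneSequence, cp: float) -> DecisionTree:
    """Subtree from the pruning sequence that is optimal for penalty ``cp``."""
    chosen = seq.entries[0]
    for entry in seq.entries:
        if entry.cp <= cp * (1 + 1e-12):
            chosen = entry
    return chosen.tree


def select_cp(
    data: pd.DataFrame,
    outcome: str,
    params: FitParams | None = None,
    rule: str = "min",
    covariates: list[str] | None = None,
) -> tuple[float, DecisionTree, PruneSequence]:
    """Cross-validated complexity-parameter selection.

    Grows the full tree, computes the weakest-link pruning sequence, and
    estimates each subtree's prediction error by K-fold cross-validation
    (seeded fold assignment; each fold tree is grown with the same
    parameters and pruned at the geometric midpoint of consecutive critical
    cp values).  ``rule="min"`` returns the subtree minimising the mean CV
    error; ``rule="one_se"`` the smallest subtree whose mean CV error is
    within one standard error of that minimum.  Ties favour the smaller
    subtree.
    """
    if rule not in ("min", "one_se"):
        raise ValueError(f"unknown selection rule {rule!r}")
    params = params or FitParams()
    covariates = _check_data(data, outcome, covariates)
    n = len(data)
    if n < params.cv_folds:
        raise ValueError(f"n={n} smaller than cv_folds={params.cv_folds}")

    full = grow_cart(data, outcome, params, covariates)
    seq = cost_complexity_path(full)
    m = len(seq)
    if m == 1:
        return seq.entries[0].cp, copy.deepcopy(full), seq

    # evaluation penalty per subtree: geometric midpoint of consecutive
    # critical cp values; the root-only subtree is evaluated at +inf so its
    # CV error is the clean mean-prediction error in every fold
    cps = np.array([e.cp for e in seq.entries])
    betas = np.empty(m)
    betas[:-1] = np.sqrt(cps[:-1] * cps[1:])
    betas[-1] = np.inf

    rng = np.random.default_rng(params.seed)
    fold = rng.permutation(np.arange(n) % params.cv_folds)
    y = data[outcome].to_numpy(dtype=float)
    errs = np.empty((n, m))
    for k in range(params.cv_folds):
        test_mask = fold == k
        train = data.loc[~test_mask]
        fold_tree = grow_cart(train, outcome, params, covariates)
        fold_seq = cost_complexity_path(fold_tree)
        Xtest = data.loc[test_mask]
        for j in range(m):
            sub = prune_at(fold_seq, betas[j])
            pred = sub.predict_frame(Xtest)
            errs[test_mask, j] = (y[test_mask] - pred) ** 2

    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(n)
    for j, entry in enumerate(seq.entries):
        entry.cv_error_mean = float(cv_mean[j])
        entry.cv_error_se = float(cv_se[j])

    j_min = m - 1 - int(np.argmin(cv_mean[::-1]))  # ties -> smaller subtree
    if rule == "min":
        j_star = j_min
    else:
        thr = cv_mean[j_min] + cv_se[j_min]
        j_star = max(j for j in range(m) if cv_mean[j] <= thr)
    chosen = copy.deepcopy(seq.entries[j_star].tree)
    chosen.params = FitParams(**{**params.to_dict(), "pruning": rule})
    return float(cps[j_star]), chosen, seq
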