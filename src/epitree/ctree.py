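"""Conditional inference tree induction for continuous outcomes.

Splitting proceeds in two formal steps at each node:

1. *Variable selection.*  Each candidate covariate is tested for marginal
   association with the outcome using the permutation-asymptotic
   standardized linear statistic ``T = Σ x_i y_i``.  Under the permutation
   null its exact moments are ``E[T] = n x̄ ȳ`` and
   ``Var[T] = S_xx S_yy / (n − 1)``, so the standardized statistic equals
   ``z = r √(n − 1)`` for the sample correlation r, referred to the
   standard normal.  Raw two-sided p-values are Bonferroni-adjusted over
   the covariates tested at the node; the node is split only if the global
   null hypothesis — no covariate is associated with the outcome — is
   rejected at level ``alpha``, in which case the covariate with the
   smallest adjusted p-value is selected.

2. *Split-point selection.*  For the selected covariate, the threshold
   maximising the absolute standardized two-sample statistic (same
   permutation moments, with the indicator 1(x ≤ c) as the transformation)
   is chosen among midpoints respecting ``minbucket``.

Because the stopping rule is a hypothesis test at a fixed level, the
probability of any split under a global null is controlled near ``alpha``,
and no pruning step is needed.  Inference below the root is conditional:
covariates are re-tested at every node on that node's subsample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tree_core import (
    DecisionTree,
    FitParams,
    TreeNode,
    assign_preorder_ids,
    detect_covariate_kinds,
)
from . import cart as _cart

__all__ = [
    "AssociationTestResult",
    "GlobalTestResult",
    "association_test",
    "global_null_test",
    "best_split_point",
    "grow_ctree",
]


@dataclass
class AssociationTestResult:
    covariate: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class GlobalTestResult:
    reject: bool
    selected: str | None
    results: list[AssociationTestResult]


def association_test(x: np.ndarray, y: np.ndarray, name: str = "x") -> AssociationTestResult:
    """Permutation-asymptotic test of marginal association between x and y.

    A constant covariate (or constant outcome) carries no information and
    yields p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        return AssociationTestResult(name, 0.0, 1.0)
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx <= 0.0 or syy <= 0.0:
        return AssociationTestResult(name, 0.0, 1.0)
    t = float(np.sum(x * y))
    mu = n * x.mean() * y.mean()
    sd = np.sqrt(sxx * syy / (n - 1))
    z = (t - mu) / sd
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return AssociationTestResult(name, z, min(p, 1.0))


def global_null_test(X: pd.DataFrame, y: np.ndarray, alpha: float) -> GlobalTestResult:
    """Bonferroni-adjusted test of the global null hypothesis at a node.

    The global null states that no candidate covariate has a univariate
    association with the outcome.  Adjusted p-values are ``min(1, m p_raw)``
    with m the number of informative (non-constant) covariates tested; the
    node rejects iff the minimum adjusted p-value is at most ``alpha``, and
    then selects the covariate attaining it (ties broken by column order).
    If the minimum p-value exceeds the threshold, no variable is selected.
    """
    y = np.asarray(y, dtype=float)
    results = [association_test(X[c].to_numpy(dtype=float), y, c) for c in X.columns]
    m = sum(1 for r in results if r.p_raw < 1.0 or abs(r.statistic) > 0)
    m = max(m, 1)
    for r in results:
        r.p_adjusted = min(1.0, m * r.p_raw)
    best = min(results, key=lambda r: (r.p_adjusted, list(X.columns).index(r.covariate)))
    if best.p_adjusted <= alpha:
        return GlobalTestResult(True, best.covariate, results)
    return GlobalTestResult(False, None, results)


def best_split_point(x: np.ndarray, y: np.ndarray, minbucket: int) -> float | None:
    """Threshold maximising the absolute standardized two-sample statistic.

    Candidates are midpoints between consecutive distinct sorted values of
    ``x`` leaving at least ``minbucket`` observations on each side; ties go
    to the smallest threshold.  Returns ``None`` when no candidate is
    feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * minbucket:
        return None
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy <= 0.0:
        return None
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    k = np.arange(1, n)
    cum = np.cumsum(ys)[:-1]
    mu = k * ys.mean()
    var = k * (n - k) / n * syy / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(cum - mu) / np.sqrt(var)
    feasible = (xs[1:] != xs[:-1]) & (k >= minbucket) & (n - k >= minbucket)
    if not feasible.any():
        return None
    z = np.where(feasible, z, -np.inf)
    j = int(np.argmax(z))
    return float((xs[j] + xs[j + 1]) / 2.0)


def grow_ctree(
    data: pd.DataFrame,
    outcome: str,
    params: FitParams | None = None,
    covariates: list[str] | None = None,
    split_criterion: str = "statistic",
) -> DecisionTree:
    """Grow a conditional inference tree.

    A node becomes terminal when it holds fewer than ``minsplit``
    observations, when the multiplicity-adjusted global null test fails at
    level ``params.alpha``, or when no split respecting ``minbucket``
    exists on the selected covariate.  Internal nodes record the selected
    covariate's adjusted p-value.

    ``split_criterion`` selects the split-point rule: ``"statistic"``
    (default, standardized two-sample statistic) or ``"sse"`` (greedy SSE
    reduction, the CART rule).
    """
    if split_criterion not in ("statistic", "sse"):
        raise ValueError(f"unknown split criterion {split_criterion!r}")
    params = params or FitParams()
    covariates = _cart._check_data(data, outcome, covariates)
    X = data[covariates]
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)

    def build(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        node = TreeNode(
            node_id=0,
            n_obs=len(idx),
            node_mean=float(yi.mean()),
            sse=float(np.sum((yi - yi.mean()) ** 2)),
            indices=idx,
        )
        if len(idx) < params.minsplit:
            return node
        test = global_null_test(X.iloc[idx], yi, params.alpha)
        if not test.reject:
            return node
        var = test.selected
        xcol = X[var].to_numpy(dtype=float)[idx]
        if split_criterion == "statistic":
            thr = best_split_point(xcol, yi, params.minbucket)
        else:
            cand = _cart.best_split(xcol, yi, params.minbucket)
            thr = None if cand is None else cand[0]
        if thr is None:
            return node
        node.split_var = var
        node.split_point = thr
        node.p_value = next(r.p_adjusted for r in test.results if r.covariate == var)
        go_left = xcol <= thr
        node.left = build(idx[go_left])
        node.right = build(idx[~go_left])
        return node

    root = build(np.arange(n))
    assign_preorder_ids(root)
    return DecisionTree(
        root=root,
        covariate_names=list(covariates),
        covariate_kinds=detect_covariate_kinds(X),
        method="ctree",
        params=params,
    )
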