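"""Synthetic data generators and the Monte-Carlo experiment harness.

Four data-generating processes are provided, all with six candidate
covariates and unit-variance Gaussian noise:

* ``tree``       — outcomes follow a fixed 7-leaf tree on X1..X4 (X5, X6
                   pure noise), leaf means
                   (−1.88, −0.30, −0.31, 0.25, −0.09, 2.23, 1.35);
* ``regression`` — linear predictor
                   eta = 1.5 X1 + 1.25 X2 + 1 X3 + 0.85 X4 + 0.75 X5 + 0 X6;
* ``hybrid``     — eta = 0.5 X1 + 0.45 X2 + 0.3 X3
                   + 1.5 1(X1<=0, X2>0, X3<=0) + 0.25 1(X1<=0, X3>0)
                   + 0.14 1(X1>0, X2>0), with X4..X6 pure noise;
* ``null``       — y ~ N(0, 1) independent of all six covariates.

Continuous covariates are i.i.d. N(0, 1); binary ones i.i.d. Bernoulli(0.5).
The default sample size is 250 for both training and the independently
generated test set.

``run_scenario`` repeats: simulate a training set, fit a method (unpruned
CART, CART pruned by the min or 1-SE rule, CTree, or an OLS comparator),
simulate an independent test set, and record test MSE, terminal-node count
and — under the null DGP — a Type-I-error flag (any split at all counts,
since no covariate is associated with the outcome).  Replicates draw from
independent child streams of one master seed, so results are reproducible
and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cart as _cart
from . import ctree as _ctree
from .tree_core import BINARY, CONTINUOUS, FitParams

__all__ = [
    "Scenario",
    "ScenarioResult",
    "DEFAULT_TREE_STRUCTURE",
    "gen_covariates",
    "gen_regression",
    "gen_hybrid",
    "gen_tree_dgp",
    "gen_null",
    "tree_dgp_mean",
    "hybrid_eta",
    "regression_eta",
    "run_scenario",
    "sample_size_sweep",
    "summarize_results",
    "METHODS",
]

METHODS = ("cart", "cart_min", "cart_1se", "ctree", "ols")

REGRESSION_BETAS = np.array([1.5, 1.25, 1.0, 0.85, 0.75, 0.0])

#: Default 7-leaf tree DGP.  The leaf means are fixed; the topology and
#: thresholds are a depth-3 arrangement of splits on X1..X4 echoing the
#: introductory example's printed cutpoints (1.69, −0.28, −1.26, 0), and
#: are fully configurable via the ``structure`` argument of
#: :func:`gen_tree_dgp`.  Preorder over leaves carries the means in their
#: printed order.
DEFAULT_TREE_STRUCTURE: dict = {
    "var": "X1",
    "point": 1.69,
    "left": {
        "var": "X2",
        "point": -0.28,
        "left": {
            "var": "X3",
            "point": -1.26,
            "left": {"mean": -1.88},
            "right": {"mean": -0.30},
        },
        "right": {
            "var": "X4",
            "point": 0.0,
            "left": {"mean": -0.31},
            "right": {"mean": 0.25},
        },
    },
    "right": {
        "var": "X3",
        "point": -1.26,
        "left": {"mean": -0.09},
        "right": {
            "var": "X4",
            "point": 0.0,
            "left": {"mean": 2.23},
            "right": {"mean": 1.35},
        },
    },
}


@dataclass
class Scenario:
    """One simulation condition."""

    kind: str  # tree | regression | hybrid | null
    n_train: int = 250
    n_test: int | None = None
    p: int = 6
    covariate_kind: str = CONTINUOUS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "regression", "hybrid", "null"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_test is None:
            self.n_test = self.n_train


def gen_covariates(n: int, p: int, kind: str, rng: np.random.Generator) -> pd.DataFrame:
    """i.i.d. N(0,1) columns, or i.i.d. Bernoulli(0.5) for ``kind="binary"``."""
    if kind == CONTINUOUS:
        X = rng.standard_normal((n, p))
    elif kind == BINARY:
        X = rng.integers(0, 2, size=(n, p)).astype(float)
    else:
        raise ValueError(f"unknown covariate kind {kind!r}")
    return pd.DataFrame(X, columns=[f"X{j + 1}" for j in range(p)])


def regression_eta(X: pd.DataFrame) -> np.ndarray:
    return X.to_numpy(dtype=float)[:, :6] @ REGRESSION_BETAS


def gen_regression(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Linear DGP: y ~ N(eta, 1); X6 is a pure-noise covariate."""
    X = gen_covariates(n, 6, CONTINUOUS, rng)
    y = regression_eta(X) + rng.standard_normal(n)
    return X.assign(y=y)


def hybrid_eta(X: pd.DataFrame) -> np.ndarray:
    x1 = X["X1"].to_numpy(dtype=float)
    x2 = X["X2"].to_numpy(dtype=float)
    x3 = X["X3"].to_numpy(dtype=float)
    return (
        0.5 * x1
        + 0.45 * x2
        + 0.3 * x3
        + 1.5 * ((x1 <= 0) & (x2 > 0) & (x3 <= 0))
        + 0.25 * ((x1 <= 0) & (x3 > 0))
        + 0.14 * ((x1 > 0) & (x2 > 0))
    )


def gen_hybrid(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Main effects of X1..X3 plus three subgroup indicators; X4..X6 noise."""
    X = gen_covariates(n, 6, CONTINUOUS, rng)
    y = hybrid_eta(X) + rng.standard_normal(n)
    return X.assign(y=y)


def tree_dgp_mean(X: pd.DataFrame, structure: dict | None = None) -> np.ndarray:
    """Route rows through a tree structure and return the leaf means."""
    structure = structure or DEFAULT_TREE_STRUCTURE
    out = np.empty(len(X), dtype=float)

    def route(node: dict, idx: np.ndarray) -> None:
        if "mean" in node:
            out[idx] = node["mean"]
            return
        v = X[node["var"]].to_numpy(dtype=float)[idx]
        go_left = v <= node["point"]
        route(node["left"], idx[go_left])
        route(node["right"], idx[~go_left])

    route(structure, np.arange(len(X)))
    return out


def gen_tree_dgp(
    n: int, rng: np.random.Generator, structure: dict | None = None
) -> pd.DataFrame:
    """7-leaf tree DGP on X1..X4 with X5, X6 pure noise; y ~ N(leaf mean, 1)."""
    X = gen_covariates(n, 6, CONTINUOUS, rng)
    y = tree_dgp_mean(X, structure) + rng.standard_normal(n)
    return X.assign(y=y)


def gen_null(n: int, rng: np.random.Generator, p: int = 6) -> pd.DataFrame:
    """Global null: y ~ N(0,1) unrelated to the covariates."""
    X = gen_covariates(n, p, CONTINUOUS, rng)
    return X.assign(y=rng.standard_normal(n))


_GENERATORS = {
    "tree": gen_tree_dgp,
    "regression": gen_regression,
    "hybrid": gen_hybrid,
    "null": gen_null,
}


@dataclass
class ScenarioResult:
    """Per-replicate records plus aggregates for one (scenario, method) cell."""

    scenario: Scenario
    method: str
    mse: np.ndarray
    n_terminal: np.ndarray
    type_i: np.ndarray

    @property
    def reps(self) -> int:
        return len(self.mse)

    def aggregate(self) -> dict:
        """Mean/SD of MSE, node-count mean and nearest-rank 20th/80th
        percentiles, and Type-I-error rate (NaN where not applicable)."""
        agg = {
            "mse_mean": float(np.mean(self.mse)),
            "mse_sd": float(np.std(self.mse, ddof=1)) if self.reps > 1 else 0.0,
        }
        if np.isnan(self.n_terminal).all():
            agg.update(nodes_mean=float("nan"), nodes_p20=float("nan"), nodes_p80=float("nan"))
        else:
            nodes = self.n_terminal[~np.isnan(self.n_terminal)]
            agg.update(
                nodes_mean=float(nodes.mean()),
                nodes_p20=float(np.percentile(nodes, 20, method="inverted_cdf")),
                nodes_p80=float(np.percentile(nodes, 80, method="inverted_cdf")),
            )
        if np.isnan(self.type_i).all():
            agg["type_i_rate"] = float("nan")
        else:
            agg["type_i_rate"] = float(np.nanmean(self.type_i))
        return agg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario.kind,
                "method": self.method,
                "rep": np.arange(self.reps),
                "n": self.scenario.n_train,
                "mse": self.mse,
                "n_terminal": self.n_terminal,
                "type_i": self.type_i,
            }
        )


def _fit_predict(
    method: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    params: FitParams,
) -> tuple[np.ndarray, float]:
    """Fit one method on ``train`` and predict ``test``; returns
    (predictions, terminal-node count — NaN for OLS)."""
    covs = [c for c in train.columns if c != "y"]
    if method == "ols":
        X = np.column_stack([np.ones(len(train)), train[covs].to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X, train["y"].to_numpy(dtype=float), rcond=None)
        Xt = np.column_stack([np.ones(len(test)), test[covs].to_numpy(dtype=float)])
        return Xt @ beta, float("nan")
    if method == "cart":
        tree = _cart.grow_cart(train, "y", params)
    elif method in ("cart_min", "cart_1se"):
        rule = "min" if method == "cart_min" else "one_se"
        _, tree, _ = _cart.select_cp(train, "y", params, rule=rule)
    elif method == "ctree":
        tree = _ctree.grow_ctree(train, "y", params)
    else:
        raise ValueError(f"unknown method {method!r}")
    return tree.predict_frame(test), float(tree.n_leaves)


def run_scenario(
    scenario: Scenario,
    method: str,
    reps: int,
    params: FitParams | None = None,
    structure: dict | None = None,
) -> ScenarioResult:
    """Monte-Carlo evaluation of one method under one DGP.

    Each replicate simulates an independent training and test set from the
    scenario's DGP, fits the method on the training set, and evaluates the
    test MSE; trees additionally record the terminal-node count, and under
    the null DGP a Type-I-error flag (>= 1 split).  Replicate RNG streams
    are spawned from ``scenario.seed``; tree cross-validation folds are
    seeded per replicate from the same stream.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    params = params or FitParams()
    gen = _GENERATORS[scenario.kind]
    gen_kwargs = {"structure": structure} if scenario.kind == "tree" and structure else {}
    mse = np.empty(reps)
    n_terminal = np.full(reps, np.nan)
    type_i = np.full(reps, np.nan)
    streams = np.random.SeedSequence(scenario.seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        train = gen(scenario.n_train, rng, **gen_kwargs)
        test = gen(scenario.n_test, rng, **gen_kwargs)
        rep_params = FitParams(
            **{**params.to_dict(), "seed": int(rng.integers(0, 2**31 - 1))}
        )
        pred, leaves = _fit_predict(method, train, test, rep_params)
        mse[r] = float(np.mean((test["y"].to_numpy(dtype=float) - pred) ** 2))
        n_terminal[r] = leaves
        if scenario.kind == "null" and not np.isnan(leaves):
            type_i[r] = float(leaves > 1)
    return ScenarioResult(scenario, method, mse, n_terminal, type_i)


def sample_size_sweep(
    method: str,
    sizes: tuple[int, ...] = (30, 250, 500, 1000, 3000, 5000),
    reps: int = 200,
    params: FitParams | None = None,
    seed: int = 0,
) -> dict[int, ScenarioResult]:
    """Regression-DGP performance across training sizes (test set same size)."""
    out = {}
    for i, n in enumerate(sizes):
        scenario = Scenario(kind="regression", n_train=n, seed=seed + i)
        out[n] = run_scenario(scenario, method, reps, params)
    return out


def summarize_results(results: list[ScenarioResult]) -> pd.DataFrame:
    """Aggregate a list of scenario results into a comparison table."""
    rows = []
    for res in results:
        row = {"scenario": res.scenario.kind, "method": res.method, "reps": res.reps}
        row.update(res.aggregate())
        rows.append(row)
    return pd.DataFrame(rows)
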