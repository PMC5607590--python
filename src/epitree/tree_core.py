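"""Shared data model for binary regression trees.

Both induction methods (greedy SSE-based CART and permutation-test-based
conditional inference trees) produce the same structure: a binary tree of
axis-aligned split rules whose terminal nodes partition the training sample
into subgroups, each predicted by its mean outcome.

Conventions
-----------
* Routing: an observation with ``x <= split_point`` goes left; binary 0/1
  covariates split at 0.5, so value 0 goes left.
* Node IDs are assigned by depth-first preorder with the root labelled 1,
  matching the numbering used in standard conditional-inference-tree
  displays (so a depth-2 tree has terminal nodes 3, 5, 6, 7 when the left
  branch is deeper).
* Leaf prediction is the arithmetic mean of the training outcomes in the
  leaf; no surrogate splits, and missing covariate values are rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"

__all__ = [
    "FitParams",
    "TreeNode",
    "DecisionTree",
    "SubgroupRule",
    "TreeParseError",
    "serialize",
    "deserialize",
    "detect_covariate_kinds",
]


class TreeParseError(ValueError):
    """A serialized tree document violates the schema."""


@dataclass
class FitParams:
    """Induction controls shared by both tree methods.

    Parameters
    ----------
    minsplit:
        Minimum number of observations a node must contain to be considered
        for splitting (default 20).
    minbucket:
        Minimum number of observations in a terminal node (default 7).
    cp:
        CART complexity parameter: a split is accepted only if it reduces
        the SSE by at least ``cp`` times the root SSE (default 0.01).
    alpha:
        CTree significance level for the multiplicity-adjusted global null
        hypothesis test at each node (default 0.05).
    pruning:
        CART pruning rule: ``"none"``, ``"min"`` (cp minimising the
        cross-validated error) or ``"one_se"`` (smallest subtree within one
        standard error of the minimum).
    cv_folds:
        Number of cross-validation folds used for pruning (default 10).
    seed:
        Seed for the fold assignment RNG.
    """

    minsplit: int = 20
    minbucket: int = 7
    cp: float = 0.01
    alpha: float = 0.05
    pruning: str = "none"
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")
        if self.minsplit < 1:
            raise ValueError("minsplit must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.cp < 0:
            raise ValueError("cp must be >= 0")
        if self.pruning not in ("none", "min", "one_se"):
            raise ValueError(f"unknown pruning rule {self.pruning!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        return {
            "minsplit": self.minsplit,
            "minbucket": self.minbucket,
            "cp": self.cp,
            "alpha": self.alpha,
            "pruning": self.pruning,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }


@dataclass
class TreeNode:
    """One node of a fitted regression tree.

    ``indices`` holds the positions (0-based row numbers into the training
    frame) of the observations contained in the node; it is carried on every
    node during fitting but is not part of the serialized document.
    """

    node_id: int
    n_obs: int
    node_mean: float
    sse: float
    split_var: str | None = None
    split_point: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    p_value: float | None = None
    indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def children(self) -> tuple["TreeNode", "TreeNode"] | None:
        if self.left is None:
            return None
        return (self.left, self.right)  # type: ignore[return-value]

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        if self.left is not None:
            yield from self.left.preorder()
            yield from self.right.preorder()  # type: ignore[union-attr]

    def leaves(self) -> Iterator["TreeNode"]:
        for node in self.preorder():
            if node.is_leaf:
                yield node

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def validate(self) -> None:
        """Check structural invariants, raising ``TreeParseError`` on failure."""
        for node in self.preorder():
            has_children = node.left is not None or node.right is not None
            has_both = node.left is not None and node.right is not None
            has_rule = node.split_var is not None and node.split_point is not None
            if has_children != has_rule or (has_children and not has_both):
                raise TreeParseError(
                    f"node {node.node_id}: a node must have either both "
                    "children and a split rule, or neither"
                )
            if has_both:
                l, r = node.left, node.right
                if l.n_obs + r.n_obs != node.n_obs:  # type: ignore[union-attr]
                    raise TreeParseError(
                        f"node {node.node_id}: children n_obs do not sum to parent"
                    )


def assign_preorder_ids(root: TreeNode) -> None:
    """Relabel ``node_id`` by depth-first preorder starting at 1."""
    for i, node in enumerate(root.preorder(), start=1):
        node.node_id = i


@dataclass
class SubgroupRule:
    """Conjunction of per-covariate half-open intervals ``(lower, upper]``.

    Only covariates appearing on the root-to-leaf path are present;
    unconstrained ends are ±inf.
    """

    intervals: dict[str, tuple[float, float]]

    def contains(self, row: Mapping[str, float]) -> bool:
        for var, (lo, hi) in self.intervals.items():
            v = row[var]
            if not (lo < v <= hi):
                return False
        return True


def detect_covariate_kinds(X: pd.DataFrame) -> dict[str, str]:
    """Classify each column as ``binary`` ({0,1}-valued) or ``continuous``."""
    kinds = {}
    for col in X.columns:
        vals = pd.unique(X[col].dropna())
        kinds[col] = BINARY if set(np.asarray(vals)) <= {0, 1} else CONTINUOUS
    return kinds


@dataclass
class DecisionTree:
    """A fitted regression tree: structure, covariate metadata and fit params."""

    root: TreeNode
    covariate_names: list[str]
    covariate_kinds: dict[str, str]
    method: str
    params: FitParams

    # ------------------------------------------------------------------
    # navigation
    # ------------------------------------------------------------------
    def nodes(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def find(self, node_id: int) -> TreeNode:
        for node in self.nodes():
            if node.node_id == node_id:
                return node
        raise KeyError(f"no node with id {node_id}")

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves

    @property
    def n_splits(self) -> int:
        return sum(1 for n in self.nodes() if not n.is_leaf)

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------
    def predict(self, row: Mapping[str, float]) -> float:
        """Route one observation to its terminal node and return the leaf mean."""
        node = self.root
        while not node.is_leaf:
            var = node.split_var
            if var not in row:
                raise ValueError(f"missing covariate {var!r} on the routing path")
            v = row[var]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"missing value for covariate {var!r} on the routing path")
            node = node.left if v <= node.split_point else node.right  # type: ignore
        return node.node_mean

    def route(self, row: Mapping[str, float]) -> TreeNode:
        """Return the terminal node an observation is routed to."""
        node = self.root
        while not node.is_leaf:
            v = row[node.split_var]  # type: ignore[index]
            node = node.left if v <= node.split_point else node.right  # type: ignore
        return node

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Vectorised prediction for every row of ``X``."""
        n = len(X)
        out = np.empty(n, dtype=float)
        cols = {v: X[v].to_numpy(dtype=float) for v in self.covariate_names if v in X}

        def _route(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.node_mean
                return
            var = node.split_var
            if var not in cols:
                raise ValueError(f"missing covariate {var!r} on the routing path")
            v = cols[var][idx]
            if np.isnan(v).any():
                raise ValueError(f"missing value for covariate {var!r} on the routing path")
            go_left = v <= node.split_point
            _route(node.left, idx[go_left])  # type: ignore[arg-type]
            _route(node.right, idx[~go_left])  # type: ignore[arg-type]

        _route(self.root, np.arange(n))
        return out

    # ------------------------------------------------------------------
    # partition & subgroup rules
    # ------------------------------------------------------------------
    def terminal_partition(self) -> list[tuple[int, np.ndarray]]:
        """Return ``(leaf node_id, training index set)`` per terminal node.

        The index sets are pairwise disjoint and their union is the full
        training index set.
        """
        out = []
        for leaf in self.root.leaves():
            if leaf.indices is None:
                raise ValueError("tree carries no training indices (deserialized?)")
            out.append((leaf.node_id, leaf.indices))
        return out

    def subgroup_rule(self, leaf_id: int) -> SubgroupRule:
        """Interval-conjunction description of one terminal node.

        Intersects all split conditions on the root-to-leaf path; repeated
        splits on one covariate tighten the interval.
        """
        path = self._path_to(leaf_id)
        if not path[-1].is_leaf:
            raise ValueError(f"node {leaf_id} is not a terminal node")
        intervals: dict[str, tuple[float, float]] = {}
        for parent, child in zip(path[:-1], path[1:]):
            var, point = parent.split_var, parent.split_point
            lo, hi = intervals.get(var, (-math.inf, math.inf))
            if child is parent.left:
                hi = min(hi, point)  # type: ignore[type-var]
            else:
                lo = max(lo, point)  # type: ignore[type-var]
            intervals[var] = (lo, hi)
        return SubgroupRule(intervals)

    def _path_to(self, node_id: int) -> list[TreeNode]:
        def rec(node: TreeNode) -> list[TreeNode] | None:
            if node.node_id == node_id:
                return [node]
            if node.is_leaf:
                return None
            for child in (node.left, node.right):
                sub = rec(child)  # type: ignore[arg-type]
                if sub is not None:
                    return [node] + sub
            return None

        path = rec(self.root)
        if path is None:
            raise KeyError(f"no node with id {node_id}")
        return path

    def describe(self) -> str:
        """Indented text rendering of the tree (one line per node)."""
        lines: list[str] = []

        def rec(node: TreeNode, depth: int, label: str) -> None:
            info = f"[{node.node_id}] {label}n={node.n_obs} mean={node.node_mean:.3f}"
            if not node.is_leaf:
                info += f" | split {node.split_var} <= {node.split_point:.3f}"
                if node.p_value is not None:
                    info += f" (p={node.p_value:.4f})"
            lines.append("  " * depth + info)
            if not node.is_leaf:
                rec(node.left, depth + 1, "L ")  # type: ignore[arg-type]
                rec(node.right, depth + 1, "R ")  # type: ignore[arg-type]

        rec(self.root, 0, "")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return serialize(self)

    @staticmethod
    def from_json(doc: str) -> "DecisionTree":
        return deserialize(doc)


def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {
        "node_id": node.node_id,
        "n": node.n_obs,
        "mean": node.node_mean,
        "sse": node.sse,
        "split": (
            None
            if node.is_leaf
            else {"var": node.split_var, "point": node.split_point}
        ),
    }
    if node.p_value is not None:
        d["p_value"] = node.p_value
    if not node.is_leaf:
        d["children"] = [_node_to_dict(node.left), _node_to_dict(node.right)]  # type: ignore[arg-type]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    try:
        node = TreeNode(
            node_id=int(d["node_id"]),
            n_obs=int(d["n"]),
            node_mean=float(d["mean"]),
            sse=float(d["sse"]),
            p_value=d.get("p_value"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise TreeParseError(f"malformed node document: {d!r}") from exc
    split = d.get("split")
    children = d.get("children")
    if split is not None:
        if not children or len(children) != 2:
            raise TreeParseError(
                f"node {node.node_id}: split rule present but children missing"
            )
        node.split_var = split["var"]
        node.split_point = float(split["point"])
        node.left = _node_from_dict(children[0])
        node.right = _node_from_dict(children[1])
    elif children:
        raise TreeParseError(f"node {node.node_id}: children present without a split rule")
    return node


def serialize(tree: DecisionTree) -> str:
    """Serialize a tree to the JSON document format (round-trip exact)."""
    doc = {
        "method": tree.method,
        "params": tree.params.to_dict(),
        "covariates": [
            {"name": name, "kind": tree.covariate_kinds[name]}
            for name in tree.covariate_names
        ],
        "root": _node_to_dict(tree.root),
    }
    return json.dumps(doc, indent=2)


def deserialize(doc: str) -> DecisionTree:
    """Parse a JSON tree document; raises ``TreeParseError`` on schema errors."""
    try:
        obj = json.loads(doc)
    except json.JSONDecodeError as exc:
        raise TreeParseError(f"invalid JSON: {exc}") from exc
    for key in ("method", "params", "covariates", "root"):
        if key not in obj:
            raise TreeParseError(f"missing top-level key {key!r}")
    root = _node_from_dict(obj["root"])
    tree = DecisionTree(
        root=root,
        covariate_names=[c["name"] for c in obj["covariates"]],
        covariate_kinds={c["name"]: c["kind"] for c in obj["covariates"]},
        method=obj["method"],
        params=FitParams(**obj["params"]),
    )
    root.validate()
    return tree
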