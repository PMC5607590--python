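"""CART induction: split search vs brute force, stopping, pruning, CV rules."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epitree import (
    FitParams,
    best_split,
    cost_complexity_path,
    gen_null,
    grow_cart,
    prune_at,
    select_cp,
    serialize,
)

from conftest import brute_force_best_split, step_data


class TestBestSplit:
    def test_four_point_step(self):
        # parent SSE 100 (mean 5, four deviations of 5), children pure
        out = best_split(np.array([1.0, 2, 3, 4]), np.array([0.0, 0, 10, 10]), 1)
        assert out == (2.5, pytest.approx(100.0))
        assert out == brute_force_best_split([1, 2, 3, 4], [0, 0, 10, 10], 1)

    def test_binary_covariate_single_candidate(self):
        out = best_split(np.array([0.0, 0, 1, 1]), np.array([1.0, 1, 3, 3]), 2)
        assert out == (0.5, pytest.approx(4.0))

    def test_constant_outcome_returns_none(self):
        assert best_split(np.array([1.0, 2, 3, 4]), np.full(4, 2.0), 1) is None

    def test_constant_covariate_returns_none(self):
        assert best_split(np.full(4, 1.0), np.array([0.0, 1, 2, 3]), 1) is None

    def test_minbucket_excludes_edge_candidates(self):
        x = np.arange(10, dtype=float)
        y = np.where(x <= 0.5, 100.0, 0.0)  # best unconstrained split at 0.5
        thr, _ = best_split(x, y, minbucket=3)
        assert thr == 2.5  # leftmost feasible candidate wins after exclusion

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 30), st.integers(1, 3))
    def test_matches_brute_force_oracle(self, seed, n, minbucket):
        rng = np.random.default_rng(seed)
        x = rng.choice([0.0, 1, 2, 3, 4], size=n) + rng.standard_normal(n) * (seed % 2)
        y = rng.standard_normal(n) + (x > x.mean())
        expected = brute_force_best_split(x, y, minbucket)
        got = best_split(x, y, minbucket)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == pytest.approx(expected[0])
            assert got[1] == pytest.approx(expected[1])


class TestGrowCart:
    def test_small_node_not_split(self, rng):
        data = pd.DataFrame({"x": rng.standard_normal(10), "y": rng.standard_normal(10)})
        tree = grow_cart(data, "y", FitParams(minsplit=20))
        assert tree.n_leaves == 1

    def test_step_signal_single_split(self):
        tree = grow_cart(step_data(), "y", FitParams(minsplit=20, minbucket=7, cp=0.01))
        assert tree.n_leaves == 2
        assert tree.root.split_var == "x"
        assert tree.root.split_point == 20.5

    def test_unpruned_null_keeps_splitting(self, rng):
        """With cp=0 on pure noise, splitting continues until the minsplit
        and minbucket guards are exhausted."""
        data = gen_null(250, rng)
        tree = grow_cart(data, "y", FitParams(cp=0.0))
        assert tree.n_leaves > 1
        for leaf in tree.root.leaves():
            assert leaf.n_obs < 20  # every splittable node was split
            assert leaf.n_obs >= 7

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            grow_cart(pd.DataFrame({"x": [], "y": []}), "y")

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"x": [1.0, np.nan, 3], "y": [0.0, 1, 2]})
        with pytest.raises(ValueError, match="missing"):
            grow_cart(data, "y")

    def test_deterministic_given_seed(self, rng):
        data = gen_null(200, rng)
        p = FitParams(seed=42)
        t1 = grow_cart(data, "y", p)
        t2 = grow_cart(data, "y", p)
        assert serialize(t1) == serialize(t2)

    def test_split_choice_matches_oracle_at_every_node(self):
        """On small instances the greedy splits equal an exhaustive search
        over all (covariate, midpoint) pairs."""
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(12, 31))
            p = int(rng.integers(1, 4))
            data = pd.DataFrame(
                rng.standard_normal((n, p)), columns=[f"X{j+1}" for j in range(p)]
            )
            data["y"] = rng.standard_normal(n) + 2 * (data["X1"] > 0)
            params = FitParams(minsplit=6, minbucket=2, cp=0.0)
            tree = grow_cart(data, "y", params)
            X = data[[c for c in data if c != "y"]]
            y = data["y"].to_numpy()
            for node in tree.nodes():
                if node.is_leaf:
                    continue
                best = None
                for col in X.columns:
                    cand = brute_force_best_split(
                        X[col].to_numpy()[node.indices], y[node.indices], 2
                    )
                    if cand and (best is None or cand[1] > best[2] + 1e-12):
                        best = (col, cand[0], cand[1])
                assert best is not None
                assert node.split_var == best[0]
                assert node.split_point == pytest.approx(best[1])


class TestCostComplexityPath:
    def test_root_only_single_entry(self, rng):
        data = pd.DataFrame({"x": rng.standard_normal(10), "y": rng.standard_normal(10)})
        seq = cost_complexity_path(grow_cart(data, "y"))
        assert len(seq) == 1

    def test_single_split_critical_cp_is_relative_reduction(self):
        data = step_data()
        tree = grow_cart(data, "y")
        seq = cost_complexity_path(tree)
        assert [e.tree.n_leaves for e in seq.entries] == [2, 1]
        root_sse = tree.root.sse
        reduction = root_sse - sum(l.sse for l in tree.root.leaves())
        assert seq.entries[1].cp == pytest.approx(reduction / root_sse)

    def test_sizes_strictly_decreasing_to_one(self, rng):
        data = gen_null(250, rng)
        seq = cost_complexity_path(grow_cart(data, "y", FitParams(cp=0.0)))
        sizes = [e.tree.n_leaves for e in seq.entries]
        assert sizes[-1] == 1
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        cps = [e.cp for e in seq.entries]
        assert all(a <= b + 1e-12 for a, b in zip(cps, cps[1:]))

    def test_training_mse_ordering(self, rng):
        """Unpruned training error never exceeds any pruned subtree's."""
        data = gen_null(250, rng)
        seq = cost_complexity_path(grow_cart(data, "y", FitParams(cp=0.0)))
        train_sse = [sum(l.sse for l in e.tree.root.leaves()) for e in seq.entries]
        assert all(train_sse[0] <= s + 1e-9 for s in train_sse[1:])

    def test_prune_at_selects_optimal_range(self):
        seq = cost_complexity_path(grow_cart(step_data(), "y"))
        assert prune_at(seq, 0.0).n_leaves == 2
        assert prune_at(seq, 1.0).n_leaves == 1


class TestSelectCp:
    def test_strong_step_signal_retained_by_both_rules(self):
        """A 5-sigma step is kept by both the min and the 1-SE rule."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(250)
            y = 5.0 * (x > 0) + rng.standard_normal(250)
            data = pd.DataFrame({"x1": x, "x2": rng.standard_normal(250), "y": y})
            params = FitParams(seed=seed)
            _, t_min, seq = select_cp(data, "y", params, rule="min")
            _, t_1se, _ = select_cp(data, "y", params, rule="one_se")
            assert t_min.n_leaves >= 2
            assert t_1se.n_leaves >= 2
            # 1-SE never selects a larger subtree than the min rule
            assert t_1se.n_leaves <= t_min.n_leaves

    def test_cv_errors_attached_and_nonnegative(self, rng):
        data = gen_null(250, rng)
        _, _, seq = select_cp(data, "y", FitParams(seed=3), rule="min")
        for e in seq.entries:
            assert e.cv_error_mean is not None and e.cv_error_mean >= 0
            assert e.cv_error_se is not None and e.cv_error_se >= 0

    def test_deterministic_given_seed(self, rng):
        data = gen_null(150, rng)
        p = FitParams(seed=9)
        cp1, t1, _ = select_cp(data, "y", p, rule="one_se")
        cp2, t2, _ = select_cp(data, "y", p, rule="one_se")
        assert cp1 == cp2 and serialize(t1) == serialize(t2)

    def test_n_smaller_than_folds_rejected(self, rng):
        data = pd.DataFrame({"x": rng.standard_normal(5), "y": rng.standard_normal(5)})
        with pytest.raises(ValueError, match="cv_folds"):
            select_cp(data, "y", FitParams(cv_folds=10), rule="min")


def test_first_split_matches_rpart(tmp_path, rng):
    """Independent reference check: on a dataset with clear signal, the
    grown tree's root split agrees with rpart's."""
    n = 120
    X = rng.standard_normal((n, 3))
    y = 2.0 * (X[:, 1] > 0.3) + rng.standard_normal(n)
    data = pd.DataFrame(X, columns=["X1", "X2", "X3"]).assign(y=y)
    csv = tmp_path / "d.csv"
    data.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        library(rpart)
        d <- read.csv("{csv}")
        fit <- rpart(y ~ ., data=d, method="anova",
                     control=rpart.control(minsplit=20, minbucket=7, cp=0.01, xval=0))
        s <- fit$splits
        cat(rownames(s)[1], s[1, "index"], "\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    var, thr = out.stdout.split()[:2]
    tree = grow_cart(data, "y")
    assert tree.root.split_var == var
    assert tree.root.split_point == pytest.approx(float(thr), abs=1e-6)
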