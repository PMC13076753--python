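"""Heterogeneity tree: splitting objective, greedy search, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from psadose.tree import build_tree, flatten_tree, render_tree, split_score


class TestSplitScore:
    def test_equal_means_zero(self):
        assert split_score([1.0, 1.0], [1.0]) == 0.0

    def test_hand_arithmetic(self):
        assert split_score([0.0, 0.0], [1.0, 1.0]) == pytest.approx(0.25)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_score([], [1.0])

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=20),
        st.lists(st.floats(-5, 5), min_size=1, max_size=20),
    )
    def test_equals_between_group_ss_over_n_squared(self, left, right):
        lv, rv = np.asarray(left), np.asarray(right)
        n = len(lv) + len(rv)
        grand = np.concatenate([lv, rv]).mean()
        bss = len(lv) * (lv.mean() - grand) ** 2 + len(rv) * (rv.mean() - grand) ** 2
        assert split_score(lv, rv) == pytest.approx(bss / n, abs=1e-9)


class TestBuildTree:
    def test_constant_theta_root_only(self):
        cov = pd.DataFrame({"bmi": np.linspace(20, 40, 30)})
        root = build_tree(cov, np.full(30, 0.3), min_leaf=1)
        assert root.is_leaf
        assert root.mean_cate == pytest.approx(0.3)

    def test_published_subgroup_structure_recovered(self):
        # 918 patients at effect 0.14 below the BMI cut, 317 at 0.52 above:
        # the first split lands at BMI 32.5 and the root mean is 0.2375
        rng = np.random.default_rng(0)
        bmi = np.r_[rng.uniform(20.0, 32.5, 918), rng.uniform(32.6, 45.0, 317)]
        theta = np.r_[np.full(918, 0.14), np.full(317, 0.52)]
        root = build_tree(pd.DataFrame({"bmi": bmi}), theta, min_leaf=50, max_depth=1)
        assert root.split is not None
        name, cut = root.split
        assert name == "bmi"
        assert 32.5 <= cut <= 32.6
        assert root.mean_cate == pytest.approx((918 * 0.14 + 317 * 0.52) / 1235)
        assert root.left.n == 918 and root.left.mean_cate == pytest.approx(0.14)
        assert root.right.n == 317 and root.right.mean_cate == pytest.approx(0.52)

    def test_six_point_toy_matches_exhaustive_search(self):
        x = np.arange(1.0, 7.0)
        theta = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        root = build_tree(pd.DataFrame({"x": x}), theta, min_leaf=1, max_depth=1)
        # brute force over all 5 midpoints
        best = max(
            ((thr, split_score(theta[x <= thr], theta[x > thr]))
             for thr in (x[:-1] + x[1:]) / 2),
            key=lambda p: p[1],
        )
        assert root.split == ("x", best[0])
        assert root.split[1] == pytest.approx(3.5)

    def test_greedy_equals_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 120
            cov = pd.DataFrame(
                {"a": rng.normal(0, 1, n), "b": rng.integers(0, 5, n).astype(float)}
            )
            theta = rng.normal(0.2, 0.3, n) + 0.4 * (cov["a"] > 0.3)
            root = build_tree(cov, theta.to_numpy(), min_leaf=5, max_depth=1)
            best_score, best_split = -1.0, None
            for name in sorted(cov.columns):
                vals = np.sort(cov[name].unique())
                for thr in (vals[:-1] + vals[1:]) / 2:
                    mask = cov[name].to_numpy() <= thr
                    if mask.sum() < 5 or (~mask).sum() < 5:
                        continue
                    s = split_score(theta[mask], theta[~mask])
                    if s > best_score + 1e-15:
                        best_score, best_split = s, (name, thr)
            assert root.split == best_split

    def test_weighted_mean_conservation_all_nodes(self, confounded_cohort):
        cov = confounded_cohort[["bmi", "age", "psaid_baseline"]]
        theta = confounded_cohort["_true_theta"].to_numpy() + np.random.default_rng(
            1
        ).normal(0, 0.05, len(cov))
        root = build_tree(cov, theta, min_leaf=50, max_depth=3)

        def check(node):
            if node.is_leaf:
                return
            lhs = node.mean_cate * node.n
            rhs = node.left.mean_cate * node.left.n + node.right.mean_cate * node.right.n
            assert lhs == pytest.approx(rhs, abs=1e-8)
            assert node.n == node.left.n + node.right.n
            check(node.left)
            check(node.right)

        check(root)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 200
        cov = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(5, 2, n)})
        theta = 0.2 + 0.5 * (cov["a"] > 0.0).to_numpy() + rng.normal(0, 0.01, n)
        root1 = build_tree(cov, theta, min_leaf=10, max_depth=2)
        perm = rng.permutation(n)
        root2 = build_tree(cov.iloc[perm].reset_index(drop=True), theta[perm],
                           min_leaf=10, max_depth=2)

        def structure(node):
            if node.is_leaf:
                return ("leaf", node.n, round(node.mean_cate, 9))
            return (node.split[0], round(node.split[1], 9),
                    structure(node.left), structure(node.right))

        assert structure(root1) == structure(root2)

    def test_min_leaf_respected(self):
        cov = pd.DataFrame({"x": np.arange(10.0)})
        theta = np.r_[np.zeros(9), 5.0]  # tempting 9/1 split forbidden
        root = build_tree(cov, theta, min_leaf=3, max_depth=2)

        def leaves(node):
            return [node.n] if node.is_leaf else leaves(node.left) + leaves(node.right)

        assert all(n >= 3 for n in leaves(root))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_tree(pd.DataFrame({"x": []}), np.array([]))


class TestFlatten:
    def test_root_only_single_leaf(self):
        cov = pd.DataFrame({"x": [1.0, 2.0]})
        root = build_tree(cov, np.array([0.5, 0.5]), min_leaf=1)
        out = flatten_tree(root)
        assert len(out) == 1
        assert out.loc[0, "n"] == 2

    def test_two_leaf_conditions_readable(self):
        rng = np.random.default_rng(0)
        bmi = np.r_[rng.uniform(20, 32.5, 60), rng.uniform(32.6, 45, 40)]
        theta = np.r_[np.full(60, 0.14), np.full(40, 0.52)]
        root = build_tree(pd.DataFrame({"bmi": bmi}), theta, min_leaf=10, max_depth=1)
        leaves = flatten_tree(root)
        conds = leaves["condition"].tolist()
        assert any(c.startswith("bmi <= 32.6") for c in conds)
        assert any(c.startswith("bmi > 32.6") for c in conds)
        assert 32.5 <= root.split[1] <= 32.7

    def test_leaf_counts_conserved(self, confounded_cohort):
        cov = confounded_cohort[["bmi", "age"]]
        theta = np.random.default_rng(2).normal(0.2, 0.2, len(cov))
        root = build_tree(cov, theta, min_leaf=30, max_depth=3)
        assert flatten_tree(root)["n"].sum() == root.n

    def test_render_puts_condition_true_child_first(self):
        rng = np.random.default_rng(0)
        bmi = np.r_[rng.uniform(20, 32, 30), rng.uniform(33, 45, 30)]
        theta = np.r_[np.full(30, 0.1), np.full(30, 0.5)]
        root = build_tree(pd.DataFrame({"bmi": bmi}), theta, min_leaf=5, max_depth=1)
        text = render_tree(root)
        assert text.index("<=") < text.index("] n=", text.index("<="))
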