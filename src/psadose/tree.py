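"""Greedy heterogeneity tree over per-patient treatment-effect estimates.

The tree partitions patients by baseline covariates so that subgroup mean
CATEs differ maximally between branches.  Splits maximize the between-child
heterogeneity score

    score = (n_L * n_R / n^2) * (mean_L - mean_R)^2

which equals the between-group sum of squares divided by n^2 — zero iff the
child means coincide.  Rows satisfying the split condition (value <= threshold
for numeric covariates, value == level for categoricals) go to the *left*
child, matching the usual rendering of such trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TreeNode", "split_score", "build_tree", "flatten_tree", "render_tree"]


@dataclass
class TreeNode:
    n: int
    mean_cate: float
    depth: int
    split: tuple | None = None  # (covariate, threshold_or_level)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def to_dict(self) -> dict:
        d = {"n": int(self.n), "mean_cate": float(self.mean_cate), "depth": int(self.depth)}
        if self.split is not None:
            cov, cut = self.split
            d["split"] = {"covariate": cov, "threshold": cut}
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


def split_score(left_values, right_values) -> float:
    """Heterogeneity score (n_L n_R / n^2)(mean_L - mean_R)^2; >= 0."""
    lv = np.asarray(left_values, dtype=float)
    rv = np.asarray(right_values, dtype=float)
    if len(lv) == 0 or len(rv) == 0:
        raise ValueError("both sides of a split must be non-empty")
    n = len(lv) + len(rv)
    return float(len(lv) * len(rv) / n**2 * (lv.mean() - rv.mean()) ** 2)


def _candidate_splits(col: pd.Series):
    """Yield (threshold_or_level, left_mask) candidates for one covariate."""
    if pd.api.types.is_numeric_dtype(col):
        vals = np.sort(col.unique().astype(float))
        mids = (vals[:-1] + vals[1:]) / 2.0
        arr = col.to_numpy(dtype=float)
        for thr in mids:
            yield float(thr), arr <= thr
    else:
        for lev in sorted(col.dropna().unique()):
            yield lev, (col == lev).to_numpy()


def _best_split(covariates: pd.DataFrame, theta: np.ndarray, min_leaf: int):
    """Exhaustive search over (covariate, threshold); deterministic tie-break
    by covariate name then lowest threshold (strict > keeps the first best)."""
    best = None  # (score, name, cut, mask)
    for name in sorted(covariates.columns):
        col = covariates[name]
        if col.isna().any():
            raise ValueError(f"tree covariate {name!r} has missing values")
        for cut, mask in _candidate_splits(col):
            n_l = int(mask.sum())
            if n_l < min_leaf or len(mask) - n_l < min_leaf:
                continue
            s = split_score(theta[mask], theta[~mask])
            if best is None or s > best[0] + 1e-15:
                best = (s, name, cut, mask)
    return best


def build_tree(
    covariates: pd.DataFrame,
    theta_hat,
    min_leaf: int = 50,
    max_depth: int = 3,
) -> TreeNode:
    """Greedy recursive partitioning of thetâ(x).

    Stops when the depth limit is reached, a node is too small to split with
    both children >= ``min_leaf``, or no split strictly improves the score
    above zero.  Invariant: each parent's mean CATE is the size-weighted mean
    of its children's.
    """
    theta = np.asarray(theta_hat, dtype=float)
    if len(covariates) == 0:
        raise ValueError("empty input")
    if len(covariates) != len(theta):
        raise ValueError("covariates and theta_hat lengths differ")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        sub_theta = theta[idx]
        node = TreeNode(n=len(idx), mean_cate=float(sub_theta.mean()), depth=depth)
        if depth >= max_depth or len(idx) < 2 * min_leaf:
            return node
        best = _best_split(covariates.iloc[idx].reset_index(drop=True), sub_theta, min_leaf)
        # scores at fp-noise level (constant theta) do not count as improvement
        if best is None or best[0] <= 1e-12 * max(1.0, sub_theta.var()):
            return node
        _, name, cut, mask = best
        node.split = (name, cut)
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(len(theta)), 0)


def _condition(split: tuple, satisfied: bool) -> str:
    name, cut = split
    if isinstance(cut, str):
        op = "==" if satisfied else "!="
        return f"{name} {op} {cut}"
    return f"{name} {'<=' if satisfied else '>'} {cut:g}"


def flatten_tree(root: TreeNode) -> pd.DataFrame:
    """Leaf table: conjunctive path condition, subgroup size, mean CATE."""
    leaves = []

    def walk(node: TreeNode, path: list[str]):
        if node.is_leaf:
            leaves.append(
                {
                    "condition": " & ".join(path) if path else "(all patients)",
                    "n": int(node.n),
                    "mean_cate": float(node.mean_cate),
                    "depth": int(node.depth),
                }
            )
            return
        walk(node.left, path + [_condition(node.split, True)])
        walk(node.right, path + [_condition(node.split, False)])

    walk(root, [])
    return pd.DataFrame(leaves)


def render_tree(root: TreeNode) -> str:
    """Plain-text rendering; the condition-true child is printed first (left)."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, label: str):
        lines.append(
            f"{prefix}{label}n={node.n}  mean CATE={node.mean_cate:+.3f}"
        )
        if not node.is_leaf:
            walk(node.left, prefix + "  ", f"[{_condition(node.split, True)}] ")
            walk(node.right, prefix + "  ", f"[{_condition(node.split, False)}] ")

    walk(root, "", "")
    return "\n".join(lines)
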