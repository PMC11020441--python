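"""Path-dependent TreeSHAP for sklearn decision trees.

Computes exact Shapley attributions for a single regression-valued decision
tree under the path-dependent feature perturbation scheme: the conditional
expectation for a feature subset follows the training cover (node sample
weights) down branches whose split feature is outside the subset.  The
polynomial-time algorithm maintains, along each root-to-leaf path, the
weighted fractions of feature subsets that flow ("one fraction") or would
flow under the background distribution ("zero fraction") through each split,
extending and unwinding the path as features enter and leave.

Also provides :func:`brute_force_shap`, an exponential-time oracle that
enumerates feature subsets directly; it is used by the test suite to verify
the fast path on small trees and has no role in production code paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np

__all__ = ["TreeArrays", "from_sklearn_tree", "tree_shap", "expected_value",
           "brute_force_shap"]


@dataclass
class TreeArrays:
    """Flat array view of one decision tree with scalar leaf values."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray              # scalar per node (used at leaves)
    node_sample_weight: np.ndarray


def from_sklearn_tree(tree, value: np.ndarray | None = None) -> TreeArrays:
    """Wrap an ``sklearn.tree._tree.Tree``.

    ``value`` overrides the per-node scalar (e.g. class-1 probability for
    classification trees); by default the regression value is used.
    """
    if value is None:
        value = tree.value[:, 0, 0].astype(float)
    return TreeArrays(
        children_left=tree.children_left,
        children_right=tree.children_right,
        feature=tree.feature,
        threshold=tree.threshold,
        value=np.asarray(value, dtype=float),
        node_sample_weight=tree.weighted_n_node_samples.astype(float),
    )


def expected_value(t: TreeArrays, node: int = 0) -> float:
    """Cover-weighted mean leaf value below ``node`` (the empty-set output)."""
    if t.children_left[node] < 0:
        return float(t.value[node])
    l, r = t.children_left[node], t.children_right[node]
    w = t.node_sample_weight
    return float(
        (w[l] * expected_value(t, l) + w[r] * expected_value(t, r)) / w[node]
    )


def _extend(path: np.ndarray, m: int, pz: float, po: float, pi: int) -> None:
    path[m, 0] = pi
    path[m, 1] = pz
    path[m, 2] = po
    path[m, 3] = 1.0 if m == 0 else 0.0
    for i in range(m - 1, -1, -1):
        path[i + 1, 3] += po * path[i, 3] * (i + 1) / (m + 1)
        path[i, 3] = pz * path[i, 3] * (m - i) / (m + 1)


def _unwind(path: np.ndarray, m: int, i: int) -> None:
    one = path[i, 2]
    zero = path[i, 1]
    n = path[m, 3]
    for j in range(m - 1, -1, -1):
        if one != 0:
            t = path[j, 3]
            path[j, 3] = n * (m + 1) / ((j + 1) * one)
            n = t - path[j, 3] * zero * (m - j) / (m + 1)
        else:
            path[j, 3] = path[j, 3] * (m + 1) / (zero * (m - j))
    for j in range(i, m):
        path[j, 0:3] = path[j + 1, 0:3]


def _unwound_sum(path: np.ndarray, m: int, i: int) -> float:
    one = path[i, 2]
    zero = path[i, 1]
    total = 0.0
    if one != 0:
        n = path[m, 3]
        for j in range(m - 1, -1, -1):
            t = n * (m + 1) / ((j + 1) * one)
            total += t
            n = path[j, 3] - t * zero * (m - j) / (m + 1)
    else:
        for j in range(m - 1, -1, -1):
            total += path[j, 3] * (m + 1) / (zero * (m - j))
    return total


def _recurse(
    t: TreeArrays,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    depth: int,
    parent_path: np.ndarray,
    pz: float,
    po: float,
    pi: int,
) -> None:
    path = parent_path.copy()
    _extend(path, depth, pz, po, pi)
    left = t.children_left[node]
    if left < 0:
        for i in range(1, depth + 1):
            w = _unwound_sum(path, depth, i)
            phi[int(path[i, 0])] += w * (path[i, 2] - path[i, 1]) * t.value[node]
        return
    right = t.children_right[node]
    split = int(t.feature[node])
    if x[split] <= t.threshold[node]:
        hot, cold = left, right
    else:
        hot, cold = right, left
    w = t.node_sample_weight
    hot_frac = w[hot] / w[node]
    cold_frac = w[cold] / w[node]
    iz, io = 1.0, 1.0
    k = 0
    for i in range(1, depth + 1):
        if int(path[i, 0]) == split:
            k = i
            break
    d = depth
    if k > 0:
        iz, io = path[k, 1], path[k, 2]
        _unwind(path, d, k)
        d -= 1
    _recurse(t, x, phi, hot, d + 1, path, hot_frac * iz, io, split)
    _recurse(t, x, phi, cold, d + 1, path, cold_frac * iz, 0.0, split)


def tree_shap(t: TreeArrays, X: np.ndarray) -> np.ndarray:
    """Shapley attributions of one tree for each row of ``X`` (n x M).

    ``sum(phi[i]) + expected_value(t) == tree prediction for X[i]`` exactly
    (up to float round-off).
    """
    X = np.asarray(X, dtype=float)
    n, m_feat = X.shape
    max_depth = _depth(t, 0) + 2
    phi = np.zeros((n, m_feat))
    for i in range(n):
        path = np.zeros((max_depth + 1, 4))
        _recurse(t, X[i], phi[i], 0, 0, path, 1.0, 1.0, -1)
    return phi


def _depth(t: TreeArrays, node: int) -> int:
    if t.children_left[node] < 0:
        return 0
    return 1 + max(_depth(t, t.children_left[node]),
                   _depth(t, t.children_right[node]))


# ---------------------------------------------------------------------------
# Brute-force oracle (test use)
# ---------------------------------------------------------------------------


def _cond_expectation(t: TreeArrays, x: np.ndarray, subset: frozenset,
                      node: int = 0) -> float:
    """E[f(x) | x_S] under the path-dependent (cover-weighted) scheme."""
    if t.children_left[node] < 0:
        return float(t.value[node])
    split = int(t.feature[node])
    l, r = t.children_left[node], t.children_right[node]
    if split in subset:
        nxt = l if x[split] <= t.threshold[node] else r
        return _cond_expectation(t, x, subset, nxt)
    w = t.node_sample_weight
    return float(
        (
            w[l] * _cond_expectation(t, x, subset, l)
            + w[r] * _cond_expectation(t, x, subset, r)
        )
        / w[node]
    )


def brute_force_shap(t: TreeArrays, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration over the tree's used
    features (unused features are null players with attribution 0)."""
    x = np.asarray(x, dtype=float)
    used = sorted({int(f) for f in t.feature if f >= 0})
    m = len(used)
    phi = np.zeros(x.shape[0])
    for j in used:
        others = [f for f in used if f != j]
        for k in range(m):
            for combo in combinations(others, k):
                s = frozenset(combo)
                weight = factorial(k) * factorial(m - k - 1) / factorial(m)
                phi[j] += weight * (
                    _cond_expectation(t, x, s | {j}) - _cond_expectation(t, x, s)
                )
    return phi
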