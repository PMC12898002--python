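"""Exact path-dependent Shapley attributions for decision trees.

Implements the polynomial-time tree-path Shapley algorithm: for one decision
tree the coalition value v(S) is the cover-weighted conditional expectation
E[f(x) | x_S] obtained by following the split when the split feature is in S
and averaging the children by their training cover otherwise.  The recursion
maintains a path of unique features with "one" and "zero" flow fractions and
Shapley permutation weights, extended at every split and unwound on repeated
features, yielding the exact Shapley values of v in time polynomial in the
number of leaves and the path depth.

Local accuracy holds exactly: sum(phi) + E[f] == f(x) for every sample, which
the feature-ranking stage relies on as a correctness guard.

``brute_force_shap`` computes the same values by explicit subset enumeration
over the features the tree actually uses; it is exponential and exists as an
independent test oracle only.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np

__all__ = ["tree_shap_values", "ensemble_shap_values", "brute_force_shap",
           "tree_expected_value"]


def _tree_arrays(sk_tree):
    t = sk_tree.tree_
    values = t.value.reshape(t.node_count, -1)
    if values.shape[1] > 1:  # classifier: probability of the last class
        row_sums = values.sum(axis=1, keepdims=True)
        leaf_val = (values / row_sums)[:, -1]
    else:
        leaf_val = values[:, 0]
    return (t.children_left, t.children_right, t.feature, t.threshold,
            t.weighted_n_node_samples, leaf_val)


def tree_expected_value(sk_tree) -> float:
    """Cover-weighted mean leaf value = v(empty set)."""
    left, right, feat, thr, cover, val = _tree_arrays(sk_tree)
    leaves = left < 0
    return float(np.sum(cover[leaves] * val[leaves]) / cover[0])


def _extend(path, pz, po, pi):
    path = [row[:] for row in path]
    depth = len(path)
    path.append([pi, pz, po, 1.0 if depth == 0 else 0.0])
    for i in range(depth - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (depth + 1)
        path[i][3] = pz * path[i][3] * (depth - i) / (depth + 1)
    return path


def _unwind(path, index):
    depth = len(path) - 1
    one = path[index][2]
    zero = path[index][1]
    path = [row[:] for row in path]
    n = path[depth][3]
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = path[i][3]
            path[i][3] = n * (depth + 1) / ((i + 1) * one)
            n = tmp - path[i][3] * zero * (depth - i) / (depth + 1)
        else:
            path[i][3] = path[i][3] * (depth + 1) / (zero * (depth - i))
    for i in range(index, depth):
        path[i][0], path[i][1], path[i][2] = path[i + 1][0], path[i + 1][1], path[i + 1][2]
    return path[:-1]


def _unwound_sum(path, index):
    depth = len(path) - 1
    one = path[index][2]
    zero = path[index][1]
    n = path[depth][3]
    total = 0.0
    if one != 0:
        for i in range(depth - 1, -1, -1):
            tmp = n / ((i + 1) * one)
            total += tmp
            n = path[i][3] - tmp * zero * (depth - i)
    else:
        for i in range(depth - 1, -1, -1):
            total += path[i][3] / (zero * (depth - i))
    return total * (depth + 1)


def tree_shap_values(sk_tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for each row of ``X`` under one fitted sklearn
    tree; returns (phi of shape (n, M), expected_value)."""
    X = np.asarray(X, dtype=float)
    left, right, feat, thr, cover, val = _tree_arrays(sk_tree)
    M = X.shape[1]
    phi = np.zeros((X.shape[0], M))

    def recurse(node, path, pz, po, pi, x, out):
        path = _extend(path, pz, po, pi)
        if left[node] < 0:
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                out[el[0]] += w * (el[2] - el[1]) * val[node]
            return
        split = feat[node]
        if x[split] <= thr[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        hot_z = cover[hot] / cover[node]
        cold_z = cover[cold] / cover[node]
        iz, io = 1.0, 1.0
        k = next((i for i in range(len(path)) if path[i][0] == split), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            path = _unwind(path, k)
        recurse(hot, path, hot_z * iz, io, split, x, out)
        recurse(cold, path, cold_z * iz, 0.0, split, x, out)

    for r in range(X.shape[0]):
        recurse(0, [], 1.0, 1.0, -1, X[r], phi[r])
    return phi, tree_expected_value(sk_tree)


def ensemble_shap_values(trees, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean attributions and expected value over a list of fitted trees
    (the attribution of an average of trees is the average of attributions)."""
    phis = []
    bases = []
    for t in trees:
        p, b = tree_shap_values(t, X)
        phis.append(p)
        bases.append(b)
    return np.mean(phis, axis=0), float(np.mean(bases))


# ---------------------------------------------------------------------------
# brute-force oracle (test use only)

def _cond_exp(node, x, S, left, right, feat, thr, cover, val):
    if left[node] < 0:
        return val[node]
    args = (x, S, left, right, feat, thr, cover, val)
    if feat[node] in S:
        child = left[node] if x[feat[node]] <= thr[node] else right[node]
        return _cond_exp(child, *args)
    wl = cover[left[node]] / cover[node]
    wr = cover[right[node]] / cover[node]
    return (wl * _cond_exp(left[node], *args) +
            wr * _cond_exp(right[node], *args))


def brute_force_shap(sk_tree, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration over the features the tree
    uses (exponential; oracle for small trees only)."""
    left, right, feat, thr, cover, val = _tree_arrays(sk_tree)
    x = np.asarray(x, dtype=float)
    used = sorted(set(int(f) for f in feat if f >= 0))
    M = len(used)
    phi = np.zeros(x.size)

    def v(S):
        return _cond_exp(0, x, frozenset(S), left, right, feat, thr, cover, val)

    for i in used:
        others = [f for f in used if f != i]
        for k in range(M):
            for S in combinations(others, k):
                w = factorial(k) * factorial(M - k - 1) / factorial(M)
                phi[i] += w * (v(set(S) | {i}) - v(S))
    return phi
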