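"""Multivariate regression trees (MRT) and chronological clustering.

An MRT recursively partitions the observations of a multivariate response by
greedy binary splits on the predictors, minimizing total within-node sum of
squares.  Ordered predictors split at boundaries between adjacent values;
categorical predictors with few levels are split by exhaustive binary
partition search.  Each split's explained-variance gain is tested by a
within-node permutation test (the split R² is the RDA R² of the induced
two-level factor), and growth stops at ``max_leaves`` or at the first
non-significant split.

Chronological clustering is the special case with time as the only
predictor: the best single split over the chronological boundaries yields a
temporally contiguous pre-shift / post-shift partition per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SplitNode",
    "SplitTree",
    "MultivariateRegressionTree",
    "mrt_fit",
    "chronological_split",
    "ChronoSplit",
]

CATEGORICAL_CAP = 15  # beyond this, levels are ordered by centroid heuristic


# ----------------------------------------------------------------- helpers
def _node_ss(y: np.ndarray) -> float:
    c = y.mean(axis=0)
    return float(((y - c) ** 2).sum())


def _between_ss(sum1, n1, sum_all, n_all) -> float:
    """Between-group SS of a binary partition from group sums."""
    sum2 = sum_all - sum1
    n2 = n_all - n1
    if n1 == 0 or n2 == 0:
        return -np.inf
    tot = float((sum_all @ sum_all)) / n_all
    return float(sum1 @ sum1) / n1 + float(sum2 @ sum2) / n2 - tot


def _best_ordered(y: np.ndarray, x: np.ndarray):
    """Best boundary split of an ordered predictor; returns (gain, threshold,
    left mask)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.cumsum(ys, axis=0)
    n = len(xs)
    total = csum[-1]
    boundaries = np.nonzero(np.diff(xs) > 0)[0]  # split after position b
    best = (-np.inf, None, None)
    for b in boundaries:
        gain = _between_ss(csum[b], b + 1, total, n)
        if gain > best[0]:
            thr = (xs[b] + xs[b + 1]) / 2.0
            best = (gain, thr, x <= thr)
    return best


def _best_categorical(y: np.ndarray, x: np.ndarray):
    """Best binary partition of a categorical predictor's levels.

    Exhaustive over 2^(k−1) − 1 partitions for k ≤ CATEGORICAL_CAP; above
    the cap, levels are ordered by their centroid's projection on the first
    principal axis of the level centroids and treated as ordered (heuristic).
    Returns (gain, frozenset of left levels, left mask, heuristic flag).
    """
    levels, codes = np.unique(x, return_inverse=True)
    k = len(levels)
    if k < 2:
        return (-np.inf, None, None, False)
    sums = np.zeros((k, y.shape[1]))
    np.add.at(sums, codes, y)
    counts = np.bincount(codes, minlength=k).astype(float)
    total, n = sums.sum(axis=0), len(x)
    if k <= CATEGORICAL_CAP:
        best = (-np.inf, None, None, False)
        # fix level 0 on the left to enumerate each partition once
        others = range(1, k)
        for size in range(0, k - 1 + 1):
            for extra in combinations(others, size):
                left = (0,) + extra
                if len(left) == k:
                    continue
                s1 = sums[list(left)].sum(axis=0)
                n1 = counts[list(left)].sum()
                gain = _between_ss(s1, n1, total, n)
                if gain > best[0]:
                    left_levels = frozenset(levels[list(left)].tolist())
                    best = (gain, left_levels, np.isin(x, list(left_levels)), False)
        return best
    # heuristic ordering of many levels along the first centroid axis
    centroids = sums / counts[:, None]
    cc = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(cc, full_matrices=False)
    proj = cc @ vt[0]
    order = np.argsort(proj)
    best = (-np.inf, None, None, True)
    csum = np.cumsum(sums[order], axis=0)
    ccount = np.cumsum(counts[order])
    for b in range(k - 1):
        gain = _between_ss(csum[b], ccount[b], total, n)
        if gain > best[0]:
            left_levels = frozenset(levels[order[: b + 1]].tolist())
            best = (gain, left_levels, np.isin(x, list(left_levels)), True)
    return best


def _best_split(y: np.ndarray, predictors: pd.DataFrame):
    """Best split over all predictors within one node.

    Returns (gain, predictor name, rule, left mask, heuristic flag) with
    rule either ("<=", threshold) or ("in", frozenset of levels)."""
    best = (-np.inf, None, None, None, False)
    for name in predictors.columns:
        col = predictors[name].to_numpy()
        if np.issubdtype(col.dtype, np.number):
            gain, thr, mask = _best_ordered(y, col.astype(float))
            if gain > best[0]:
                best = (gain, name, ("<=", float(thr)), mask, False)
        else:
            gain, left, mask, heur = _best_categorical(y, col)
            if gain > best[0]:
                best = (gain, name, ("in", left), mask, heur)
    return best


def _split_p_value(y, predictors, observed_gain, node_ss, n_perm, rng) -> float:
    """Permutation p for a node's best split: responses are shuffled within
    the node and the best achievable split gain recomputed."""
    if node_ss <= 0:
        return 1.0
    obs_r2 = observed_gain / node_ss
    exceed = 0
    n = len(y)
    for _ in range(n_perm):
        perm_y = y[rng.permutation(n)]
        gain, *_ = _best_split(perm_y, predictors)
        exceed += (gain / node_ss) >= obs_r2 - 1e-12
    return (exceed + 1) / (n_perm + 1)


# -------------------------------------------------------------------- tree
@dataclass
class SplitNode:
    node_id: int
    indices: np.ndarray = field(repr=False)
    ss: float = 0.0
    predictor: str | None = None
    rule: tuple | None = None
    p: float | None = None
    heuristic: bool = False
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"node_id": self.node_id, "n_obs": int(len(self.indices)), "ss": self.ss}
        if not self.is_leaf:
            rule_kind, rule_val = self.rule
            d.update(
                predictor=self.predictor,
                rule={"kind": rule_kind,
                      "value": sorted(rule_val) if rule_kind == "in" else rule_val},
                p=self.p,
                heuristic=self.heuristic,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


@dataclass
class SplitTree:
    root: SplitNode
    labels: np.ndarray           # leaf label per observation
    r2_path: list[float]         # cumulative R² after each accepted split
    total_ss: float

    @property
    def n_leaves(self) -> int:
        return len(np.unique(self.labels))

    @property
    def r2(self) -> float:
        return self.r2_path[-1] if self.r2_path else 0.0

    def to_dict(self) -> dict:
        return {
            "total_ss": self.total_ss,
            "r2_path": self.r2_path,
            "n_leaves": int(self.n_leaves),
            "root": self.root.to_dict(),
        }


class MultivariateRegressionTree(BaseEstimator):
    """Greedy multivariate regression tree with permutation-tested splits.

    Parameters
    ----------
    max_leaves : int
        Upper bound on the number of terminal groups.
    alpha : float
        Significance level a split must reach to be accepted.
    n_perm : int
        Permutations for each split test (0 disables testing — every best
        split is accepted up to ``max_leaves``).
    seed : int
        Seed for the permutation stream.

    After ``fit(Y, predictors)``: ``tree_`` (:class:`SplitTree`),
    ``labels_``, ``r2_``.
    """

    def __init__(self, max_leaves: int = 4, alpha: float = 0.05,
                 n_perm: int = 999, seed: int = 0):
        self.max_leaves = max_leaves
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, Y, predictors: pd.DataFrame) -> "MultivariateRegressionTree":
        y = np.asarray(Y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        predictors = pd.DataFrame(predictors).reset_index(drop=True)
        if len(predictors) != len(y):
            raise ValueError("predictors must align with response rows")
        rng = np.random.default_rng(self.seed)
        n = len(y)
        total_ss = _node_ss(y)
        root = SplitNode(0, np.arange(n), ss=total_ss)
        leaves = [root]
        next_id = 1
        r2_path: list[float] = []
        explained = 0.0
        while len(leaves) < self.max_leaves:
            # best candidate split among current leaves
            best = None
            for leaf in leaves:
                if len(leaf.indices) < 2 or leaf.ss <= 0:
                    continue
                sub_y = y[leaf.indices]
                sub_p = predictors.iloc[leaf.indices]
                gain, name, rule, mask, heur = _best_split(sub_y, sub_p)
                if name is None or not np.isfinite(gain) or gain <= 0:
                    continue
                if best is None or gain > best[0]:
                    best = (gain, leaf, name, rule, mask, heur)
            if best is None:
                break
            gain, leaf, name, rule, mask, heur = best
            if self.n_perm:
                p = _split_p_value(
                    y[leaf.indices], predictors.iloc[leaf.indices],
                    gain, leaf.ss, self.n_perm, rng,
                )
                if p > self.alpha:
                    break
            else:
                p = None
            li = leaf.indices[mask]
            ri = leaf.indices[~mask]
            leaf.predictor, leaf.rule, leaf.p, leaf.heuristic = name, rule, p, heur
            leaf.left = SplitNode(next_id, li, ss=_node_ss(y[li]))
            leaf.right = SplitNode(next_id + 1, ri, ss=_node_ss(y[ri]))
            next_id += 2
            leaves.remove(leaf)
            leaves += [leaf.left, leaf.right]
            explained += gain
            r2_path.append(explained / total_ss if total_ss > 0 else 0.0)
        labels = np.empty(n, dtype=int)
        for leaf in leaves:
            labels[leaf.indices] = leaf.node_id
        self.tree_ = SplitTree(root, labels, r2_path, total_ss)
        self.labels_ = labels
        self.r2_ = self.tree_.r2
        return self


def mrt_fit(Y, predictors, max_leaves: int = 4, alpha: float = 0.05,
            n_perm: int = 999, seed: int = 0) -> SplitTree:
    """Functional wrapper over :class:`MultivariateRegressionTree`."""
    est = MultivariateRegressionTree(max_leaves, alpha, n_perm, seed)
    return est.fit(Y, predictors).tree_


@dataclass(frozen=True)
class ChronoSplit:
    boundary: float              # threshold: pre-shift is time ≤ boundary
    labels: np.ndarray           # 0 = pre-shift, 1 = post-shift
    r2: float
    p: float | None
    n_perm: int

    @property
    def shift_time(self) -> float:
        """First time step of the post-shift group's side of the boundary."""
        return self.boundary


def chronological_split(Y, time, n_perm: int = 999, seed: int = 0) -> ChronoSplit:
    """Best single chronological split of a multivariate response.

    Searches the n_distinct − 1 boundaries between consecutive time values
    for the binary, temporally contiguous partition maximizing explained SS
    (the split R² equals the RDA R² of the induced two-level factor) and
    tests it by permuting responses over observations.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    t = np.asarray(time, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time values")
    total = _node_ss(y)
    if total <= 0:
        raise ValueError("constant response")
    gain, thr, mask = _best_ordered(y, t)
    r2 = gain / total
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        exceed = 0
        n = len(y)
        for _ in range(n_perm):
            g, *_ = _best_ordered(y[rng.permutation(n)], t)
            exceed += (g / total) >= r2 - 1e-12
        p = (exceed + 1) / (n_perm + 1)
    return ChronoSplit(
        boundary=float(thr), labels=(~mask).astype(int), r2=float(r2),
        p=p, n_perm=n_perm,
    )
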