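"""Total beta diversity as community variance, and Local Contributions to
Beta Diversity (LCBD) with permutation significance.

The total sum of squares of a community is read directly off the
percentage-difference matrix: because √d is Euclidean, the raw d values are
the *squared* embedded distances, so SS_total = (1/N)·Σ_{i<j} d_ij and
BD_total = SS_total/(N−1) is the total variance (at most 0.5 for the
percentage difference).  LCBD_i is observation i's share of that variance:
the i-th diagonal element of the Gower-centered matrix of −½·d, divided by
SS_total.  Significance of each LCBD is assessed by permuting every species
column independently across observations (the null of no observation-level
compositional uniqueness) and recomputing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .community import CommunityTable
from .dissimilarity import decompose_matrix, gower_center

__all__ = [
    "BetaDivResult",
    "BetaDiversity",
    "total_ss",
    "bd_total",
    "lcbd",
    "lcbd_significance",
]


class DegenerateTableError(ValueError):
    """All observations identical: beta diversity is zero, LCBD undefined."""


def total_ss(d_total: np.ndarray, n_obs: int | None = None) -> float:
    """SS_total = (1/N) · Σ over the lower triangle of the percentage-
    difference matrix (the d values being squared embedded distances)."""
    d = np.asarray(d_total, dtype=float)
    n = d.shape[0] if n_obs is None else n_obs
    if n < 2:
        raise ValueError("need at least 2 observations")
    return float(np.tril(d, k=-1).sum() / n)


def bd_total(ss: float, n_obs: int) -> float:
    """Total beta diversity BD_total = SS_total / (N − 1), in [0, 0.5]."""
    if n_obs < 2:
        raise ValueError("need at least 2 observations")
    if ss < 0:
        raise ValueError("SS_total must be non-negative")
    return ss / (n_obs - 1)


def _lcbd_from_d(d: np.ndarray) -> tuple[np.ndarray, float]:
    g = gower_center(-0.5 * d)
    diag = np.diag(g).copy()
    ss = float(diag.sum())  # trace identity: Σ diag = SS_total
    return diag, ss


def lcbd(d_total: np.ndarray) -> np.ndarray:
    """Per-observation LCBD fractions (non-negative, summing to 1)."""
    d = np.asarray(d_total, dtype=float)
    diag, ss = _lcbd_from_d(d)
    if ss <= 0:
        raise DegenerateTableError("all observations identical: SS_total = 0")
    return diag / ss


def lcbd_significance(
    table: CommunityTable,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permutation p-values for each observation's LCBD.

    Each permutation shuffles every species column independently across
    observations; p_i = (#{LCBD_i^perm ≥ LCBD_i^obs} + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    rng = np.random.default_rng(seed)
    X = table.matrix()
    n, s = X.shape
    observed = lcbd(decompose_matrix(table).d_total)
    exceed = np.zeros(n)
    work = table.copy()
    cols = np.arange(s)
    for _ in range(n_perm):
        # independent permutation of every species column in one shot
        order = rng.random((n, s)).argsort(axis=0)
        work.values.iloc[:, :] = X[order, cols]
        d = decompose_matrix(work).d_total
        diag, ss = _lcbd_from_d(d)
        if ss <= 0:
            continue  # permuted table degenerate: contributes no exceedance
        exceed += (diag / ss) >= observed - 1e-12
    return (exceed + 1.0) / (n_perm + 1.0)


@dataclass(frozen=True)
class BetaDivResult:
    ss_total: float
    bd_total: float
    lcbd: np.ndarray
    p_values: np.ndarray | None
    n_perm: int
    obs_ids: pd.Index

    def to_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        out = pd.DataFrame({"LCBD": self.lcbd}, index=self.obs_ids.rename("obs_id"))
        if self.p_values is not None:
            out["p_value"] = self.p_values
            out[f"significant_at_{alpha:g}"] = self.p_values <= alpha
        return out


class BetaDiversity(BaseEstimator):
    """Estimator computing SS_total, BD_total and LCBD for a community table.

    Parameters
    ----------
    n_perm : int
        Number of column permutations for LCBD p-values; 0 skips the test.
    seed : int
        Seed for the permutation stream.

    Attributes (after :meth:`fit`)
    ------------------------------
    ss_total_ : float
    bd_total_ : float
    lcbd_ : ndarray of shape (n_obs,)
    p_values_ : ndarray or None
    """

    def __init__(self, n_perm: int = 999, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, table: CommunityTable) -> "BetaDiversity":
        d = decompose_matrix(table).d_total
        diag, ss = _lcbd_from_d(d)
        if ss <= 0:
            raise DegenerateTableError("all observations identical: SS_total = 0")
        # diag sums to SS computed from the lower triangle — checked every call
        assert abs(ss - total_ss(d)) <= 1e-8 * max(ss, 1.0)
        self.ss_total_ = ss
        self.bd_total_ = bd_total(ss, d.shape[0])
        self.lcbd_ = diag / ss
        self.p_values_ = (
            lcbd_significance(table, self.n_perm, self.seed) if self.n_perm else None
        )
        self.obs_ids_ = table.obs_ids
        return self

    def result_(self) -> BetaDivResult:
        return BetaDivResult(
            self.ss_total_, self.bd_total_, self.lcbd_, self.p_values_,
            self.n_perm, self.obs_ids_,
        )
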