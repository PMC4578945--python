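"""Dufrêne–Legendre indicator values for the pre-shift / post-shift groups,
permutation inference, sequential Bonferroni (Holm) correction, and joint
selection of shift-driving species.

A species' indicator value for a group is the product of its specificity
(share of its mean abundance concentrated in the group) and its fidelity
(fraction of the group's observations where it occurs); the species-level
IndVal is the maximum over groups, in [0, 1].  Significance comes from
permuting group labels over observations.  Species driving a compositional
shift are those that are significant indicators after Holm correction, are
not vanishingly rare, and carry large RDA scores against the temporal
clusters; the score's sign separates increasers from decreasers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IndValResult",
    "IndicatorSpecies",
    "indval",
    "indval_test",
    "holm_adjust",
    "select_shift_species",
]


def _indval_matrix(X: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Per-(species, group) A·B values. X is observations × species."""
    n, s = X.shape
    counts = np.bincount(codes, minlength=k).astype(float)
    sums = np.zeros((k, s))
    np.add.at(sums, codes, X)
    means = sums / counts[:, None]                      # group mean abundance
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    occ = np.zeros((k, s))
    np.add.at(occ, codes, (X > 0).astype(float))
    B = occ / counts[:, None]                           # occurrence fraction
    return A * B


@dataclass(frozen=True)
class IndValResult:
    species: pd.Index
    indval: np.ndarray        # max over groups of A·B, in [0, 1]
    best_group: np.ndarray    # group level achieving the max
    A: np.ndarray             # specificity at the best group
    B: np.ndarray             # fidelity at the best group
    frequency: np.ndarray     # occurrence fraction over all observations
    p_raw: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "indval": self.indval,
                "best_group": self.best_group,
                "A": self.A,
                "B": self.B,
                "frequency": self.frequency,
            },
            index=self.species.rename("species"),
        )
        if self.p_raw is not None:
            out["p_raw"] = self.p_raw
        if self.p_adjusted is not None:
            out["p_holm"] = self.p_adjusted
        return out


class IndicatorSpecies(BaseEstimator):
    """Indicator-value estimator over a fixed grouping.

    ``fit(X, labels)`` computes per-species IndVal and, when ``n_perm > 0``,
    label-permutation p-values with Holm adjustment.  ``X`` may be a
    DataFrame (species named by columns) or array.
    """

    def __init__(self, n_perm: int = 999, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, labels) -> "IndicatorSpecies":
        if isinstance(X, pd.DataFrame):
            species = X.columns
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            species = pd.Index([f"sp{j}" for j in range(mat.shape[1])])
        labels = np.asarray(labels)
        levels, codes = np.unique(labels, return_inverse=True)
        k = len(levels)
        if k < 2:
            raise ValueError("need at least 2 groups")
        if np.bincount(codes, minlength=k).min() == 0:
            raise ValueError("every group must be non-empty")
        iv = _indval_matrix(mat, codes, k)
        best = iv.argmax(axis=0)
        observed = iv[best, np.arange(mat.shape[1])]
        p = None
        if self.n_perm:
            rng = np.random.default_rng(self.seed)
            exceed = np.zeros(mat.shape[1])
            n = mat.shape[0]
            for _ in range(self.n_perm):
                perm_iv = _indval_matrix(mat, codes[rng.permutation(n)], k)
                exceed += perm_iv.max(axis=0) >= observed - 1e-12
            p = (exceed + 1.0) / (self.n_perm + 1.0)
        counts = np.bincount(codes, minlength=k).astype(float)
        sums = np.zeros((k, mat.shape[1]))
        np.add.at(sums, codes, mat)
        means = sums / counts[:, None]
        denom = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            A_best = np.where(
                denom > 0, means[best, np.arange(mat.shape[1])] / np.where(denom > 0, denom, 1.0), 0.0
            )
        occ = np.zeros((k, mat.shape[1]))
        np.add.at(occ, codes, (mat > 0).astype(float))
        B_best = (occ / counts[:, None])[best, np.arange(mat.shape[1])]
        self.result_ = IndValResult(
            species=species,
            indval=observed,
            best_group=levels[best],
            A=A_best,
            B=B_best,
            frequency=(mat > 0).mean(axis=0),
            p_raw=p,
            p_adjusted=holm_adjust(p) if p is not None else None,
        )
        self.indval_ = observed
        self.p_values_ = p
        return self


def indval(X, labels) -> IndValResult:
    """Per-species indicator values (no permutation test)."""
    return IndicatorSpecies(n_perm=0).fit(X, labels).result_


def indval_test(X, labels, n_perm: int = 999, seed: int = 0) -> IndValResult:
    """Indicator values with label-permutation p-values and Holm adjustment."""
    return IndicatorSpecies(n_perm=n_perm, seed=seed).fit(X, labels).result_


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down ('sequential Bonferroni') adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def select_shift_species(
    indval_result: IndValResult,
    rda_scores: np.ndarray,
    rda_share: np.ndarray | None = None,
    alpha: float = 0.05,
    frequency_floor: float = 0.001,
) -> pd.DataFrame:
    """Ranked table of species jointly flagged by IndVal and RDA scores.

    Keeps species with Holm-adjusted p ≤ ``alpha`` and overall occurrence
    frequency ≥ ``frequency_floor``; ranks them by |RDA score| descending.
    ``direction`` is "increase" for a positive score (higher biomass in the
    post-shift group), "decrease" otherwise.  ``r2_share`` is each species'
    share of the shift R² when provided.  An empty selection yields an
    empty table.
    """
    if indval_result.p_adjusted is None:
        raise ValueError("indval_result carries no adjusted p-values; run indval_test")
    scores = np.asarray(rda_scores, dtype=float)
    if scores.shape[0] != len(indval_result.species):
        raise ValueError("RDA scores must cover the same species set")
    keep = (indval_result.p_adjusted <= alpha) & (
        indval_result.frequency >= frequency_floor
    )
    out = pd.DataFrame(
        {
            "species": np.asarray(indval_result.species)[keep],
            "indval": indval_result.indval[keep],
            "best_group": indval_result.best_group[keep],
            "p_raw": indval_result.p_raw[keep],
            "p_holm": indval_result.p_adjusted[keep],
            "rda_score": scores[keep],
            "direction": np.where(scores[keep] > 0, "increase", "decrease"),
            "frequency": indval_result.frequency[keep],
        }
    )
    if rda_share is not None:
        out["r2_share"] = np.asarray(rda_share, dtype=float)[keep]
    return out.reindex(
        out["rda_score"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
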