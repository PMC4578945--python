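"""Percentage-difference (Bray–Curtis) dissimilarity and its additive
decomposition into replacement and abundance-difference components.

For two observations with quantity vectors *y1*, *y2* define, summing over
species,

    A = Σ min(y1j, y2j)        shared quantity
    B = Σ (y1j − min)          surplus of observation 1
    C = Σ (y2j − min)          surplus of observation 2

The percentage difference is d = (B + C) / (2A + B + C) and splits exactly
into a replacement part, 2·min(B, C) / (2A + B + C) — reciprocal quantity
exchange among species — and an abundance-difference part,
|B − C| / (2A + B + C) — net change in total quantity.  d is not Euclidean,
but the matrix of √d is, which licenses principal-coordinates embedding and
the variance-style (SS / BD / LCBD) machinery built on it.

Convention for empty observations: a pair of all-zero vectors has d = 0
(identical); a pair with exactly one all-zero vector has d = 1, entirely
abundance difference (repl = 0, diff = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .community import CommunityTable

__all__ = [
    "ABCComponents",
    "DecomposedDissimilarity",
    "PCoAResult",
    "abc",
    "percentage_difference",
    "decompose_pair",
    "decompose_matrix",
    "sqrt_embed",
    "gower_center",
    "pcoa",
]


@dataclass(frozen=True)
class ABCComponents:
    A: float
    B: float
    C: float


@dataclass(frozen=True)
class DecomposedDissimilarity:
    """Paired square matrices with D_total = D_repl + D_diff elementwise."""

    d_total: np.ndarray
    d_repl: np.ndarray
    d_diff: np.ndarray
    obs_ids: pd.Index

    @property
    def n_obs(self) -> int:
        return self.d_total.shape[0]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        ids = self.obs_ids
        return {
            name: pd.DataFrame(getattr(self, attr), index=ids, columns=ids)
            for name, attr in (
                ("d_total", "d_total"),
                ("d_repl", "d_repl"),
                ("d_diff", "d_diff"),
            )
        }

    def to_long(self) -> pd.DataFrame:
        """Long-format pair table `obs_i, obs_j, d_total, d_repl, d_diff` (i < j)."""
        i, j = np.triu_indices(self.n_obs, k=1)
        return pd.DataFrame(
            {
                "obs_i": self.obs_ids[i],
                "obs_j": self.obs_ids[j],
                "d_total": self.d_total[i, j],
                "d_repl": self.d_repl[i, j],
                "d_diff": self.d_diff[i, j],
            }
        )


def _check_pair(y1, y2):
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {y1.shape} vs {y2.shape}")
    if (y1 < 0).any() or (y2 < 0).any():
        raise ValueError("quantities must be non-negative")
    return y1, y2


def abc(y1, y2) -> ABCComponents:
    """Shared quantity A and per-observation surpluses B, C for one pair."""
    y1, y2 = _check_pair(y1, y2)
    mn = np.minimum(y1, y2)
    return ABCComponents(A=float(mn.sum()), B=float((y1 - mn).sum()), C=float((y2 - mn).sum()))


def percentage_difference(y1, y2) -> float:
    """d = (B+C)/(2A+B+C); equivalently Σ|y1−y2| / Σ(y1+y2).  0 for a
    both-empty pair by convention."""
    comp = abc(y1, y2)
    denom = 2 * comp.A + comp.B + comp.C
    if denom == 0:
        return 0.0
    return (comp.B + comp.C) / denom


def decompose_pair(y1, y2) -> tuple[float, float]:
    """(replacement, abundance-difference) parts; they sum to d exactly."""
    comp = abc(y1, y2)
    denom = 2 * comp.A + comp.B + comp.C
    if denom == 0:
        return (0.0, 0.0)
    return (2 * min(comp.B, comp.C) / denom, abs(comp.B - comp.C) / denom)


def decompose_matrix(table: CommunityTable) -> DecomposedDissimilarity:
    """All-pairs decomposition of a community table.

    Uses the closed forms  B + C = Σ|y1 − y2| (city-block distance),
    |B − C| = |T1 − T2| (difference of row totals) and
    2A + B + C = T1 + T2, so the whole decomposition reduces to one
    city-block distance matrix plus row totals.
    """
    X = table.matrix()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    bc = squareform(pdist(X, metric="cityblock"))  # B + C
    totals = X.sum(axis=1)
    denom = totals[:, None] + totals[None, :]  # 2A + B + C
    dt = np.abs(totals[:, None] - totals[None, :])  # |B − C|
    with np.errstate(invalid="ignore", divide="ignore"):
        d_total = np.where(denom > 0, bc / np.where(denom > 0, denom, 1.0), 0.0)
        d_diff = np.where(denom > 0, dt / np.where(denom > 0, denom, 1.0), 0.0)
    d_repl = d_total - d_diff  # = 2·min(B,C)/denom
    np.fill_diagonal(d_total, 0.0)
    np.fill_diagonal(d_repl, 0.0)
    np.fill_diagonal(d_diff, 0.0)
    d_repl[d_repl < 0] = 0.0  # clip roundoff
    return DecomposedDissimilarity(d_total, d_repl, d_diff, table.obs_ids)


def sqrt_embed(d_total: np.ndarray) -> np.ndarray:
    """Elementwise square root of the percentage-difference matrix.

    The result is Euclidean-embeddable (its Gower-centered form is positive
    semi-definite up to numerical tolerance), unlike the raw matrix.
    """
    return np.sqrt(np.asarray(d_total, dtype=float))


def gower_center(a: np.ndarray) -> np.ndarray:
    """Double-center a square matrix: G = (I − 11ᵀ/n) A (I − 11ᵀ/n)."""
    a = np.asarray(a, dtype=float)
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


@dataclass(frozen=True)
class PCoAResult:
    """Principal coordinates: axes for positive eigenvalues, sorted descending."""

    coordinates: np.ndarray  # n_obs × n_axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    negative_eigenvalues: np.ndarray  # dropped eigenvalues (≤ tolerance)
    trace: float  # trace of the Gower-centered matrix

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pcoa(distances: np.ndarray, *, negative_tol: float = 1e-8) -> PCoAResult:
    """Principal coordinates analysis of a symmetric zero-diagonal distance
    matrix.

    Gower-centers −½·d², eigendecomposes, and returns coordinates
    V·√λ for eigenvalues λ > 0.  For a Euclidean-embeddable input, pairwise
    Euclidean distances among the coordinates reproduce the input.  Negative
    eigenvalues beyond ``negative_tol`` (relative to the largest) trigger a
    warning; the corresponding axes are dropped either way.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    g = gower_center(-0.5 * d**2)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0) if eigval.size else 1.0
    pos = eigval > scale * 1e-12
    if eigval.size and eigval[-1] < -negative_tol * scale:
        warnings.warn(
            f"dropping {int((~pos).sum())} non-positive PCoA axes "
            f"(most negative eigenvalue {eigval[-1]:.3e}); the input distance "
            "matrix is not fully Euclidean-embeddable",
            stacklevel=2,
        )
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigval[pos],
        negative_eigenvalues=eigval[~pos],
        trace=float(np.trace(g)),
    )
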