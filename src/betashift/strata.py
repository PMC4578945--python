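"""Stratified beta diversity: per-group decomposition summaries and
triangle-plot coordinates.

Stratifying by site gives the *temporal* response (pairs within a site
differ in time); stratifying by time step gives the *spatial* response
(pairs within a time step differ in site).  Each pair yields a triplet

    (similarity, replacement, abundance difference) = (1 − d, repl, diff)

summing to one, so a group of pairs lives inside a ternary triangle whose
corners are compositional stability, compensatory replacement, and total-
quantity fluctuation.  Two reporting scales are emitted: mean-pairwise
(triplets; sums to 1 with similarity) and the BD/variance scale
(SS_comp/(n_g − 1); replacement + difference = total exactly, max 0.5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable
from .dissimilarity import DecomposedDissimilarity

__all__ = [
    "GroupSummary",
    "pair_triplets",
    "stratify",
    "group_summary",
    "summarize_strata",
    "triangle_coordinates",
]


def pair_triplets(
    decomp: DecomposedDissimilarity,
    pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """(similarity, repl, diff) triplet per observation pair; rows sum to 1.

    ``pairs`` holds positional index pairs; None means all i<j pairs.
    """
    if pairs is None:
        i, j = np.triu_indices(decomp.n_obs, k=1)
    else:
        if len(pairs) == 0:
            raise ValueError("empty pair set")
        i, j = np.asarray(pairs, dtype=int).T
    return np.column_stack(
        [1.0 - decomp.d_total[i, j], decomp.d_repl[i, j], decomp.d_diff[i, j]]
    )


def stratify(table: CommunityTable, by: str) -> dict[object, np.ndarray]:
    """Group observation positions by ``"site"`` or ``"time"``.

    Groups with fewer than two observations are excluded with a warning
    (no within-group pair exists).
    """
    if by not in ("site", "time"):
        raise ValueError("by must be 'site' or 'time'")
    labels = table.meta[by].to_numpy()
    groups: dict[object, np.ndarray] = {}
    for key in pd.unique(labels):
        idx = np.nonzero(labels == key)[0]
        if len(idx) < 2:
            warnings.warn(f"group {key!r} has <2 observations; excluded", stacklevel=2)
            continue
        groups[key] = idx
    return groups


@dataclass(frozen=True)
class GroupSummary:
    group_id: object
    n_obs: int
    n_pairs: int
    mean_sim: float
    mean_repl: float
    mean_diff: float
    ci_sim: float          # t-based 95% half-widths (descriptive)
    ci_repl: float
    ci_diff: float
    bd_total: float        # variance scale: SS_comp/(n_g − 1)
    bd_repl: float
    bd_diff: float
    frac_repl: float       # BD_repl / BD_total
    frac_diff: float
    degenerate: bool       # BD_total == 0: fractions undefined


def _half_width(x: np.ndarray) -> float:
    if len(x) < 2:
        return math.nan
    se = x.std(ddof=1) / math.sqrt(len(x))
    return float(stats.t.ppf(0.975, len(x) - 1) * se)


def group_summary(decomp: DecomposedDissimilarity, idx: np.ndarray, group_id=None) -> GroupSummary:
    """Within-group decomposition summary on both reporting scales."""
    idx = np.asarray(idx, dtype=int)
    n = len(idx)
    if n < 2:
        raise ValueError("group must contain at least 2 observations")
    ii, jj = np.triu_indices(n, k=1)
    gi, gj = idx[ii], idx[jj]
    tot = decomp.d_total[gi, gj]
    rep = decomp.d_repl[gi, gj]
    dif = decomp.d_diff[gi, gj]
    sim = 1.0 - tot
    bd_t = tot.sum() / n / (n - 1)
    bd_r = rep.sum() / n / (n - 1)
    bd_d = dif.sum() / n / (n - 1)
    degenerate = bd_t <= 0
    return GroupSummary(
        group_id=group_id,
        n_obs=n,
        n_pairs=len(tot),
        mean_sim=float(sim.mean()),
        mean_repl=float(rep.mean()),
        mean_diff=float(dif.mean()),
        ci_sim=_half_width(sim),
        ci_repl=_half_width(rep),
        ci_diff=_half_width(dif),
        bd_total=float(bd_t),
        bd_repl=float(bd_r),
        bd_diff=float(bd_d),
        frac_repl=math.nan if degenerate else float(bd_r / bd_t),
        frac_diff=math.nan if degenerate else float(bd_d / bd_t),
        degenerate=bool(degenerate),
    )


def summarize_strata(
    table: CommunityTable, decomp: DecomposedDissimilarity, by: str
) -> pd.DataFrame:
    """One :class:`GroupSummary` row per stratum (scope column records
    whether groups are spatial — by site — or temporal — by time step)."""
    scope = "spatial" if by == "site" else "temporal"
    rows = []
    for key, idx in stratify(table, by).items():
        s = group_summary(decomp, idx, group_id=key)
        row = s.__dict__.copy()
        row["scope"] = scope
        rows.append(row)
    out = pd.DataFrame(rows)
    return out[
        ["group_id", "scope", "n_obs", "n_pairs", "mean_sim", "mean_repl", "mean_diff",
         "ci_sim", "ci_repl", "ci_diff", "bd_total", "bd_repl", "bd_diff",
         "frac_repl", "frac_diff", "degenerate"]
    ]


def triangle_coordinates(triplets: np.ndarray) -> np.ndarray:
    """Ternary projection of (similarity, repl, diff) triplets.

    x = repl + diff/2, y = diff·√3/2; the corners (1,0,0), (0,1,0), (0,0,1)
    map to (0,0), (1,0) and (0.5, √3/2).
    """
    t = np.atleast_2d(np.asarray(triplets, dtype=float))
    x = t[:, 1] + t[:, 2] / 2.0
    y = t[:, 2] * (math.sqrt(3.0) / 2.0)
    return np.column_stack([x, y])
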