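"""Redundancy analysis (RDA) with factor predictors, the two-way crossed
space–time multivariate ANOVA by RDA, and the distance-respecting response
embedding.

RDA of a multivariate response on a single factor reduces to projecting the
(column-centered) response onto group centroids: R² is the fraction of total
sum of squares carried by the fitted values, and the pseudo-F statistic is
the ratio of fitted to residual mean squares.  Significance is assessed by
permutation.  For the balanced site × time crossed design, the total SS
partitions orthogonally into site, time, interaction and residual; main
effects are tested by permuting the residuals of the model that excludes the
tested term, and the interaction by permuting the residuals of the
main-effects model (reduced-model residual permutation).

Community-level tests run on principal coordinates of the square-rooted
percentage-difference matrix (:func:`embed_for_tests`), which respects the
dissimilarity structure; species-score RDA runs on the (transformed) species
matrix directly, where axes are species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dissimilarity import DecomposedDissimilarity, pcoa, sqrt_embed

__all__ = ["RDAResult", "RDA", "rda", "two_way_crossed_anova", "embed_for_tests"]


@dataclass(frozen=True)
class RDAResult:
    r2: float
    f: float
    df: tuple[int, int]
    p: float | None
    n_perm: int
    terms: pd.DataFrame | None = None           # per-term partition (two-way)
    species_scores: np.ndarray | None = field(default=None, repr=False)
    species_share: np.ndarray | None = field(default=None, repr=False)


def _as_matrix(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    return y


def _group_means(y: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    sums = np.zeros((k, y.shape[1]))
    np.add.at(sums, codes, y)
    counts = np.bincount(codes, minlength=k).astype(float)
    return sums / counts[:, None]


def _factor(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    return levels, codes


class RDA(BaseEstimator):
    """Single-factor redundancy analysis estimator.

    fit(Y, labels) computes centroid-fitted values, R², pseudo-F, an optional
    row-permutation p-value, and — when the response columns are species —
    signed species scores.  For a two-level factor the single canonical axis
    makes the species score proportional to the centroid difference; the
    sign convention is positive for species with the higher fitted value in
    the *second* (sorted) level, so with pre/post labels sorted pre-first,
    positive means "increased after the shift".

    Attributes after fit: ``r2_``, ``f_``, ``df_``, ``p_``,
    ``species_scores_``, ``species_share_``, ``fitted_``.
    """

    def __init__(self, n_perm: int = 0, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, Y, labels) -> "RDA":
        y = _as_matrix(Y)
        labels = np.asarray(labels)
        if len(labels) != y.shape[0]:
            raise ValueError("labels must align with response rows")
        yc = y - y.mean(axis=0)
        ss_tot = float((yc**2).sum())
        if ss_tot <= 0:
            raise ValueError("constant response: R² undefined")
        levels, codes = _factor(labels)
        k = len(levels)
        if k < 2:
            raise ValueError("factor needs at least 2 levels")
        n = y.shape[0]

        def r2_of(ymat: np.ndarray) -> float:
            yc_ = ymat - ymat.mean(axis=0)
            means = _group_means(yc_, codes, k)
            fitted = means[codes]
            return float((fitted**2).sum()) / float((yc_**2).sum())

        means = _group_means(yc, codes, k)
        fitted = means[codes]
        ss_fit = float((fitted**2).sum())
        r2 = ss_fit / ss_tot
        df1, df2 = k - 1, n - k
        ss_res = ss_tot - ss_fit
        f = (ss_fit / df1) / (ss_res / df2) if df2 > 0 and ss_res > 0 else np.inf

        p = None
        if self.n_perm:
            rng = np.random.default_rng(self.seed)
            exceed = 0
            for _ in range(self.n_perm):
                exceed += r2_of(y[rng.permutation(n)]) >= r2 - 1e-12
            p = (exceed + 1) / (self.n_perm + 1)

        scores = share = None
        if k == 2:
            # centroid difference per species, second sorted level minus first
            diff = means[1] - means[0]
            scores = diff
            ss_fit_per_col = (fitted**2).sum(axis=0)
            share = ss_fit_per_col / ss_fit if ss_fit > 0 else np.zeros(y.shape[1])

        self.levels_ = levels
        self.fitted_ = fitted + y.mean(axis=0)
        self.r2_, self.f_, self.df_, self.p_ = r2, float(f), (df1, df2), p
        self.species_scores_ = scores
        self.species_share_ = share
        return self

    def result_(self) -> RDAResult:
        return RDAResult(
            r2=self.r2_, f=self.f_, df=self.df_, p=self.p_, n_perm=self.n_perm,
            species_scores=self.species_scores_, species_share=self.species_share_,
        )


def rda(Y, labels, n_perm: int = 0, seed: int = 0) -> RDAResult:
    """Functional wrapper over :class:`RDA`."""
    return RDA(n_perm=n_perm, seed=seed).fit(Y, labels).result_()


def two_way_crossed_anova(
    Y, site, time, n_perm: int = 999, seed: int = 0
) -> RDAResult:
    """Two-way crossed multivariate ANOVA by RDA for a balanced design.

    Returns the per-term partition (site, time, site:time, residual) with
    pseudo-F statistics against the full-model residual and reduced-model
    residual-permutation p-values.
    """
    y = _as_matrix(Y)
    n = y.shape[0]
    s_levels, s_codes = _factor(site)
    t_levels, t_codes = _factor(time)
    a, b = len(s_levels), len(t_levels)
    cell_codes = s_codes * b + t_codes
    counts = np.bincount(cell_codes, minlength=a * b)
    if counts.min() == 0 or counts.min() != counts.max():
        raise ValueError(
            "unbalanced site × time design: equal replication per cell is "
            "required (aggregate to cell means first)"
        )
    r = counts[0]
    df_site, df_time = a - 1, b - 1
    df_int = df_site * df_time
    df_res = a * b * (r - 1)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (one replicate per cell)")

    def partition(ymat: np.ndarray):
        yc = ymat - ymat.mean(axis=0)
        ss_tot = float((yc**2).sum())
        fit_s = _group_means(yc, s_codes, a)[s_codes]
        fit_t = _group_means(yc, t_codes, b)[t_codes]
        fit_c = _group_means(yc, cell_codes, a * b)[cell_codes]
        ss_s = float((fit_s**2).sum())
        ss_t = float((fit_t**2).sum())
        ss_c = float((fit_c**2).sum())
        return ss_tot, ss_s, ss_t, ss_c - ss_s - ss_t, ss_tot - ss_c

    ss_tot, ss_s, ss_t, ss_i, ss_r = partition(y)
    if ss_tot <= 0:
        raise ValueError("constant response")
    ms_res = ss_r / df_res

    def f_of(ss, df):
        return (ss / df) / ms_res if ms_res > 0 else np.inf

    f_s, f_t, f_i = f_of(ss_s, df_site), f_of(ss_t, df_time), f_of(ss_i, df_int)

    rng = np.random.default_rng(seed)
    # reduced models: site tested under Y ~ time, time under Y ~ site,
    # interaction under Y ~ site + time
    yc = y - y.mean(axis=0)
    red = {
        "site": _group_means(yc, t_codes, b)[t_codes],
        "time": _group_means(yc, s_codes, a)[s_codes],
        "site:time": None,
    }
    fit_main = red["site"] + red["time"]
    red["site:time"] = fit_main
    exceed = {"site": 0, "time": 0, "site:time": 0}
    obs_f = {"site": f_s, "time": f_t, "site:time": f_i}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        for term in ("site", "time", "site:time"):
            resid = yc - red[term]
            ystar = red[term] + resid[perm]
            _, pss_s, pss_t, pss_i, pss_r = partition(ystar)
            pms = pss_r / df_res
            if term == "site":
                fstar = (pss_s / df_site) / pms if pms > 0 else np.inf
            elif term == "time":
                fstar = (pss_t / df_time) / pms if pms > 0 else np.inf
            else:
                fstar = (pss_i / df_int) / pms if pms > 0 else np.inf
            exceed[term] += fstar >= obs_f[term] - 1e-12
    p = {k: (v + 1) / (n_perm + 1) for k, v in exceed.items()} if n_perm else \
        {k: None for k in exceed}

    terms = pd.DataFrame(
        {
            "term": ["site", "time", "site:time", "residual"],
            "SS": [ss_s, ss_t, ss_i, ss_r],
            "df": [df_site, df_time, df_int, df_res],
            "F": [f_s, f_t, f_i, np.nan],
            "p": [p["site"], p["time"], p["site:time"], np.nan],
        }
    )
    return RDAResult(
        r2=(ss_s + ss_t + ss_i) / ss_tot,
        f=f_i,
        df=(df_int, df_res),
        p=p["site:time"],
        n_perm=n_perm,
        terms=terms,
    )


def embed_for_tests(decomp: DecomposedDissimilarity) -> np.ndarray:
    """PCoA coordinates of the square-rooted total-dissimilarity matrix,
    keeping every positive-eigenvalue axis, so Euclidean distances among the
    rows reproduce √d_BC."""
    return pcoa(sqrt_embed(decomp.d_total)).coordinates
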