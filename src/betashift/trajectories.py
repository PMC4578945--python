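"""Univariate temporal trajectory models for habitat cover, total biomass
and species richness.

Three model families describe a response y(t):

* linear — constant rate of change;
* quadratic — humped/curved dynamics, fitted on orthogonal polynomials of
  degree two; the vertex time of a concave fit locates the response maximum;
* logistic step — an abrupt transition between two asymptotes,

      Y(t) = Y_b + (Y_a − Y_b) / (1 + exp((T − t)/σ)),

  where Y_b and Y_a are the asymptotic levels before and after the
  inflection at time T and σ > 0 is the transition scale (years).  The curve
  passes through (Y_b + Y_a)/2 at t = T.  For a declining response with
  Y_b > 0 the percent decline is (Y_b − Y_a)/Y_b · 100.

Model selection uses AIC (computed with the Gaussian likelihood, error
variance counted as a parameter, so values are comparable across the linear
and nonlinear fits) and, for quadratic vs linear, the nested-model F test.
A stepwise multiple regression with space–time interaction terms
(time, time², site, time:site, time²:site, season) summarizes island-wide
variation in richness/biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LogisticParams",
    "TrajectoryFit",
    "orthogonal_poly",
    "logistic_curve",
    "fit_logistic",
    "fit_linear",
    "fit_quadratic",
    "select_model",
    "stepwise_regression",
    "StepwiseResult",
]


def orthogonal_poly(t, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial design columns (no constant column).

    Columns are centered (orthogonal to the constant), mutually orthogonal
    and unit-normalized, as produced by a QR decomposition of the Vandermonde
    matrix of the centered time values.
    """
    t = np.asarray(t, dtype=float)
    if degree < 1:
        raise ValueError("degree must be ≥ 1")
    if len(np.unique(t)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct time values, got {len(np.unique(t))}"
        )
    tc = t - t.mean()
    v = np.vander(tc, degree + 1, increasing=True)
    q, r = np.linalg.qr(v)
    # fix signs so the linear column increases with time
    q = q * np.sign(np.diag(r))
    return q[:, 1:]


def logistic_curve(t, y_b, y_a, T, sigma):
    """Two-asymptote logistic step in time."""
    t = np.asarray(t, dtype=float)
    z = np.clip((T - t) / sigma, -700.0, 700.0)  # avoid exp overflow
    return y_b + (y_a - y_b) / (1.0 + np.exp(z))


@dataclass(frozen=True)
class LogisticParams:
    y_b: float   # asymptote before the inflection (response units)
    y_a: float   # asymptote after
    T: float     # inflection time (years)
    sigma: float  # transition scale (years, > 0)

    @property
    def decline_pct(self) -> float | None:
        if self.y_b > 0:
            return (self.y_b - self.y_a) / self.y_b * 100.0
        return None


@dataclass(frozen=True)
class TrajectoryFit:
    kind: str                       # {"linear", "quadratic", "logistic"}
    params: dict = field(repr=False)
    r2: float = math.nan
    aic: float = math.nan
    converged: bool = True
    n_obs: int = 0
    decline_pct: float | None = None   # logistic only, Y_b > 0
    vertex_time: float | None = None   # concave quadratic only
    message: str = ""

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind == "logistic":
            return logistic_curve(t, p["y_b"], p["y_a"], p["T"], p["sigma"])
        coeffs = p["raw_coefficients"]  # ascending powers of t
        return sum(c * t**k for k, c in enumerate(coeffs))


def _gaussian_aic(resid: np.ndarray, n_mean_params: int) -> float:
    n = len(resid)
    ss = float(resid @ resid)
    if ss <= 0:
        return -math.inf
    k = n_mean_params + 1  # + error variance
    return n * math.log(2 * math.pi * ss / n) + n + 2 * k


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(((y - fitted) ** 2).sum()) / ss_tot


def fit_linear(t, y) -> TrajectoryFit:
    """Ordinary least squares y ~ t."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time values")
    coeffs = np.polynomial.polynomial.polyfit(t, y, 1)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    return TrajectoryFit(
        kind="linear",
        params={"raw_coefficients": list(coeffs), "slope": float(coeffs[1])},
        r2=_r2(y, fitted),
        aic=_gaussian_aic(y - fitted, 2),
        n_obs=len(y),
    )


def fit_quadratic(t, y) -> TrajectoryFit:
    """OLS on an orthogonal degree-2 design; reports the vertex time when
    the fitted parabola is concave."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct time values")
    design = np.column_stack([np.ones_like(t), orthogonal_poly(t, 2)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    # raw-scale coefficients (identical fitted values) for vertex/predict
    coeffs = np.polynomial.polynomial.polyfit(t, y, 2)
    vertex = float(-coeffs[1] / (2 * coeffs[2])) if coeffs[2] < 0 else None
    return TrajectoryFit(
        kind="quadratic",
        params={
            "raw_coefficients": list(coeffs),
            "orthogonal_coefficients": list(beta),
        },
        r2=_r2(y, fitted),
        aic=_gaussian_aic(y - fitted, 3),
        n_obs=len(y),
        vertex_time=vertex,
    )


def fit_logistic(t, y, start_strategy: str = "asymptotes") -> TrajectoryFit:
    """Nonlinear least squares for the two-asymptote logistic step.

    Start values ("asymptotes" strategy): Y_b from the mean of the first
    three time points, Y_a from the last three, T at the median time and
    σ = range/10, with σ bounded in (1e−3, range].  Non-convergence returns
    ``converged=False`` with the solver message instead of raising.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    times = np.unique(t)
    if len(times) < 5:
        raise ValueError("need at least 5 distinct time values spanning the inflection")
    if start_strategy != "asymptotes":
        raise ValueError(f"unknown start strategy {start_strategy!r}")
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    early = ys[np.isin(ts, times[:3])]
    late = ys[np.isin(ts, times[-3:])]
    t_range = float(times[-1] - times[0])
    p0 = [float(early.mean()), float(late.mean()), float(np.median(times)), t_range / 10.0]
    lo = [-np.inf, -np.inf, times[0] - t_range, 1e-3]
    hi = [np.inf, np.inf, times[-1] + t_range, t_range]
    try:
        popt, _ = optimize.curve_fit(
            logistic_curve, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as exc:
        return TrajectoryFit(
            kind="logistic", params={"start": p0}, converged=False,
            n_obs=len(y), message=str(exc),
        )
    params = LogisticParams(*map(float, popt))
    fitted = logistic_curve(t, *popt)
    return TrajectoryFit(
        kind="logistic",
        params={"y_b": params.y_b, "y_a": params.y_a, "T": params.T, "sigma": params.sigma},
        r2=_r2(y, fitted),
        aic=_gaussian_aic(y - fitted, 4),
        n_obs=len(y),
        decline_pct=params.decline_pct,
    )


def select_model(fits: list[TrajectoryFit]) -> TrajectoryFit:
    """Lowest-AIC fit among converged candidates.

    When both a linear and a quadratic candidate are present, the nested
    quadratic-vs-linear F test is recorded on the winner
    (``params["quadratic_vs_linear"]``).
    """
    if not fits:
        raise ValueError("no candidate fits")
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("all candidate fits failed to converge")
    best = min(ok, key=lambda f: f.aic)
    by_kind = {f.kind: f for f in ok}
    if "linear" in by_kind and "quadratic" in by_kind and len(fits) > 1:
        lin, quad = by_kind["linear"], by_kind["quadratic"]
        n = lin.n_obs
        ss_lin = (1 - lin.r2)
        ss_quad = (1 - quad.r2)
        df_res = n - 3
        if df_res > 0 and ss_quad > 0:
            f_stat = (ss_lin - ss_quad) / 1 / (ss_quad / df_res)
            p = float(stats.f.sf(f_stat, 1, df_res))
        else:
            f_stat, p = math.inf, 0.0
        best = TrajectoryFit(
            kind=best.kind,
            params={**best.params, "quadratic_vs_linear": {"F": float(f_stat), "p": p, "df": (1, df_res)}},
            r2=best.r2, aic=best.aic, converged=best.converged, n_obs=best.n_obs,
            decline_pct=best.decline_pct, vertex_time=best.vertex_time,
        )
    return best


# --------------------------------------------------------------------------
# stepwise multiple regression with marginality
# --------------------------------------------------------------------------

CANONICAL_ORDER = ["time", "time2", "site", "time:site", "time2:site", "season"]


@dataclass
class StepwiseResult:
    retained: list
    anova: pd.DataFrame  # sequential (type-I) SS table for retained terms
    r2: float
    aic: float
    df_model: int
    df_resid: int
    f_full: float
    p_full: float


def _term_designs(time, site, season) -> tuple[dict, dict]:
    """Per-term design blocks and marginality dependencies."""
    time = np.asarray(time, dtype=float)
    poly = orthogonal_poly(time, 2)
    site = pd.Series(np.asarray(site))
    site_d = pd.get_dummies(site, drop_first=True).to_numpy(dtype=float)
    terms = {
        "time": poly[:, :1],
        "time2": poly[:, 1:2],
        "site": site_d,
        "time:site": poly[:, :1] * site_d if site_d.shape[1] else None,
        "time2:site": poly[:, 1:2] * site_d if site_d.shape[1] else None,
    }
    deps = {
        "time": set(),
        "time2": {"time"},
        "site": set(),
        "time:site": {"time", "site"},
        "time2:site": {"time2", "site", "time:site"},
    }
    if season is not None:
        sd = pd.get_dummies(pd.Series(np.asarray(season)), drop_first=True).to_numpy(dtype=float)
        if sd.shape[1]:
            terms["season"] = sd
            deps["season"] = set()
    return {k: v for k, v in terms.items() if v is not None and v.shape[1] > 0}, deps


def _fit_terms(y, terms, active):
    x = np.column_stack([np.ones(len(y))] + [terms[t] for t in active]) if active \
        else np.ones((len(y), 1))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"rank-deficient design with terms {active}: aliased columns")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    return fitted, resid, x.shape[1]


def stepwise_regression(response, time, site, season=None) -> StepwiseResult:
    """Bidirectional AIC-stepwise multiple regression of a univariate
    response on time, time², site, their interactions, and season.

    Marginality is respected: an interaction may only enter when its main
    effects are present, and a main effect may only leave after every
    interaction containing it has left.  The returned table reports
    sequential (type-I) sums of squares for the retained terms in the
    canonical order time, time², site, time:site, time²:site, season, with
    per-term partial R², F against the full-model residual, and p.
    """
    y = np.asarray(response, dtype=float)
    terms, deps = _term_designs(time, site, season)
    active = [t for t in CANONICAL_ORDER if t in terms]

    def aic_of(subset):
        _, resid, ncol = _fit_terms(y, terms, subset)
        return _gaussian_aic(resid, ncol)

    current = list(active)
    current_aic = aic_of(current)
    while True:
        moves = []
        for t in current:  # drops honoring marginality
            if any(t in deps[o] for o in current if o != t):
                continue
            cand = [c for c in current if c != t]
            moves.append((aic_of(cand), cand))
        for t in active:  # additions honoring marginality
            if t in current or not deps[t] <= set(current):
                continue
            cand = [c for c in CANONICAL_ORDER if c in current + [t]]
            moves.append((aic_of(cand), cand))
        if not moves:
            break
        best_aic, best_set = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-9:
            current, current_aic = best_set, best_aic
        else:
            break

    retained = [t for t in CANONICAL_ORDER if t in current]
    fitted, resid, ncol = _fit_terms(y, terms, retained)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    df_model = ncol - 1
    df_resid = len(y) - ncol
    ms_res = ss_res / df_resid if df_resid > 0 else math.nan
    rows = []
    prev_ss_fit = 0.0
    sofar: list[str] = []
    for t in retained:  # sequential decomposition in canonical order
        sofar.append(t)
        f_seq, _, _ = _fit_terms(y, terms, sofar)
        ss_fit = float(((f_seq - y.mean()) ** 2).sum())
        ss_term = ss_fit - prev_ss_fit
        prev_ss_fit = ss_fit
        df_t = terms[t].shape[1]
        f_stat = (ss_term / df_t) / ms_res if ms_res > 0 else math.inf
        rows.append(
            {
                "term": t,
                "r2": ss_term / ss_tot if ss_tot > 0 else math.nan,
                "df": df_t,
                "F": f_stat,
                "p": float(stats.f.sf(f_stat, df_t, df_resid)) if ms_res > 0 else 0.0,
            }
        )
    r2_full = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    f_full = (
        ((ss_tot - ss_res) / df_model) / ms_res if df_model > 0 and ms_res > 0 else math.nan
    )
    p_full = (
        float(stats.f.sf(f_full, df_model, df_resid)) if df_model > 0 and ms_res > 0 else math.nan
    )
    return StepwiseResult(
        retained=retained,
        anova=pd.DataFrame(rows),
        r2=r2_full,
        aic=current_aic,
        df_model=df_model,
        df_resid=df_resid,
        f_full=f_full,
        p_full=p_full,
    )
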