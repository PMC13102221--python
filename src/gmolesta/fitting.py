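"""Trap-data standardization and constrained nonlinear least squares.

Pheromone-trap catch series from many site-years are standardized onto a
common (thermal time, cumulative proportion) scale — cumulative catch
divided by the site-year total, observation dates replaced by cumulative
degree-days — and pooled into one global fit of the four-peak occurrence
curve.  Series with fewer than three non-zero reads are discarded first:
one or two isolated catches are as likely to be recording mistakes as
flight activity.

The 11 free parameters (alpha1..3, beta1, dbeta1..3, gamma1..4; alpha4 is
completed from the unit-sum constraint) are estimated by least squares on an
unconstrained internal scale: a multinomial-logit transform keeps the mixing
proportions on the simplex and log transforms keep the thermal-time and
steepness parameters in their admissible half-lines, so the optimizer never
sees a constraint boundary.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .degree_days import CddSeries
from .errors import (
    ConstraintViolationError,
    DegenerateDataWarning,
    InvalidInputError,
)
from .occurrence import OccurrenceParams, evaluate, _FREE_NAMES

__all__ = [
    "TrapSeries",
    "StandardizedSeries",
    "FitResult",
    "filter_datasets",
    "standardize",
    "pool_points",
    "auto_init",
    "fit_model",
    "FREE_PARAM_NAMES",
]

FREE_PARAM_NAMES: Tuple[str, ...] = _FREE_NAMES
N_FREE = 11


@dataclass(frozen=True)
class TrapSeries:
    """One site-year of pheromone-trap adult counts at ~15-day reads."""

    site_id: str
    dates: Tuple[dt.date, ...]
    counts: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.counts):
            raise InvalidInputError("dates and counts must be equally long")
        if len(self.dates) == 0:
            raise InvalidInputError("empty trap series")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise InvalidInputError("observation dates must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise InvalidInputError("counts must be non-negative")
        years = {d.year for d in self.dates}
        if len(years) > 1:
            raise InvalidInputError("a trap series must lie within one season (one year)")

    @property
    def year(self) -> int:
        return self.dates[0].year

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def n_nonzero(self) -> int:
        return int(sum(1 for c in self.counts if c > 0))


@dataclass(frozen=True)
class StandardizedSeries:
    """A trap series on the (CDD, cumulative proportion) scale."""

    site_id: str
    year: int
    cdd: np.ndarray
    cum_prop: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cdd) != len(self.cum_prop):
            raise InvalidInputError("cdd and cum_prop must be equally long")
        if np.any(np.diff(self.cum_prop) < -1e-12):
            raise InvalidInputError("cumulative proportions must be nondecreasing")


@dataclass(frozen=True)
class FitResult:
    """Outcome of the pooled nonlinear least-squares fit.

    ``df_model`` is always 11 (the free-parameter count); ``f_statistic``
    and ``r_squared`` use the corrected (mean-centred) total sum of squares.
    """

    params: OccurrenceParams
    standard_errors: dict
    sse: float
    r_squared: float
    f_statistic: float
    df_model: int
    df_error: int
    n_points: int
    converged: bool
    n_iterations: int
    message: str = ""
    pinned: Tuple[str, ...] = ()


def filter_datasets(
    series: Iterable[TrapSeries], min_nonzero: int = 3
) -> Tuple[List[TrapSeries], List[Tuple[TrapSeries, str]]]:
    """Split series into (kept, rejected-with-reason) by the non-zero-read rule."""
    kept: List[TrapSeries] = []
    rejected: List[Tuple[TrapSeries, str]] = []
    for s in series:
        if s.n_nonzero >= min_nonzero:
            kept.append(s)
        else:
            rejected.append(
                (s, f"only {s.n_nonzero} non-zero reads (need >= {min_nonzero})")
            )
    return kept, rejected


def standardize(series: TrapSeries, cdd: CddSeries) -> StandardizedSeries:
    """Cumulative catch proportion against cumulative degree-days.

    Leading zero reads are retained: they pin the curve's left tail at zero.
    """
    total = series.total
    if total == 0:
        raise InvalidInputError(f"series {series.site_id}/{series.year} has zero total catch")
    x = np.array([cdd.cdd_at(d) for d in series.dates], dtype=float)
    y = np.cumsum(series.counts) / float(total)
    return StandardizedSeries(site_id=series.site_id, year=series.year, cdd=x, cum_prop=y)


def pool_points(
    standardized: Iterable[StandardizedSeries],
) -> Tuple[np.ndarray, np.ndarray]:
    """Pool all site-year points, equally weighted, sorted by thermal time."""
    xs, ys = [], []
    for s in standardized:
        xs.append(s.cdd)
        ys.append(s.cum_prop)
    if not xs:
        raise InvalidInputError("no standardized series to pool")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = np.argsort(x, kind="stable")
    return x[order], y[order]


# --- unconstrained reparameterization ---------------------------------------

def _params_to_u(p: OccurrenceParams) -> np.ndarray:
    a = np.clip(np.asarray(p.alpha, dtype=float), 1e-9, None)
    a = a / a.sum()
    u = np.empty(N_FREE)
    u[0:3] = np.log(a[:3] / a[3])  # multinomial logit, alpha4 as reference
    u[3] = np.log(p.beta1)
    u[4:7] = np.log(p.dbeta)
    u[7] = np.log(-p.gamma[0])
    u[8:11] = np.log(p.gamma[1:])
    return u


def _u_to_params(u: np.ndarray, parameterization: str) -> OccurrenceParams:
    e = np.exp(np.clip(u[0:3], -60, 60))
    denom = 1.0 + e.sum()
    alpha = (e[0] / denom, e[1] / denom, e[2] / denom, 1.0 / denom)
    return OccurrenceParams(
        alpha=alpha,
        beta1=float(np.exp(u[3])),
        dbeta=tuple(np.exp(u[4:7])),
        gamma=(-float(np.exp(u[7])), *np.exp(u[8:11])),
        parameterization=parameterization,
    )


def auto_init(
    points: Union[Tuple[np.ndarray, np.ndarray], Iterable[StandardizedSeries]],
    parameterization: str = "rate",
) -> OccurrenceParams:
    """Initial estimates from the shape of the pooled empirical curve.

    Peak medians are read off the aggregated cumulative curve at the four
    mass octiles 12.5/37.5/62.5/87.5% (the middle of each quarter of the
    season's catch); mixing proportions from the catch mass falling in four
    equal-width thermal-time bands; steepness starts at field-typical
    defaults.  Emits :class:`DegenerateDataWarning` when the data do not
    separate four peaks (e.g. a single flight peak).
    """
    if isinstance(points, tuple):
        x, y = points
    else:
        x, y = pool_points(points)
    if len(x) < 8:
        raise InvalidInputError(f"need >= 8 points for initialization, got {len(x)}")
    # aggregate to a low-noise monotone empirical curve: equal-count bins in
    # thermal time, mean proportion per bin, running maximum for monotonicity
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n_bins = int(np.clip(len(xs) // 8, 4, 60))
    edges_idx = np.linspace(0, len(xs), n_bins + 1).astype(int)
    bx = np.array([xs[a:b].mean() for a, b in zip(edges_idx, edges_idx[1:]) if b > a])
    by = np.array([ys[a:b].mean() for a, b in zip(edges_idx, edges_idx[1:]) if b > a])
    by = np.maximum.accumulate(by)
    lo, hi = by[0], by[-1]
    g = (by - lo) / (hi - lo) if hi > lo else by

    def quantile(level: float) -> float:
        return float(np.interp(level, g, bx))

    def curve_at(pos: np.ndarray) -> np.ndarray:
        return np.interp(pos, bx, g)

    span = bx[-1] - bx[0]
    # alternate share/median refinement: shares from the mass between peak
    # midpoints, medians from the mid-mass level of each share band
    alpha = np.full(4, 0.25)
    mus = np.array([quantile(q) for q in (0.125, 0.375, 0.625, 0.875)])
    for _ in range(3):
        cum = np.concatenate([[0.0], np.cumsum(alpha)])
        levels = (cum[:-1] + cum[1:]) / 2.0
        mus = np.array([quantile(lv) for lv in levels])
        bounds = (mus[:-1] + mus[1:]) / 2.0
        mass = np.diff(curve_at(np.concatenate([[bx[0]], bounds, [bx[-1]]])))
        mass = np.clip(mass, 1e-3, None)
        alpha = mass / mass.sum()
    dbetas = np.diff(mus)
    # four genuine peaks spread their medians across the season; medians
    # crowded into a sliver of the observed thermal-time range mean the data
    # carry fewer distinguishable peaks
    degenerate = (
        span <= 0
        or np.any(dbetas < 0.02 * max(span, 1.0))
        or (mus[-1] - mus[0]) < 0.25 * span
    )
    if degenerate:
        warnings.warn(
            "pooled data do not separate four peaks; initial spacings are degenerate",
            DegenerateDataWarning,
        )
        dbetas = np.maximum(dbetas, 0.05 * max(span, 1.0))
    gamma_rest = (0.06, 0.06, 0.06) if parameterization == "rate" else (17.0, 17.0, 17.0)
    return OccurrenceParams(
        alpha=tuple(alpha),
        beta1=max(mus[0], 1.0),
        dbeta=tuple(dbetas),
        gamma=(-8.0, *gamma_rest),
        parameterization=parameterization,
    )


def _jacobian_free(x: np.ndarray, p: OccurrenceParams) -> np.ndarray:
    """Central-difference Jacobian of the model wrt the 11 free parameters."""
    free = p.free
    J = np.empty((len(x), N_FREE))
    for j in range(N_FREE):
        h = 1e-6 * max(1.0, abs(free[j]))
        up, dn = free.copy(), free.copy()
        up[j] += h
        dn[j] -= h
        try:
            f_up = evaluate(x, OccurrenceParams.from_free(up, p.parameterization))
            f_dn = evaluate(x, OccurrenceParams.from_free(dn, p.parameterization))
        except (ConstraintViolationError, InvalidInputError):
            # one-sided step when a central step leaves the feasible region
            f_up = evaluate(x, p)
            f_dn = evaluate(x, OccurrenceParams.from_free(dn, p.parameterization))
            h = h / 2.0
        J[:, j] = (np.asarray(f_up) - np.asarray(f_dn)) / (2.0 * h)
    return J


def fit_model(
    data: Union[Tuple[np.ndarray, np.ndarray], Iterable[StandardizedSeries]],
    init: Optional[OccurrenceParams] = None,
    *,
    parameterization: str = "rate",
    ftol: float = 1e-10,
    max_nfev: int = 24000,  # ~2000 iterations at 12 evaluations each
) -> FitResult:
    """Fit the four-peak occurrence curve to pooled standardized points.

    Minimizes sum (cum_prop - f(cdd))^2 over the 11 free parameters under
    the simplex/positivity/negativity constraints (enforced by
    reparameterization).  Non-convergence and degenerate inputs are flagged
    on the result, never raised.
    """
    if isinstance(data, tuple):
        x, y = np.asarray(data[0], dtype=float), np.asarray(data[1], dtype=float)
    else:
        x, y = pool_points(data)
    n = len(x)
    if n < N_FREE + 1:
        raise InvalidInputError(f"need >= {N_FREE + 1} pooled points, got {n}")
    if init is None:
        init = auto_init((x, y), parameterization)
    if init.parameterization != parameterization:
        init = init.with_parameterization(parameterization)

    ss_total = float(np.sum((y - y.mean()) ** 2))
    df_error = n - N_FREE - 1
    if ss_total == 0.0:
        return FitResult(
            params=init, standard_errors={}, sse=float(np.sum((y - evaluate(x, init)) ** 2)),
            r_squared=0.0, f_statistic=float("nan"), df_model=N_FREE,
            df_error=df_error, n_points=n, converged=False, n_iterations=0,
            message="degenerate input: constant cumulative proportions (no signal)",
        )

    def residuals(u: np.ndarray) -> np.ndarray:
        return y - evaluate(x, _u_to_params(u, parameterization))

    res = least_squares(
        residuals,
        _params_to_u(init),
        method="trf",
        ftol=ftol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    params = _u_to_params(res.x, parameterization)
    sse = float(np.sum(res.fun ** 2))
    r_squared = float(np.clip(1.0 - sse / ss_total, 0.0, 1.0))
    ss_model = ss_total - sse
    if df_error > 0 and sse > 0:
        f_stat = (ss_model / N_FREE) / (sse / df_error)
    else:
        f_stat = float("inf")

    # asymptotic SEs from the Jacobian wrt the original free parameters
    standard_errors: dict = {}
    if df_error > 0 and sse > 0:
        J = _jacobian_free(x, params)
        mse = sse / df_error
        try:
            cov = mse * np.linalg.pinv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            standard_errors = dict(zip(FREE_PARAM_NAMES, se.tolist()))
        except np.linalg.LinAlgError:
            standard_errors = {}

    pinned = tuple(
        name
        for name, a in zip(("alpha1", "alpha2", "alpha3", "alpha4"), params.alpha)
        if a < 1e-6
    )
    return FitResult(
        params=params,
        standard_errors=standard_errors,
        sse=sse,
        r_squared=r_squared,
        f_statistic=float(f_stat),
        df_model=N_FREE,
        df_error=df_error,
        n_points=n,
        converged=bool(res.success),
        n_iterations=int(res.nfev),
        message=res.message,
        pinned=pinned,
    )
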