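"""Synthetic climate and trap-catch generation with the structure the
analysis assumes.

The temperature generator emulates a temperate East-Asian annual cycle
(cold winters, warm late-July peak) whose season accumulates roughly
1,900-2,400 degree-days above 8.1 degC — enough that the fourth flight
peak at ~1,816 DD falls in late summer.  Trap counts are tied to thermal
time through the occurrence curve: the expected catch of each 15-day read
is the curve's increment over that interval, and counts are drawn
multinomially (or Dirichlet-multinomially when overdispersed) so a season's
catches sum exactly to the site total.  Because catches follow thermal time
rather than the calendar, warmed climates advance them automatically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .degree_days import DEFAULT_THRESHOLDS, CddSeries, ThermalThresholds, accumulate_cdd
from .errors import CoverageError, InvalidInputError
from .fitting import TrapSeries
from .occurrence import OccurrenceParams, evaluate

__all__ = [
    "ClimateSpec",
    "SamplingSpec",
    "SiteData",
    "gen_temperature",
    "gen_trap_series",
    "gen_study",
]


@dataclass(frozen=True)
class ClimateSpec:
    """Annual temperature cycle: mean + seasonal sine + daily noise.

    Defaults describe a Korean apple-growing climatology: annual mean
    12 degC, seasonal amplitude 13 degC (January ~ -1 degC, warmest day
    around July 27, ~25 degC), diurnal range 9 degC, day-to-day noise SD
    1.5 degC.  ``warming_offset`` shifts both tmin and tmax uniformly and
    is the hook for scenario generation.
    """

    annual_mean: float = 12.0
    amplitude: float = 13.0
    phase: float = 208.0  # day of year of peak warmth
    diurnal_range: float = 9.0
    noise_sd: float = 1.5
    warming_offset: float = 0.0
    seed: Optional[int] = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.diurnal_range < 0 or self.noise_sd < 0:
            raise InvalidInputError("amplitude, diurnal range and noise SD must be >= 0")


@dataclass(frozen=True)
class SamplingSpec:
    """Trap observation design: 15-day reads across the apple season."""

    first: Tuple[int, int] = (3, 1)  # (month, day) of the first read
    last: Tuple[int, int] = (10, 31)
    interval: int = 15  # days between reads
    total: int = 500  # seasonal catch N per site
    overdispersion: float = 0.0  # 0 = multinomial; >0 = Dirichlet-multinomial
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise InvalidInputError("interval must be >= 1 day")
        if self.total < 0:
            raise InvalidInputError("total catch must be >= 0")
        if self.overdispersion < 0:
            raise InvalidInputError("overdispersion must be >= 0")


def gen_temperature(
    spec: ClimateSpec, year: int = 2023, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """One year of daily (tmin, tmax), Jan 1 through Dec 31.

    Daily mean = annual_mean + amplitude * sin(2*pi*(doy - phase + 91.25)/365)
    + N(0, noise_sd); tmin/tmax = mean -/+ diurnal_range/2 + warming_offset.
    The same noise draw perturbs tmin and tmax so tmin <= tmax always holds.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    mean = (
        spec.annual_mean
        + spec.amplitude * np.sin(2.0 * np.pi * (doy - spec.phase + 91.25) / 365.0)
        + rng.normal(0.0, spec.noise_sd, size=len(doy))
    )
    half = spec.diurnal_range / 2.0
    return pd.DataFrame(
        {
            "date": dates,
            "tmin": mean - half + spec.warming_offset,
            "tmax": mean + half + spec.warming_offset,
        }
    )


def _observation_dates(year: int, sampling: SamplingSpec) -> List[dt.date]:
    first = dt.date(year, *sampling.first)
    last = dt.date(year, *sampling.last)
    out, d = [], first
    while d <= last:
        out.append(d)
        d += dt.timedelta(days=sampling.interval)
    return out


def gen_trap_series(
    p: OccurrenceParams,
    cdd: CddSeries,
    sampling: SamplingSpec,
    site_id: str = "S001",
    rng: Optional[np.random.Generator] = None,
) -> TrapSeries:
    """Draw one site-year of trap counts from the occurrence curve.

    The expected catch of read k is N * [f(CDD_k) - f(CDD_{k-1})], with the
    window opening one interval before the first read; interval
    probabilities are renormalized over the window so counts sum to N
    exactly.  ``overdispersion`` rho > 0 draws the interval probabilities
    from Dirichlet(p_i / rho) first, inflating the count variance the way
    field trap data are inflated.
    """
    if rng is None:
        rng = np.random.default_rng(sampling.seed)
    obs_dates = _observation_dates(cdd.year, sampling)
    try:
        edges = [max(obs_dates[0] - dt.timedelta(days=sampling.interval), dt.date(cdd.year, 1, 1))]
        edges += obs_dates
        cdd_edges = np.array([cdd.cdd_at(d) for d in edges])
    except InvalidInputError as exc:
        raise CoverageError(str(exc)) from exc
    probs = np.diff(evaluate(cdd_edges, p))
    probs = np.clip(probs, 0.0, None)
    if probs.sum() <= 0:
        raise InvalidInputError("occurrence curve carries no mass over the sampling window")
    probs = probs / probs.sum()
    if sampling.total == 0:
        counts = np.zeros(len(obs_dates), dtype=int)
    elif sampling.overdispersion > 0:
        alpha = np.clip(probs / sampling.overdispersion, 1e-9, None)
        counts = rng.multinomial(sampling.total, rng.dirichlet(alpha))
    else:
        counts = rng.multinomial(sampling.total, probs)
    return TrapSeries(site_id=site_id, dates=tuple(obs_dates), counts=tuple(int(c) for c in counts))


@dataclass(frozen=True)
class SiteData:
    """Paired synthetic series for one site: temperatures, CDD and catches."""

    site_id: str
    climate: ClimateSpec
    temps: pd.DataFrame
    cdd: CddSeries
    trap: TrapSeries


def gen_study(
    p: OccurrenceParams,
    n_sites: int,
    climate: ClimateSpec = ClimateSpec(),
    sampling: SamplingSpec = SamplingSpec(),
    seed: int = 0,
    year: int = 2023,
    mean_jitter_sd: float = 1.0,
    amplitude_jitter_sd: float = 0.5,
    thresholds: ThermalThresholds = DEFAULT_THRESHOLDS,
) -> List[SiteData]:
    """A multi-site study: per-site climate jitter, paired temp/trap series.

    Per-site random streams are spawned deterministically from the master
    seed, so a fixed seed reproduces the study byte for byte.
    """
    if n_sites < 1:
        raise InvalidInputError("n_sites must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_sites)
    out: List[SiteData] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        site_climate = dataclasses.replace(
            climate,
            annual_mean=climate.annual_mean + rng.normal(0.0, mean_jitter_sd),
            amplitude=max(climate.amplitude + rng.normal(0.0, amplitude_jitter_sd), 0.0),
        )
        temps = gen_temperature(site_climate, year=year, rng=rng)
        cdd = accumulate_cdd(temps, thresholds)
        trap = gen_trap_series(p, cdd, sampling, site_id=f"S{i + 1:03d}", rng=rng)
        out.append(SiteData(site_id=trap.site_id, climate=site_climate, temps=temps, cdd=cdd, trap=trap))
    return out
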