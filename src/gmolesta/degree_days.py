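"""Thermal-time (degree-day) computation with the single-sine method.

The day's temperature course is approximated by one sine cycle between the
daily minimum and maximum.  Development accrues in proportion to the area of
that curve between a lower and an upper developmental threshold; the upper
threshold uses a *horizontal cutoff*, i.e. temperatures above it contribute
as if the insect sat exactly at the threshold.  Accumulation starts from a
January 1 biofix.

The integral contract is

    DD = (1/2pi) * integral_0^{2pi} max(0, min(T(th), upper) - lower) dth,
    T(th) = m + A sin(th),  m = (tmax+tmin)/2,  A = (tmax-tmin)/2,

evaluated here in closed form through the identity
``max(0, min(T,U)-L) = max(0, T-L) - max(0, T-U)`` (valid for L <= U), so a
single two-case helper covers all six threshold configurations.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError, TemperatureGapError

__all__ = [
    "DailyTemperature",
    "ThermalThresholds",
    "CddSeries",
    "DEFAULT_THRESHOLDS",
    "single_sine_dd",
    "accumulate_cdd",
    "cdd_to_julian_day",
]


class DailyTemperature(NamedTuple):
    """One day's minimum/maximum air temperature (deg C)."""

    date: dt.date
    tmin: float
    tmax: float


@dataclass(frozen=True)
class ThermalThresholds:
    """Lower/upper developmental thresholds (deg C).

    ``upper=inf`` expresses the legacy "no upper developmental threshold"
    variants, reducing the computation to the classic two-case single sine.
    Only the horizontal cutoff is implemented; the flag exists so the choice
    is explicit in reports.
    """

    lower: float
    upper: float = math.inf
    cutoff_method: str = "horizontal"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidInputError(
                f"lower threshold ({self.lower}) must be below upper ({self.upper})"
            )
        if self.cutoff_method != "horizontal":
            raise InvalidInputError(
                f"unsupported cutoff method {self.cutoff_method!r}; only 'horizontal' is implemented"
            )


#: Thresholds of this model: 8.1 degC lower, 32.2 degC upper.
DEFAULT_THRESHOLDS = ThermalThresholds(lower=8.1, upper=32.2)


def _dd_above(m: np.ndarray, a: np.ndarray, thr: float) -> np.ndarray:
    """(1/2pi) * integral of max(0, m + a*sin(th) - thr) over one cycle.

    Classic two-case single-sine form: full accumulation when the whole sine
    sits above ``thr``, partial when intercepted, zero when below.
    """
    if math.isinf(thr):
        return np.zeros_like(m)
    full = m - thr  # value when tmin >= thr
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip((thr - m) / np.where(a > 0, a, np.nan), -1.0, 1.0)
        th1 = np.arcsin(ratio)
        partial = ((m - thr) * (np.pi / 2 - th1) + a * np.cos(th1)) / np.pi
    out = np.where(
        m + a <= thr,  # tmax <= thr: never above
        0.0,
        np.where(m - a >= thr, full, partial),  # tmin >= thr: always above
    )
    # degenerate flat day (a == 0) never takes the partial branch
    return np.where(a == 0, np.maximum(full, 0.0), out)


def single_sine_dd(
    tmin: Union[float, np.ndarray],
    tmax: Union[float, np.ndarray],
    thresholds: ThermalThresholds = DEFAULT_THRESHOLDS,
) -> Union[float, np.ndarray]:
    """Degree-days for one day from (tmin, tmax), horizontal cutoff.

    Vectorises over array inputs.  Result is bounded by
    ``0 <= DD <= upper - lower``.
    """
    tn = np.asarray(tmin, dtype=float)
    tx = np.asarray(tmax, dtype=float)
    if not (np.all(np.isfinite(tn)) and np.all(np.isfinite(tx))):
        raise InvalidInputError("temperatures must be finite")
    if np.any(tn > tx):
        raise InvalidInputError("tmin must not exceed tmax")
    m = (tx + tn) / 2.0
    a = (tx - tn) / 2.0
    dd = _dd_above(m, a, thresholds.lower) - _dd_above(m, a, thresholds.upper)
    dd = np.maximum(dd, 0.0)
    if dd.ndim == 0:
        return float(dd)
    return dd


@dataclass(frozen=True)
class CddSeries:
    """Date-indexed cumulative degree-days from a January 1 biofix."""

    dates: pd.DatetimeIndex
    daily_dd: np.ndarray
    cumulative: np.ndarray = field(default=None)  # type: ignore[assignment]
    thresholds: ThermalThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.cumulative is None:
            object.__setattr__(self, "cumulative", np.cumsum(self.daily_dd))
        if len(self.dates) != len(self.daily_dd) or len(self.dates) != len(self.cumulative):
            raise InvalidInputError("dates, daily_dd and cumulative must be equally long")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def year(self) -> int:
        return int(self.dates[0].year)

    def cdd_at(self, date: Union[dt.date, str, pd.Timestamp]) -> float:
        """End-of-day cumulative degree-days on ``date``."""
        ts = pd.Timestamp(date)
        idx = self.dates.get_indexer([ts])
        if idx[0] < 0:
            raise InvalidInputError(f"date {ts.date()} not covered by this CDD series")
        return float(self.cumulative[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        """Export as the ``date,doy,daily_dd,cdd`` table."""
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "doy": self.dates.dayofyear,
                "daily_dd": self.daily_dd,
                "cdd": self.cumulative,
            }
        )


def _coerce_temperature_frame(temps) -> pd.DataFrame:
    if isinstance(temps, pd.DataFrame):
        df = temps.copy()
    else:
        df = pd.DataFrame(list(temps), columns=["date", "tmin", "tmax"])
    missing = {"date", "tmin", "tmax"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"temperature table lacks columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values("date").reset_index(drop=True)


def accumulate_cdd(
    temps: Union[pd.DataFrame, Iterable[DailyTemperature]],
    thresholds: ThermalThresholds = DEFAULT_THRESHOLDS,
    *,
    require_jan1: bool = True,
) -> CddSeries:
    """Accumulate daily single-sine degree-days over a consecutive series.

    The series must start on January 1 (the biofix) and contain every day up
    to its end; a gap raises :class:`TemperatureGapError` naming the first
    missing day rather than imputing.
    """
    df = _coerce_temperature_frame(temps)
    if df.empty:
        raise InvalidInputError("empty temperature series")
    first = df["date"].iloc[0]
    if require_jan1 and not (first.month == 1 and first.day == 1):
        raise InvalidInputError(f"series must start on January 1; starts {first.date()}")
    expected = pd.date_range(first, periods=len(df), freq="D")
    actual = pd.DatetimeIndex(df["date"])
    if not actual.equals(expected):
        mism = np.nonzero(~(actual == expected[: len(actual)]))[0]
        first_missing = expected[mism[0]] if len(mism) else expected[len(actual)]
        raise TemperatureGapError(first_missing.date())
    daily = np.asarray(
        single_sine_dd(df["tmin"].to_numpy(), df["tmax"].to_numpy(), thresholds)
    )
    return CddSeries(dates=actual, daily_dd=daily, thresholds=thresholds)


def cdd_to_julian_day(cdd: CddSeries, target: float) -> Optional[int]:
    """Day of year (Jan 1 = 1) on which cumulative degree-days first reach ``target``.

    Returns ``None`` when the series never reaches the target.  No within-day
    interpolation is attempted: trap reads and temperatures are daily, so
    sub-day precision would be spurious.
    """
    if not np.isfinite(target) or target < 0:
        raise InvalidInputError(f"target CDD must be finite and >= 0, got {target}")
    idx = int(np.searchsorted(cdd.cumulative, target, side="left"))
    if idx >= len(cdd):
        return None
    return int(cdd.dates[idx].dayofyear)
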