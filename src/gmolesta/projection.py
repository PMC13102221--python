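"""Forecast 50%-occurrence dates under arbitrary temperature scenarios.

Projection is a direct reuse of the validation machinery: the fitted peak
CDDs are mapped through the thermal-time accumulation of each scenario's
temperature series.  Because degree-days are monotone in temperature, a
pointwise-warmer scenario can never yield a later peak date; the upper
developmental threshold (32.2 degC, horizontal cutoff) means mid-summer
heat beyond it adds nothing, so peaks falling in hot periods shift less.

Multi-year scenario decades are represented by projecting each year and
averaging the projected days — never by averaging temperatures first, which
would smear the nonlinearity of the threshold crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

import pandas as pd

from .degree_days import DEFAULT_THRESHOLDS, ThermalThresholds
from .occurrence import OccurrenceParams
from .validation import predict_peak_days

__all__ = ["ScenarioSeries", "project_peaks", "shift_report", "summarize_shifts"]


@dataclass(frozen=True)
class ScenarioSeries:
    """One site-year temperature series under a named scenario."""

    scenario: str
    site_id: str
    temps: pd.DataFrame  # columns date, tmin, tmax


def project_peaks(
    p: OccurrenceParams,
    scenario: ScenarioSeries,
    thresholds: ThermalThresholds = DEFAULT_THRESHOLDS,
) -> Tuple[Optional[int], ...]:
    """Julian day of each peak's 50% occurrence under one scenario series."""
    return predict_peak_days(p, scenario.temps, thresholds)


def shift_report(
    p: OccurrenceParams,
    baseline: Union[ScenarioSeries, Iterable[ScenarioSeries]],
    scenarios: Iterable[ScenarioSeries],
    thresholds: ThermalThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-peak advancement (baseline day - scenario day) for every scenario.

    Baselines and scenario series are matched by ``site_id``.  A peak that
    is unreached in either series is reported as missing, never as zero.
    Columns: scenario, site, peak, baseline_doy, scenario_doy, advance_days.
    """
    baselines = [baseline] if isinstance(baseline, ScenarioSeries) else list(baseline)
    base_days = {
        b.site_id: project_peaks(p, b, thresholds) for b in baselines
    }
    rows: List[dict] = []
    for sc in scenarios:
        if sc.site_id not in base_days:
            raise KeyError(f"no baseline series for site {sc.site_id!r}")
        bdays = base_days[sc.site_id]
        sdays = project_peaks(p, sc, thresholds)
        for k in range(4):
            b, s = bdays[k], sdays[k]
            rows.append(
                {
                    "scenario": sc.scenario,
                    "site": sc.site_id,
                    "peak": k + 1,
                    "baseline_doy": b,
                    "scenario_doy": s,
                    "advance_days": (b - s) if (b is not None and s is not None) else None,
                }
            )
    return pd.DataFrame(rows)


def summarize_shifts(report: pd.DataFrame) -> pd.DataFrame:
    """Mean advancement per scenario and peak, averaged over sites.

    Missing cells (unreached peaks) are excluded from the mean rather than
    treated as zero.
    """
    return (
        report.dropna(subset=["advance_days"])
        .groupby(["scenario", "peak"], sort=False)["advance_days"]
        .mean()
        .unstack("peak")
    )
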