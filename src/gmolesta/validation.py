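"""Peak segmentation of trap series and model-vs-observation comparison.

A season's trap-count sequence is cut into flight peaks: a peak is a maximal
run of non-decreasing counts followed by a maximal run of non-increasing
counts, and it ends at the local minimum terminating the decrease.  Ties
(equal consecutive counts) continue the current phase — 15-day sampling
makes strict monotonicity too brittle.  For each peak the observed
50%-occurrence point is located by linear interpolation between the two
observations bracketing the half-catch level, on either the Julian-day or
the thermal-time axis.  Observed timings are then compared against the
predictions of this model and of two earlier degree-day threshold sets, and
the absolute deviations summarized and tested (one-way ANOVA + Tukey HSD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .degree_days import (
    ThermalThresholds,
    accumulate_cdd,
    cdd_to_julian_day,
)
from .errors import InvalidInputError
from .fitting import TrapSeries
from .occurrence import OccurrenceParams, peak_cdd

__all__ = [
    "PeakSegment",
    "Segmentation",
    "LegacyModel",
    "KIM_MODEL",
    "DAMAS_MODEL",
    "DeviationRecord",
    "segment_peaks",
    "observed_50pct",
    "Observed50",
    "predict_peak_days",
    "deviation_summary",
    "deviation_anova",
    "AnovaResult",
]


@dataclass(frozen=True)
class PeakSegment:
    """A contiguous slice of a trap series attributed to one flight peak."""

    peak_index: int
    start: int  # index into the (trimmed) series, inclusive
    stop: int  # inclusive
    counts: Tuple[int, ...]

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def within_cum(self) -> np.ndarray:
        """Cumulative catch proportion within this segment (ends at 1)."""
        if self.total == 0:
            raise InvalidInputError("segment has zero total catch")
        return np.cumsum(self.counts) / float(self.total)


@dataclass(frozen=True)
class Segmentation:
    segments: Tuple[PeakSegment, ...]
    shortfall: bool  # fewer than four peaks were detectable
    n_candidates: int  # before any merging
    offset: int  # index of the first kept observation in the original series


@dataclass(frozen=True)
class LegacyModel:
    """An earlier peak-timing rule: fixed peak CDDs under its own thresholds."""

    name: str
    thresholds: ThermalThresholds
    peak_cdds: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.peak_cdds, self.peak_cdds[1:])):
            raise InvalidInputError("peak CDDs must be strictly increasing")


#: Kim et al.: lower threshold 8.1 degC, no upper threshold.
KIM_MODEL = LegacyModel(
    name="Kim et al.",
    thresholds=ThermalThresholds(lower=8.1, upper=math.inf),
    peak_cdds=(102.3, 628.3, 1369.9, 1876.0),
)

#: Damas et al. (peach): lower threshold 9.5 degC, no upper threshold.
DAMAS_MODEL = LegacyModel(
    name="Damas et al.",
    thresholds=ThermalThresholds(lower=9.5, upper=math.inf),
    peak_cdds=(77.9, 204.8, 578.4, 1438.0),
)


class DeviationRecord(NamedTuple):
    """Per-peak predicted vs observed 50%-occurrence Julian days, one model/site-year."""

    site_id: str
    year: int
    model: str
    predicted: Tuple[Optional[int], ...]
    observed: Tuple[Optional[float], ...]

    @property
    def abs_deviations(self) -> Tuple[Optional[float], ...]:
        return tuple(
            abs(p - o) if (p is not None and o is not None) else None
            for p, o in zip(self.predicted, self.observed)
        )


def segment_peaks(series_or_counts: Union[TrapSeries, Sequence[int]], max_peaks: int = 4) -> Segmentation:
    """Cut a count sequence into flight-peak segments.

    Leading and trailing zero reads are trimmed first.  If more than
    ``max_peaks`` candidates emerge, adjacent candidates are merged smallest
    total first (absorbed into the larger neighbour) until ``max_peaks``
    remain, preserving totals.  Fewer candidates set the shortfall flag.
    """
    counts = (
        list(series_or_counts.counts)
        if isinstance(series_or_counts, TrapSeries)
        else list(series_or_counts)
    )
    if not counts or all(c == 0 for c in counts):
        raise InvalidInputError("cannot segment an empty or all-zero series")
    lo = next(i for i, c in enumerate(counts) if c > 0)
    hi = max(i for i, c in enumerate(counts) if c > 0)
    trimmed = counts[lo : hi + 1]

    # phase scan: non-decreasing run, then non-increasing run, repeat
    bounds: List[Tuple[int, int]] = []
    i, n = 0, len(trimmed)
    while i < n:
        start = i
        while i + 1 < n and trimmed[i + 1] >= trimmed[i]:
            i += 1
        while i + 1 < n and trimmed[i + 1] <= trimmed[i]:
            i += 1
        bounds.append((start, i))
        i += 1
    n_candidates = len(bounds)

    merged = [[s, e, sum(trimmed[s : e + 1])] for s, e in bounds]
    while len(merged) > max_peaks:
        k = min(range(len(merged)), key=lambda j: merged[j][2])
        if k == 0:
            nb = 1
        elif k == len(merged) - 1:
            nb = k - 1
        else:
            nb = k - 1 if merged[k - 1][2] >= merged[k + 1][2] else k + 1
        a, b = sorted((k, nb))
        merged[a] = [merged[a][0], merged[b][1], merged[a][2] + merged[b][2]]
        del merged[b]

    segments = tuple(
        PeakSegment(
            peak_index=j + 1,
            start=lo + s,
            stop=lo + e,
            counts=tuple(trimmed[s : e + 1]),
        )
        for j, (s, e, _) in enumerate(merged)
    )
    return Segmentation(
        segments=segments,
        shortfall=len(segments) < max_peaks,
        n_candidates=n_candidates,
        offset=lo,
    )


class Observed50(NamedTuple):
    value: float
    edge: bool  # half-catch already reached at the segment's first observation


def observed_50pct(segment: PeakSegment, axis: Sequence[float]) -> Observed50:
    """Observed 50%-occurrence point of one peak on the given axis.

    ``axis`` holds the axis values (Julian days or CDD) of the segment's
    observations.  The within-segment cumulative proportion is interpolated
    linearly between the two observations bracketing the 0.5 level.  When
    the proportion lands on 0.5 exactly at an observation that is not the
    last, the crossing is ambiguous anywhere up to the next observation and
    the midpoint of that span is returned.
    """
    ax = np.asarray(axis, dtype=float)
    if len(ax) != len(segment.counts):
        raise InvalidInputError("axis length must match the segment's observations")
    c = segment.within_cum
    k = int(np.searchsorted(c, 0.5, side="left"))
    if c[k] == 0.5 and k + 1 < len(c):
        return Observed50(value=float((ax[k] + ax[k + 1]) / 2.0), edge=False)
    if k == 0:
        return Observed50(value=float(ax[0]), edge=True)
    frac = (0.5 - c[k - 1]) / (c[k] - c[k - 1])
    return Observed50(value=float(ax[k - 1] + frac * (ax[k] - ax[k - 1])), edge=False)


def predict_peak_days(
    model: Union[OccurrenceParams, LegacyModel],
    temps: pd.DataFrame,
    thresholds: Optional[ThermalThresholds] = None,
) -> Tuple[Optional[int], ...]:
    """Predicted Julian day of each peak's 50% occurrence for one year.

    CDD are accumulated with the model's own thresholds (this model:
    8.1/32.2 degC; the legacy sets: their lower threshold, no upper), then
    each peak CDD is mapped to the first day reaching it.  Unreached peaks
    yield ``None``.
    """
    if isinstance(model, LegacyModel):
        thr = model.thresholds
        targets = model.peak_cdds
    else:
        from .degree_days import DEFAULT_THRESHOLDS

        thr = thresholds or DEFAULT_THRESHOLDS
        targets = tuple(peak_cdd(model, k) for k in (1, 2, 3, 4))
    cdd = accumulate_cdd(temps, thr)
    return tuple(cdd_to_julian_day(cdd, t) for t in targets)


def records_to_frame(records: Iterable[DeviationRecord]) -> pd.DataFrame:
    """Long-format deviation table: site,year,model,peak,predicted_doy,observed_doy,abs_dev."""
    rows = []
    for r in records:
        for k, (p, o, d) in enumerate(zip(r.predicted, r.observed, r.abs_deviations), start=1):
            rows.append(
                {
                    "site": r.site_id,
                    "year": r.year,
                    "model": r.model,
                    "peak": k,
                    "predicted_doy": p,
                    "observed_doy": o,
                    "abs_dev": d,
                }
            )
    return pd.DataFrame(rows)


def deviation_summary(records: Iterable[DeviationRecord]) -> pd.DataFrame:
    """Per-model mean +/- SE of absolute deviations, pooled over peaks and sites.

    Returns one row per model with columns ``mean_abs_dev``, ``se`` (sample
    SD / sqrt(n)), ``n`` plus per-peak means ``peak1..peak4``.
    """
    df = records_to_frame(records).dropna(subset=["abs_dev"])
    if df.empty:
        raise InvalidInputError("no usable deviation records")
    rows = []
    for model, grp in df.groupby("model", sort=False):
        devs = grp["abs_dev"].to_numpy(dtype=float)
        se = float(np.std(devs, ddof=1) / np.sqrt(len(devs))) if len(devs) > 1 else float("nan")
        row = {
            "model": model,
            "mean_abs_dev": float(devs.mean()),
            "se": se,
            "n": len(devs),
        }
        for k in (1, 2, 3, 4):
            sub = grp.loc[grp["peak"] == k, "abs_dev"]
            row[f"peak{k}"] = float(sub.mean()) if len(sub) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    letters: Dict[str, str]  # compact letter display per group


def deviation_anova(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across models' deviations with Tukey HSD letter groups.

    Groups sharing a letter are not significantly different at ``alpha``.
    The sum-of-squares decomposition is computed directly so that identical
    groups yield F = 0 (rather than 0/0); the p-value comes from the F
    distribution and pairwise comparisons from Tukey's HSD.
    """
    names = list(groups)
    data = [np.asarray(groups[name], dtype=float) for name in names]
    if len(names) < 2 or any(len(d) < 2 for d in data):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(data)
    grand = allv.mean()
    ssb = float(sum(len(d) * (d.mean() - grand) ** 2 for d in data))
    ssw = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    dfb, dfw = len(names) - 1, len(allv) - len(names)
    if ssb <= 1e-300:
        f_stat, p = 0.0, 1.0
    elif ssw <= 1e-300:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f_stat, dfb, dfw))

    # Tukey HSD -> graph of non-significant pairs -> letters from its cliques
    nonsig = nx.Graph()
    nonsig.add_nodes_from(names)
    if ssw > 1e-300:
        labels = np.concatenate([[name] * len(d) for name, d in zip(names, data)])
        tk = pairwise_tukeyhsd(allv, labels, alpha=alpha)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            if not row["reject"]:
                nonsig.add_edge(str(row["group1"]), str(row["group2"]))
    else:
        nonsig.add_edges_from((a, b) for a in names for b in names if a < b)

    order = sorted(names, key=lambda nm: float(np.mean(groups[nm])))
    cliques = sorted(
        (sorted(cl, key=order.index) for cl in nx.find_cliques(nonsig)),
        key=lambda cl: order.index(cl[0]),
    )
    letters: Dict[str, List[str]] = {nm: [] for nm in names}
    for letter_i, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_i)
        for nm in clique:
            letters[nm].append(letter)
    return AnovaResult(
        f_statistic=f_stat,
        p_value=p,
        df_between=dfb,
        df_within=dfw,
        letters={nm: "".join(sorted(ls)) for nm, ls in letters.items()},
    )
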