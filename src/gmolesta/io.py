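"""CSV round-tripping for the package's file schemas.

Temperature CSV: ``date,tmin,tmax`` (ISO dates, degC), optionally with a
leading ``site`` column for the long multi-site format; scenario CSV adds a
``scenario`` column.  Trap CSV: ``site,date,count``.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Iterable, List

import pandas as pd

from .errors import InvalidInputError
from .fitting import TrapSeries

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_trap_csv",
    "write_trap_csv",
]


def read_temperature_csv(path) -> Dict[str, pd.DataFrame]:
    """Read a temperature CSV into per-site frames (key ``""`` if siteless)."""
    df = pd.read_csv(path)
    need = {"date", "tmin", "tmax"} - set(df.columns)
    if need:
        raise InvalidInputError(f"temperature CSV {path} lacks columns {sorted(need)}")
    df["date"] = pd.to_datetime(df["date"])
    if "site" in df.columns:
        return {
            str(site): grp[["date", "tmin", "tmax"]].reset_index(drop=True)
            for site, grp in df.groupby("site", sort=False)
        }
    return {"": df[["date", "tmin", "tmax"]]}


def write_temperature_csv(frames: Dict[str, pd.DataFrame], path) -> None:
    parts = []
    for site, df in frames.items():
        part = df.copy()
        part.insert(0, "site", site)
        part["date"] = pd.to_datetime(part["date"]).dt.strftime("%Y-%m-%d")
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_trap_csv(path) -> List[TrapSeries]:
    """Read ``site,date,count`` into one TrapSeries per site-year."""
    df = pd.read_csv(path)
    need = {"site", "date", "count"} - set(df.columns)
    if need:
        raise InvalidInputError(f"trap CSV {path} lacks columns {sorted(need)}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["site", "date"])
    out: List[TrapSeries] = []
    for (site, year), grp in df.groupby([df["site"], df["date"].dt.year], sort=False):
        out.append(
            TrapSeries(
                site_id=str(site),
                dates=tuple(d.date() for d in grp["date"]),
                counts=tuple(int(c) for c in grp["count"]),
            )
        )
    return out


def write_trap_csv(series: Iterable[TrapSeries], path) -> None:
    rows = [
        {"site": s.site_id, "date": d.isoformat(), "count": c}
        for s in series
        for d, c in zip(s.dates, s.counts)
    ]
    pd.DataFrame(rows, columns=["site", "date", "count"]).to_csv(path, index=False)
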