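"""CSV readers and writers for the package's tabular formats.

All tables are comma-separated UTF-8 with a header row and '.' decimals.

* depth tables: ``depth_mm,<proxy>`` columns;
* monthly tables: ``year,month,value``;
* event catalogues: ``year,month,category,label``;
* water samples: ``site_id,salinity,ba_nmol_kg``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DepthSeries, EventCatalog, EventRecord, MonthlySeries, WaterSample
from .errors import DataGapError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "read_depth_series",
    "read_monthly_series",
    "read_event_catalog",
    "read_water_samples",
    "write_table",
    "write_monthly_series",
    "write_depth_series",
]

# full double precision round-trips through text
_FLOAT_FMT = "%.17g"


def read_depth_series(
    path,
    proxy_name: str,
    column_map: Mapping[str, str] | None = None,
    analytical_rsd: float | None = None,
) -> DepthSeries:
    """Read a depth-indexed proxy table.

    ``column_map`` may rename nonstandard headers, e.g.
    ``{"depth_mm": "depth", "ba_ca": "Ba/Ca"}`` maps the expected logical
    names onto the columns actually present in the file.
    """
    df = pd.read_csv(path)
    colmap = {"depth_mm": "depth_mm", proxy_name: proxy_name}
    if column_map:
        colmap.update(column_map)
    for logical, actual in colmap.items():
        if actual not in df.columns:
            raise SchemaError(f"{path}: missing column {actual!r} (for {logical!r})")
    depth = pd.to_numeric(df[colmap["depth_mm"]], errors="coerce").to_numpy()
    vals = pd.to_numeric(df[colmap[proxy_name]], errors="coerce").to_numpy()
    if np.any(~np.isfinite(depth)) or np.any(~np.isfinite(vals)):
        raise SchemaError(f"{path}: non-numeric entries in depth or {proxy_name}")
    order = np.argsort(depth, kind="stable")
    depth, vals = depth[order], vals[order]
    if np.any(np.diff(depth) == 0):
        raise SchemaError(f"{path}: duplicated depths")
    return DepthSeries(depth, vals, proxy_name=proxy_name, analytical_rsd=analytical_rsd)


def read_monthly_series(path, units: str = "", max_gap_months: int = 3) -> MonthlySeries:
    """Read a ``year,month,value`` table onto a contiguous monthly grid.

    Gaps of up to ``max_gap_months`` missing months are filled by linear
    interpolation (and logged); longer gaps raise :class:`DataGapError`.
    """
    df = pd.read_csv(path)
    for col in ("year", "month", "value"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    idx = pd.PeriodIndex(
        [pd.Period(year=int(y), month=int(m), freq="M") for y, m in zip(df["year"], df["month"])]
    )
    s = pd.Series(pd.to_numeric(df["value"], errors="coerce").to_numpy(), index=idx)
    s = s.sort_index()
    if s.index.has_duplicates:
        raise SchemaError(f"{path}: duplicated months")
    full = pd.period_range(s.index[0], s.index[-1], freq="M")
    gaps = full.difference(s.index)
    if len(gaps):
        # reject any single contiguous run of missing months longer than the cap
        ords = gaps.asi8
        run = 1
        longest = 1
        for d in np.diff(ords):
            run = run + 1 if d == 1 else 1
            longest = max(longest, run)
        if longest > max_gap_months:
            raise DataGapError(f"{path}: gap of {longest} months exceeds {max_gap_months}")
        logger.info("%s: filled %d missing month(s) by linear interpolation: %s",
                    path, len(gaps), list(gaps.astype(str)))
    s = s.reindex(full).interpolate(method="linear", limit_area="inside")
    if s.isna().any():
        raise SchemaError(f"{path}: non-numeric values remain after interpolation")
    return MonthlySeries(s, units=units)


def read_event_catalog(path) -> EventCatalog:
    df = pd.read_csv(path)
    for col in ("year", "month", "category"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        label = str(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else ""
        records.append(
            EventRecord(
                date=pd.Period(year=int(row["year"]), month=int(row["month"]), freq="M"),
                category=str(row["category"]),
                label=label,
            )
        )
    return EventCatalog(records)


def read_water_samples(path) -> list[WaterSample]:
    df = pd.read_csv(path)
    for col in ("site_id", "salinity", "ba_nmol_kg"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return [
        WaterSample(str(r["site_id"]), float(r["salinity"]), float(r["ba_nmol_kg"]))
        for _, r in df.iterrows()
    ]


def write_table(records: Iterable[Mapping] | pd.DataFrame, path, columns: Sequence[str] | None = None) -> Path:
    """Write records to CSV with a deterministic column order and full precision.

    ``records`` may be a DataFrame or an iterable of mappings; an empty
    iterable with explicit ``columns`` yields a header-only file.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows:
            cols = columns if columns is not None else list(rows[0].keys())
            df = pd.DataFrame(rows, columns=cols)
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    if columns is not None:
        df = df[list(columns)]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_monthly_series(series: MonthlySeries, path) -> Path:
    return write_table(series.to_frame(), path, columns=("year", "month", "value"))


def write_depth_series(series: DepthSeries, path) -> Path:
    df = pd.DataFrame({"depth_mm": series.depth_mm, series.proxy_name or "value": series.values})
    return write_table(df, path)
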