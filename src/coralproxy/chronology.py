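"""Tie-point chronology: from Sr/Ca extrema to a monthly-resolved record.

The age model rests on the anticorrelation between skeletal Sr/Ca and sea
surface temperature: each Sr/Ca maximum marks a winter (coolest month) and
each minimum a summer (warmest month). Within the instrumental SST span the
i-th maximum counting down from the core top is paired with the i-th
coolest observed month counting back from collection; before the
instrumental record, maxima/minima default to fixed climatological months
(February/August). Between tie points growth is assumed constant, giving a
piecewise-linear depth-to-time map used to resample the depth profiles onto
a monthly grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (
    AgeModel,
    DepthSeries,
    MonthlySeries,
    TiePoint,
    month_mid,
    period_of,
)
from .errors import CalibrationError, ChronologyError

logger = logging.getLogger(__name__)

__all__ = [
    "ProxyCalibration",
    "detect_extrema",
    "build_tiepoints",
    "build_age_model",
    "resample_monthly",
    "calibrate_sst_proxy",
    "reconstruct_sst",
    "delta_srca",
]


@dataclass(frozen=True)
class ProxyCalibration:
    """Linear proxy-SST calibration: proxy = intercept + slope * SST."""

    slope: float  # proxy units per deg C
    intercept: float
    r: float
    n: int
    span: tuple[pd.Period, pd.Period] | None = None

    def predict(self, sst: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(sst, dtype=float)

    def invert(self, proxy: np.ndarray) -> np.ndarray:
        if self.slope == 0:
            raise CalibrationError("cannot invert a zero-slope calibration")
        return (np.asarray(proxy, dtype=float) - self.intercept) / self.slope


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge shrinkage (no phase shift)."""
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.pad(values, window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[window // 2: window // 2 + values.size]
    return out


def detect_extrema(
    series: DepthSeries,
    min_separation_mm: float = 4.8,
    kind: str = "maxima",
    smooth_window_mm: float | None = None,
    min_prominence_frac: float = 0.2,
) -> np.ndarray:
    """Locate annual-scale local extrema of a depth profile.

    The profile is pre-smoothed with a centred moving average (default
    window: six months of mean growth, ~4.8 mm — wide enough to suppress
    analytical noise near the flat seasonal extremes while leaving the
    annual cycle and its extremal positions intact, since a symmetric
    moving average introduces no phase shift) before peak picking; extrema
    closer together than ``min_separation_mm`` are suppressed, keeping the
    more extreme one. Plateau ties resolve to the plateau midpoint.
    Returns the extremal depths in increasing order.
    """
    if kind not in ("maxima", "minima"):
        raise ChronologyError(f"unknown extremum kind {kind!r}")
    depth = series.depth_mm
    values = series.values
    spacing = float(np.median(np.diff(depth)))
    if smooth_window_mm is None:
        smooth_window_mm = 4.8  # ~6 months of growth at ~9.6 mm/yr
    window = max(1, int(round(smooth_window_mm / spacing)))
    smoothed = _moving_average(values, window)
    sig = smoothed if kind == "maxima" else -smoothed
    distance = max(1, int(round(min_separation_mm / spacing)))
    # reject residual noise bumps: a real annual extremum rises well above
    # its surroundings, so require a fraction of the smoothed signal's
    # robust range (5th-95th percentile) as prominence
    lo, hi = np.percentile(smoothed, [5, 95])
    prominence = min_prominence_frac * (hi - lo)
    peaks, props = find_peaks(sig, distance=distance, plateau_size=1,
                              prominence=prominence if prominence > 0 else None)
    if peaks.size == 0:
        raise ChronologyError(f"no {kind} found in {series.proxy_name!r}")
    # plateau midpoints
    lefts = props.get("left_edges", peaks)
    rights = props.get("right_edges", peaks)
    mids = (depth[lefts] + depth[rights]) / 2.0
    return np.sort(mids)


def _seasonal_extreme_dates(
    sst: MonthlySeries, month: int, minimum: bool, window: int = 2
) -> list[pd.Period]:
    """Date of the coolest/warmest observed month of each annual season.

    For each year, the extremum is searched within ``month +/- window``
    months; seasons not fully covered by the SST record are skipped.
    Returns dates in increasing order.
    """
    out = []
    for year in range(sst.start.year - 1, sst.end.year + 2):
        center = period_of(year, month)
        lo, hi = center - window, center + window
        if lo < sst.start or hi > sst.end:
            continue
        seg = sst.data.loc[lo:hi]
        pick = seg.idxmin() if minimum else seg.idxmax()
        out.append(pick)
    return out


def build_tiepoints(
    extrema_max: np.ndarray,
    extrema_min: np.ndarray,
    sst: MonthlySeries | None = None,
    instrumental_start: pd.Period | None = None,
    collection_date: pd.Period | None = None,
    coolest_month: int = 2,
    warmest_month: int = 8,
) -> list[TiePoint]:
    """Pair Sr/Ca extrema depths with calendar months.

    All extrema are merged and walked from the core top downwards; each one
    is dated with the newest season of its kind strictly older than the
    previously assigned date. When the extrema alternate cleanly this pairs
    the i-th maximum from the top with the i-th coolest observed month
    counting back from collection (likewise minima and warmest months), and
    it stays consistent when a truncated extremum at the core edges is
    missing. Seasons younger than ``instrumental_start`` must be dated from
    the SST record (a shortfall raises :class:`ChronologyError`); older
    seasons fall back to the climatological coolest/warmest month.
    """
    extrema_max = np.sort(np.asarray(extrema_max, dtype=float))
    extrema_min = np.sort(np.asarray(extrema_min, dtype=float))
    if extrema_max.size == 0:
        raise ChronologyError("no maxima to anchor the chronology")
    if collection_date is None:
        if sst is not None:
            collection_date = sst.end
        else:
            raise ChronologyError("collection_date required when no SST is given")
    if sst is not None and instrumental_start is None:
        instrumental_start = sst.start

    inst_dates: dict[str, list[pd.Period]] = {"winter": [], "summer": []}
    if sst is not None:
        for kind, month, minimum in (("winter", coolest_month, True),
                                     ("summer", warmest_month, False)):
            inst_dates[kind] = sorted(
                (d for d in _seasonal_extreme_dates(sst, month, minimum=minimum)
                 if d <= collection_date),
                key=lambda p: -p.ordinal,
            )

    def next_date(kind: str, before: pd.Period) -> pd.Period:
        month = coolest_month if kind == "winter" else warmest_month
        for d in inst_dates[kind]:
            if d < before:
                return d
        # climatological fallback for pre-instrumental seasons
        year = before.year
        while period_of(year, month) >= before:
            year -= 1
        fallback = period_of(year, month)
        if sst is not None and instrumental_start is not None and fallback >= instrumental_start:
            raise ChronologyError(
                f"{kind} extremum before {before} falls inside the instrumental "
                f"span but the SST record covers only {len(inst_dates[kind])} seasons"
            )
        return fallback

    merged = sorted(
        [(float(d), "winter") for d in extrema_max]
        + [(float(d), "summer") for d in extrema_min]
    )
    tiepoints: list[TiePoint] = []
    last_date = collection_date + 1
    for depth, kind in merged:
        date = next_date(kind, last_date)
        tiepoints.append(TiePoint(depth, date, kind))
        last_date = date
    dates = [t.date.ordinal for t in tiepoints]
    if any(b >= a for a, b in zip(dates[:-1], dates[1:])):
        raise ChronologyError("tie point dates do not strictly decrease with depth")
    kinds = [t.kind for t in tiepoints]
    if any(a == b for a, b in zip(kinds[:-1], kinds[1:])):
        logger.warning("tie point kinds do not alternate everywhere; check extrema")
    return tiepoints


def build_age_model(tiepoints: list[TiePoint], collection_date: pd.Period) -> AgeModel:
    """Piecewise-linear age model through the tie points (constant growth
    between anchors, extrapolated at the end segments, capped at collection)."""
    return AgeModel(tiepoints=list(tiepoints), collection_date=collection_date)


def resample_monthly(series: DepthSeries, model: AgeModel, units: str = "") -> MonthlySeries:
    """Resample a depth profile onto the monthly grid of the age model.

    Each month's value is the linear interpolation of the profile at the
    depth mapped to the month's midpoint (the 15th); months whose midpoint
    falls outside the profile's depth span are omitted.
    """
    t_young = model.depth_to_time(series.depth_mm[0])
    t_old = model.depth_to_time(series.depth_mm[-1])
    first = pd.Period(ordinal=int(np.ceil(t_old - 0.5)), freq="M")
    last = pd.Period(ordinal=int(np.floor(t_young - 0.5)), freq="M")
    if first > last:
        raise ChronologyError("age model and depth profile do not overlap")
    months = pd.period_range(first, last, freq="M")
    mids = months.asi8.astype(float) + 0.5
    depths = model.time_to_depth(mids)
    inside = (depths >= series.depth_mm[0]) & (depths <= series.depth_mm[-1])
    if not inside.any():
        raise ChronologyError("no month midpoint falls inside the profile span")
    months = months[inside]
    vals = np.interp(depths[inside], series.depth_mm, series.values)
    return MonthlySeries(pd.Series(vals, index=months), units=units)


def calibrate_sst_proxy(proxy: MonthlySeries, sst: MonthlySeries) -> ProxyCalibration:
    """Ordinary least squares of the proxy on SST over their overlap.

    Requires at least 24 overlapping months so the fit spans two full
    seasonal cycles.
    """
    p, s = proxy.overlap(sst)
    if len(p) < 24:
        raise CalibrationError(f"only {len(p)} overlapping months; need >= 24")
    x = s.values
    y = p.values
    slope, intercept = np.polyfit(x, y, 1)
    from .core import pearson

    corr = pearson(x, y)
    return ProxyCalibration(
        slope=float(slope),
        intercept=float(intercept),
        r=corr.r,
        n=len(p),
        span=(p.start, p.end),
    )


def reconstruct_sst(proxy: MonthlySeries, cal: ProxyCalibration) -> MonthlySeries:
    """Invert the thermometer: SST = (proxy - intercept) / slope."""
    return MonthlySeries(
        pd.Series(cal.invert(proxy.values), index=proxy.index), units="degC"
    )


def delta_srca(
    proxy: MonthlySeries, cal: ProxyCalibration, sst: MonthlySeries
) -> MonthlySeries:
    """Growth-disturbance proxy: measured Sr/Ca minus the SST prediction."""
    p, s = proxy.overlap(sst)
    resid = p.values - cal.predict(s.values)
    return MonthlySeries(pd.Series(resid, index=p.index), units=proxy.units)
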