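"""Annual skeletal growth parameters and their response to the Ba/Ca trend.

Extension (mm/yr) is the distance between successive winter tie points
(Sr/Ca maxima = SST minima); density (g/cm^3) is the yearly average of a
calibrated density profile placed on the age model; calcification
(g cm^-2 yr^-1) is extension (in cm) times density. The per-period
correlation of extension/calcification with the annual-mean low-pass Ba/Ca
quantifies how growth responds to the sediment-load proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AgeModel, CorrelationResult, DepthSeries, TiePoint, pearson
from .errors import ChronologyError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnualGrowthRecord",
    "annual_extension",
    "annual_density",
    "calcification_rate",
    "growth_records",
    "growth_vs_lowpass",
    "PeriodRegression",
]


@dataclass(frozen=True)
class AnnualGrowthRecord:
    year: int
    extension_mm: float
    density_g_cm3: float
    calcification_g_cm2: float

    def __post_init__(self) -> None:
        if self.extension_mm <= 0:
            raise DegenerateDataError(f"non-positive extension in year {self.year}")
        if not 0.5 < self.density_g_cm3 < 2.5:
            raise DegenerateDataError(
                f"density {self.density_g_cm3} g/cm^3 outside the plausible coral range"
            )


def annual_extension(winter_tiepoints: list[TiePoint]) -> pd.Series:
    """Annual extension: spacing of successive winter tie points.

    The interval between the winter of year Y and the winter of year Y+1 is
    labelled with year Y (the calendar year containing its summer midpoint).
    Returns a Series indexed by year, in mm/yr.
    """
    tps = sorted(
        (t for t in winter_tiepoints if t.kind == "winter"),
        key=lambda t: t.date.ordinal,
    )
    if len(tps) < 2:
        raise ChronologyError("need at least 2 winter tie points")
    depths = np.array([t.depth_mm for t in tps])
    if np.any(np.diff(depths) >= 0):
        raise ChronologyError("winter tie point depths must decrease with date")
    years = []
    ext = []
    for older, younger in zip(tps[:-1], tps[1:]):
        years.append(int(older.date.year))
        ext.append(float(older.depth_mm - younger.depth_mm))
    return pd.Series(ext, index=pd.Index(years, name="year"), name="extension_mm")


def annual_density(density: DepthSeries, model: AgeModel) -> pd.Series:
    """Time-averaged density per complete calendar year.

    Density samples are dated through the age model; years only partially
    covered by the profile are omitted and logged.
    """
    t = model.depth_to_time(density.depth_mm)
    periods = pd.PeriodIndex(
        [pd.Period(ordinal=int(np.floor(ti)), freq="M") for ti in t]
    )
    s = pd.Series(density.values, index=periods)
    by_year = s.groupby(periods.year)
    months_per_year = by_year.apply(lambda g: g.index.month.nunique())
    complete = months_per_year[months_per_year == 12].index
    dropped = sorted(set(months_per_year.index) - set(complete))
    if dropped:
        logger.info("annual_density: omitting partially covered year(s) %s", dropped)
    if len(complete) == 0:
        raise ChronologyError("density profile covers no complete calendar year")
    out = by_year.mean().loc[complete]
    out.index.name = "year"
    return out.rename("density_g_cm3")


def calcification_rate(extension_mm: pd.Series, density_g_cm3: pd.Series) -> pd.Series:
    """Calcification = extension (cm) * density, for the matched years."""
    years = extension_mm.index.intersection(density_g_cm3.index)
    unmatched = set(extension_mm.index).symmetric_difference(density_g_cm3.index)
    if unmatched:
        logger.warning("calcification_rate: dropping unmatched year(s) %s", sorted(unmatched))
    if len(years) == 0:
        raise DegenerateDataError("no common years between extension and density")
    ext = extension_mm.loc[years]
    if np.any(ext.to_numpy() <= 0):
        raise DegenerateDataError("extension must be positive")
    out = ext / 10.0 * density_g_cm3.loc[years]
    return out.rename("calcification_g_cm2")


def growth_records(
    extension_mm: pd.Series, density_g_cm3: pd.Series
) -> list[AnnualGrowthRecord]:
    calc = calcification_rate(extension_mm, density_g_cm3)
    return [
        AnnualGrowthRecord(
            year=int(y),
            extension_mm=float(extension_mm.loc[y]),
            density_g_cm3=float(density_g_cm3.loc[y]),
            calcification_g_cm2=float(calc.loc[y]),
        )
        for y in calc.index
    ]


@dataclass(frozen=True)
class PeriodRegression:
    """Per-period association of a growth variable with the low-pass proxy."""

    correlation: CorrelationResult
    slope: float
    slope_se: float
    intercept: float


def _regress(x: np.ndarray, y: np.ndarray) -> PeriodRegression:
    corr = pearson(x, y)
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sxx = np.sum((x - x.mean()) ** 2)
    dof = max(n - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return PeriodRegression(
        correlation=corr, slope=float(slope), slope_se=se, intercept=float(intercept)
    )


def growth_vs_lowpass(
    records: list[AnnualGrowthRecord],
    lowpass_annual: pd.Series,
    boundary_year: int = 1996,
) -> dict[str, dict[str, PeriodRegression]]:
    """Per-period OLS of extension and calcification on the annual low-pass proxy.

    Years strictly before ``boundary_year`` form period A, the rest period B.
    Periods with fewer than 3 overlapping years are skipped with a warning.
    Returns ``{"extension"|"calcification": {"A"|"B": PeriodRegression}}``.
    """
    rec_years = pd.Index([r.year for r in records])
    common = rec_years.intersection(lowpass_annual.index)
    by_year = {r.year: r for r in records}
    out: dict[str, dict[str, PeriodRegression]] = {"extension": {}, "calcification": {}}
    for label, years in (
        ("A", [y for y in common if y < boundary_year]),
        ("B", [y for y in common if y >= boundary_year]),
    ):
        if len(years) < 3:
            logger.warning("growth_vs_lowpass: period %s has %d year(s); skipped",
                           label, len(years))
            continue
        x = lowpass_annual.loc[years].to_numpy(dtype=float)
        ext = np.array([by_year[y].extension_mm for y in years])
        calc = np.array([by_year[y].calcification_g_cm2 for y in years])
        out["extension"][label] = _regress(x, ext)
        out["calcification"][label] = _regress(x, calc)
    return out
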