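"""Domain types shared across the pipeline, plus basic statistics.

The package works in two coordinate systems:

* **depth** below the living coral surface, in mm (0 = tissue surface at the
  collection date, increasing downcore, i.e. back in time);
* **calendar months**, represented as :class:`pandas.Period` objects with
  monthly frequency. Continuous time uses the period ordinal plus 0.5 (the
  middle of the month), so linear interpolation between months is well
  defined.

An :class:`AgeModel` is the piecewise-linear, strictly monotone bridge
between the two, anchored on :class:`TiePoint` records (a skeletal Sr/Ca
extremum paired with an instrumental SST extremum or a fixed climatological
month).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ChronologyError, DegenerateDataError, SchemaError

__all__ = [
    "DepthSeries",
    "MonthlySeries",
    "TiePoint",
    "AgeModel",
    "CorrelationResult",
    "EventRecord",
    "EventCatalog",
    "WaterSample",
    "month_mid",
    "period_of",
    "pearson",
]


def period_of(year: int, month: int) -> pd.Period:
    """Calendar month as a monthly-frequency :class:`pandas.Period`."""
    return pd.Period(year=year, month=month, freq="M")


def month_mid(p: pd.Period) -> float:
    """Continuous time coordinate of the middle of month *p* (ordinal + 0.5)."""
    return p.ordinal + 0.5


@dataclass(frozen=True)
class DepthSeries:
    """A proxy profile sampled along the coral growth axis.

    Parameters
    ----------
    depth_mm
        Sample depths below the living surface, strictly increasing.
    values
        Proxy value at each depth. Units depend on the proxy: Ba/Ca in
        umol/mol, Sr/Ca in mmol/mol, Mg/Ca in mmol/mol, density in g/cm^3.
    proxy_name
        Identifier such as ``"ba_ca"`` or ``"sr_ca"``.
    analytical_rsd
        Fractional 1-sigma relative standard deviation of the analysis
        (e.g. 0.0224 for a 2.24% RSD), or ``None`` when unknown.
    """

    depth_mm: np.ndarray
    values: np.ndarray
    proxy_name: str = ""
    analytical_rsd: float | None = None

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth_mm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depth_mm", depth)
        object.__setattr__(self, "values", vals)
        if depth.ndim != 1 or vals.ndim != 1 or depth.size != vals.size:
            raise SchemaError("depth and values must be 1-D arrays of equal length")
        if depth.size < 2:
            raise SchemaError("a depth series needs at least 2 samples")
        if not np.all(np.isfinite(depth)) or not np.all(np.isfinite(vals)):
            raise SchemaError(f"non-finite entries in depth series {self.proxy_name!r}")
        if np.any(np.diff(depth) <= 0):
            raise SchemaError(
                f"depths must be strictly increasing in {self.proxy_name!r} "
                "(duplicate or unsorted depths)"
            )

    def __len__(self) -> int:
        return int(self.depth_mm.size)

    @property
    def span_mm(self) -> tuple[float, float]:
        return float(self.depth_mm[0]), float(self.depth_mm[-1])


class MonthlySeries:
    """A proxy or environmental series on a contiguous monthly grid.

    Wraps a :class:`pandas.Series` indexed by a monthly ``PeriodIndex`` with
    no gaps; most pipeline stages (filtering, climatology, resampling)
    require this contiguity and it is enforced at construction.
    """

    def __init__(self, data: pd.Series, units: str = "") -> None:
        if not isinstance(data.index, pd.PeriodIndex) or data.index.freqstr not in ("M",):
            raise SchemaError("MonthlySeries requires a monthly PeriodIndex")
        if len(data) == 0:
            raise SchemaError("MonthlySeries cannot be empty")
        ords = data.index.asi8
        if np.any(np.diff(ords) != 1):
            raise SchemaError("month index must be contiguous and increasing")
        self.data = data.astype(float)
        self.units = units

    # -- constructors -------------------------------------------------
    @classmethod
    def from_arrays(cls, years, months, values, units: str = "") -> "MonthlySeries":
        idx = pd.PeriodIndex(
            [pd.Period(year=int(y), month=int(m), freq="M") for y, m in zip(years, months)]
        )
        return cls(pd.Series(np.asarray(values, dtype=float), index=idx), units=units)

    @classmethod
    def from_start(cls, start: pd.Period, values, units: str = "") -> "MonthlySeries":
        values = np.asarray(values, dtype=float)
        idx = pd.period_range(start, periods=len(values), freq="M")
        return cls(pd.Series(values, index=idx), units=units)

    # -- accessors ----------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def index(self) -> pd.PeriodIndex:
        return self.data.index

    @property
    def start(self) -> pd.Period:
        return self.data.index[0]

    @property
    def end(self) -> pd.Period:
        return self.data.index[-1]

    def __len__(self) -> int:
        return len(self.data)

    def mid_ordinals(self) -> np.ndarray:
        """Continuous mid-month time coordinates for every month."""
        return self.data.index.asi8.astype(float) + 0.5

    def slice(self, start: pd.Period | None = None, end: pd.Period | None = None) -> "MonthlySeries":
        sub = self.data.loc[start:end]
        return MonthlySeries(sub, units=self.units)

    def with_values(self, values: np.ndarray) -> "MonthlySeries":
        return MonthlySeries(pd.Series(np.asarray(values, float), index=self.index), units=self.units)

    def overlap(self, other: "MonthlySeries") -> tuple["MonthlySeries", "MonthlySeries"]:
        """Both series restricted to their common span."""
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if lo > hi:
            raise SchemaError("series do not overlap")
        return self.slice(lo, hi), other.slice(lo, hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.index.year,
                "month": self.index.month,
                "value": self.values,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"MonthlySeries({self.start}..{self.end}, n={len(self)}, "
            f"units={self.units!r})"
        )


@dataclass(frozen=True)
class TiePoint:
    """A (depth, calendar month) chronology anchor.

    ``kind`` is ``"winter"`` for a Sr/Ca maximum tied to the coolest month
    and ``"summer"`` for a Sr/Ca minimum tied to the warmest month.
    """

    depth_mm: float
    date: pd.Period
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("winter", "summer"):
            raise ChronologyError(f"unknown tie point kind {self.kind!r}")


@dataclass
class AgeModel:
    """Piecewise-linear, strictly monotone depth -> calendar-time mapping.

    Between tie points the growth rate is assumed constant; above the first
    tie point the shallowest segment's rate is extrapolated but capped at
    the collection date, and below the last tie point the deepest segment's
    rate is extrapolated.
    """

    tiepoints: list[TiePoint]
    collection_date: pd.Period
    _depths: np.ndarray = field(init=False, repr=False)
    _times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tps = sorted(self.tiepoints, key=lambda t: t.depth_mm)
        if len(tps) < 2:
            raise ChronologyError("an age model needs at least 2 tie points")
        depths = np.array([t.depth_mm for t in tps], dtype=float)
        times = np.array([month_mid(t.date) for t in tps], dtype=float)
        if np.any(np.diff(depths) <= 0):
            raise ChronologyError("tie point depths must be strictly increasing")
        if np.any(np.diff(times) >= 0):
            raise ChronologyError("tie point dates must strictly decrease with depth")
        self.tiepoints = tps
        self._depths = depths
        self._times = times

    # continuous time is the mid-month ordinal coordinate of core.month_mid
    def depth_to_time(self, depth_mm) -> np.ndarray:
        depth = np.atleast_1d(np.asarray(depth_mm, dtype=float))
        t = np.interp(depth, self._depths, self._times)
        # linear extrapolation beyond the anchored span
        top_rate = (self._times[1] - self._times[0]) / (self._depths[1] - self._depths[0])
        above = depth < self._depths[0]
        t[above] = self._times[0] + (depth[above] - self._depths[0]) * top_rate
        bot_rate = (self._times[-1] - self._times[-2]) / (self._depths[-1] - self._depths[-2])
        below = depth > self._depths[-1]
        t[below] = self._times[-1] + (depth[below] - self._depths[-1]) * bot_rate
        # the skeleton cannot be younger than the collection date
        np.minimum(t, month_mid(self.collection_date) + 0.5, out=t)
        return t if np.ndim(depth_mm) else float(t[0])

    def time_to_depth(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        # times decrease with depth; np.interp needs increasing x
        rev_t = self._times[::-1]
        rev_d = self._depths[::-1]
        d = np.interp(tt, rev_t, rev_d)
        top_rate = (self._depths[1] - self._depths[0]) / (self._times[1] - self._times[0])
        late = tt > self._times[0]
        d[late] = self._depths[0] + (tt[late] - self._times[0]) * top_rate
        bot_rate = (self._depths[-1] - self._depths[-2]) / (self._times[-1] - self._times[-2])
        early = tt < self._times[-1]
        d[early] = self._depths[-1] + (tt[early] - self._times[-1]) * bot_rate
        return d if np.ndim(t) else float(d[0])

    @property
    def span_time(self) -> tuple[float, float]:
        """(oldest, youngest) continuous time covered by the tie points."""
        return float(self._times[-1]), float(self._times[0])


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided t-test significance."""

    r: float
    p: float
    n: int


@dataclass(frozen=True)
class EventRecord:
    date: pd.Period
    category: str
    label: str = ""


@dataclass
class EventCatalog:
    """Documented local events (floods, typhoons, landslides, quarry collapses)."""

    records: list[EventRecord]

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> list[EventRecord]:
        return sorted(self.records, key=lambda r: r.date.ordinal)


@dataclass(frozen=True)
class WaterSample:
    """A river/estuary/bay water sample: practical salinity and dissolved Ba."""

    site_id: str
    salinity: float
    ba_nmol_kg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.salinity <= 40.0:
            raise SchemaError(f"salinity {self.salinity} outside [0, 40]")
        if not self.ba_nmol_kg > 0:
            raise SchemaError("Ba concentration must be positive")


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    The significance follows the usual transformation
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom.
    Inputs must be equal-length, finite, with at least 3 pairs and nonzero
    variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("pearson needs two equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise DegenerateDataError("pearson needs at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateDataError("pearson inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("pearson inputs must have nonzero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)
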