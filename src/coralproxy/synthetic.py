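"""Forward simulator for a virtual massive-coral (*Porites*-type) core.

The simulator produces a depth-resolved geochemical core with fully known
truth, emulating the statistical structure of a ~46-year subtropical
bay record:

* monthly SST with a seasonal cycle (warmest August, coolest February);
* skeletal Sr/Ca and Mg/Ca as linear thermometers of that SST;
* a seawater Ba/Ca forcing made of a piecewise-linear multidecadal trend
  (rise -> fall -> rise around a shift year), a seasonal term peaking in the
  typhoon season, and lagged exponentially-decaying spike events standing in
  for flood-driven sediment pulses;
* skeletal density with a seasonal modulation;
* annual extension drawn lognormally around a mean growth rate, mapped to
  depth by inverting the cumulative growth curve and sampled at a fixed
  micro-sampling interval;
* multiplicative analytical noise at instrument-like relative standard
  deviations.

Because the coral/seawater Ba partitioning is ~1, the noise-free skeletal
Ba/Ca equals the seawater Ba/Ca forcing; every downstream stage can be
scored against the emitted :class:`TruthBundle`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DepthSeries, MonthlySeries, TiePoint, month_mid, period_of
from .errors import ConfigError, ResolutionError

__all__ = [
    "SpikeEvent",
    "SyntheticCoreConfig",
    "TruthBundle",
    "simulate_environment",
    "simulate_core",
    "inject_spike",
]


@dataclass(frozen=True)
class SpikeEvent:
    """A discrete sediment-pulse event driving a lagged Ba spike.

    The skeletal response begins ``lag_months`` after the event and decays
    exponentially with e-folding time ``decay_months``.
    """

    year: int
    month: int
    magnitude: float  # umol/mol added at the response peak
    lag_months: int = 0
    decay_months: float = 2.0

    def __post_init__(self) -> None:
        if self.magnitude < 0 or self.decay_months < 0 or self.lag_months < 0:
            raise ConfigError("spike magnitude, lag and decay must be non-negative")


def _default_spikes() -> tuple[SpikeEvent, ...]:
    # eight flood/heavy-rain pulses spread over the record, with the
    # documented-flood analogues (1977, 1990, 1991, 2010) among them
    return (
        SpikeEvent(1972, 7, 0.9, 2),
        SpikeEvent(1977, 6, 1.0, 3),
        SpikeEvent(1983, 8, 1.1, 1),
        SpikeEvent(1990, 9, 1.2, 0),
        SpikeEvent(1991, 8, 1.0, 2),
        SpikeEvent(1996, 9, 1.0, 2),
        SpikeEvent(2005, 8, 0.9, 3),
        SpikeEvent(2010, 10, 1.5, 4),
    )


@dataclass(frozen=True)
class SyntheticCoreConfig:
    """All tunables of the virtual core; defaults emulate the target record."""

    n_years: int = 46
    collection_year: int = 2014
    collection_month: int = 10

    mean_extension_mm_yr: float = 9.6
    extension_sigma: float = 0.08  # lognormal sigma of per-year extension
    winter_slowdown: float = 0.0  # 0 = uniform intra-annual growth
    extension_ba_sensitivity: float = 0.0  # mm/yr per (umol/mol) forcing anomaly
    sampling_interval_mm: float = 0.25

    sst_mean_c: float = 25.0
    sst_amplitude_c: float = 3.8
    sst_noise_c: float = 0.3
    warmest_month: int = 8  # August; coolest is +6 months (February)

    srca_intercept: float = 10.5  # mmol/mol
    srca_slope: float = -0.06  # mmol/mol per deg C (negative thermometer)
    mgca_intercept: float = 1.2  # mmol/mol
    mgca_slope: float = 0.13  # mmol/mol per deg C

    ba_baseline: float = 3.8  # umol/mol
    # (year, level anomaly) knots of the piecewise-linear multidecadal forcing
    ba_trend_knots: tuple[tuple[int, float], ...] = (
        (1968, -0.15),
        (1980, 0.30),
        (1995, -0.30),
        (2014, 0.35),
    )
    ba_seasonal_amplitude: float = 0.12  # umol/mol
    ba_seasonal_peak_month: int = 9  # September, within the Aug-Oct spike season
    spike_events: tuple[SpikeEvent, ...] = field(default_factory=_default_spikes)

    density_mean: float = 1.25  # g/cm^3
    density_amplitude: float = 0.08

    rsd_ba: float = 0.0224
    rsd_sr: float = 0.0017
    rsd_mg: float = 0.0073

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_extension_mm_yr", "sampling_interval_mm", "ba_baseline",
                     "density_mean", "sst_amplitude_c"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("rsd_ba", "rsd_sr", "rsd_mg"):
            v = getattr(self, name)
            if not 0 <= v < 0.1:
                raise ConfigError(f"{name} must lie in [0, 0.1)")
        years = [y for y, _ in self.ba_trend_knots]
        if years != sorted(years):
            raise ConfigError("ba_trend_knots must be ordered in time")
        if years and (years[0] < self.start.year or years[-1] > self.collection_year):
            raise ConfigError("ba_trend_knots outside the simulated span")
        if not 0 <= self.winter_slowdown < 1:
            raise ConfigError("winter_slowdown must lie in [0, 1)")

    # -- span helpers -------------------------------------------------
    @property
    def collection(self) -> pd.Period:
        return period_of(self.collection_year, self.collection_month)

    @property
    def n_months(self) -> int:
        return self.n_years * 12

    @property
    def start(self) -> pd.Period:
        return self.collection - (self.n_months - 1)

    @property
    def coolest_month(self) -> int:
        return (self.warmest_month + 5) % 12 + 1

    # -- (de)serialisation --------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["spike_events"] = [dataclasses.asdict(s) for s in self.spike_events]
        d["ba_trend_knots"] = [list(k) for k in self.ba_trend_knots]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCoreConfig":
        d = dict(d)
        if "spike_events" in d:
            d["spike_events"] = tuple(SpikeEvent(**s) for s in d["spike_events"])
        if "ba_trend_knots" in d:
            d["ba_trend_knots"] = tuple((int(y), float(v)) for y, v in d["ba_trend_knots"])
        return cls(**d)


@dataclass
class TruthBundle:
    """Everything the simulator knows that the pipeline must recover."""

    sst: MonthlySeries
    ba_forcing: MonthlySeries  # noise-free skeletal Ba/Ca == seawater Ba/Ca
    winter_tiepoints: list[TiePoint] = field(default_factory=list)
    summer_tiepoints: list[TiePoint] = field(default_factory=list)
    annual_extensions: dict[int, float] = field(default_factory=dict)
    shift_year: int | None = None
    peak_months: list[pd.Period] = field(default_factory=list)
    msc_forcing: np.ndarray | None = None  # 12 climatological seasonal values

    def to_json(self) -> str:
        d = {
            "shift_year": self.shift_year,
            "peak_months": [str(p) for p in self.peak_months],
            "winter_tiepoints": [
                {"depth_mm": t.depth_mm, "date": str(t.date)} for t in self.winter_tiepoints
            ],
            "summer_tiepoints": [
                {"depth_mm": t.depth_mm, "date": str(t.date)} for t in self.summer_tiepoints
            ],
            "annual_extensions": {str(y): v for y, v in self.annual_extensions.items()},
            "msc_forcing": list(self.msc_forcing) if self.msc_forcing is not None else None,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _seasonal(months: np.ndarray, peak_month: int) -> np.ndarray:
    """Unit-amplitude cosine over calendar months, maximum at ``peak_month``."""
    return np.cos(2.0 * np.pi * (months - peak_month) / 12.0)


def inject_spike(
    forcing: MonthlySeries,
    event_month: pd.Period,
    magnitude: float,
    lag_months: int,
    decay_months: float,
) -> MonthlySeries:
    """Add a lagged, exponentially decaying pulse to a monthly forcing.

    The response starts at ``event_month + lag_months`` with amplitude
    ``magnitude`` and decays as ``exp(-k / decay_months)`` at the k-th month
    after onset; ``decay_months = 0`` degenerates to a single-month impulse.
    """
    if magnitude < 0 or decay_months < 0 or lag_months < 0:
        raise ConfigError("magnitude, lag and decay must be non-negative")
    onset = event_month + lag_months
    if onset < forcing.start or onset > forcing.end:
        raise ConfigError(f"spike onset {onset} outside series span")
    values = forcing.values.copy()
    idx0 = onset.ordinal - forcing.start.ordinal
    k = np.arange(len(values) - idx0, dtype=float)
    if decay_months == 0:
        kernel = np.zeros_like(k)
        kernel[0] = 1.0
    else:
        kernel = np.exp(-k / decay_months)
    values[idx0:] += magnitude * kernel
    return forcing.with_values(values)


def simulate_environment(
    config: SyntheticCoreConfig, seed: int | None = None
) -> tuple[MonthlySeries, MonthlySeries, TruthBundle]:
    """Simulate monthly SST and the seawater Ba/Ca forcing.

    Returns the two series plus a partial :class:`TruthBundle` carrying the
    injected spike peak months, the trend shift year implied by the knots,
    and the exact seasonal climatology of the forcing.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    idx = pd.period_range(config.start, periods=config.n_months, freq="M")
    months = idx.month.to_numpy()
    dec_year = idx.year.to_numpy() + (months - 0.5) / 12.0

    sst = (
        config.sst_mean_c
        + config.sst_amplitude_c * _seasonal(months, config.warmest_month)
        + rng.normal(0.0, config.sst_noise_c, size=len(idx))
    )
    sst_series = MonthlySeries(pd.Series(sst, index=idx), units="degC")

    knot_years = np.array([y for y, _ in config.ba_trend_knots], dtype=float)
    knot_levels = np.array([v for _, v in config.ba_trend_knots], dtype=float)
    seasonal = config.ba_seasonal_amplitude * _seasonal(months, config.ba_seasonal_peak_month)
    if len(knot_years):
        trend = np.interp(dec_year, knot_years, knot_levels)
    else:
        trend = np.zeros(len(idx))
    forcing = MonthlySeries(
        pd.Series(config.ba_baseline + trend + seasonal, index=idx), units="umol/mol"
    )

    peak_months: list[pd.Period] = []
    for ev in config.spike_events:
        forcing = inject_spike(
            forcing, period_of(ev.year, ev.month), ev.magnitude, ev.lag_months, ev.decay_months
        )
        peak_months.append(period_of(ev.year, ev.month) + ev.lag_months)

    # shift year: last knot where the trend slope turns from falling to rising
    shift_year = None
    slopes = np.diff(knot_levels) / np.maximum(np.diff(knot_years), 1e-9)
    for i in range(1, len(slopes)):
        if slopes[i - 1] < 0 <= slopes[i]:
            shift_year = int(knot_years[i])
    msc = config.ba_seasonal_amplitude * _seasonal(
        np.arange(1, 13), config.ba_seasonal_peak_month
    )
    truth = TruthBundle(
        sst=sst_series,
        ba_forcing=forcing,
        shift_year=shift_year,
        peak_months=peak_months,
        msc_forcing=msc,
    )
    return sst_series, forcing, truth


def _intra_annual_weights(config: SyntheticCoreConfig) -> np.ndarray:
    """Relative monthly growth weights (length 12, mean 1).

    ``winter_slowdown`` in (0, 1) suppresses growth around the coolest month
    to probe chronology robustness; 0 gives uniform monthly growth.
    """
    m = np.arange(1, 13)
    w = 1.0 + config.winter_slowdown * _seasonal(m, config.warmest_month)
    return w / w.mean()


def simulate_core(
    config: SyntheticCoreConfig, seed: int | None = None
) -> tuple[dict[str, DepthSeries], TruthBundle]:
    """Simulate the full virtual core.

    Returns a dict of depth series (keys ``sr_ca``, ``mg_ca``, ``ba_ca``,
    ``density``) and the complete :class:`TruthBundle`. Identical
    ``(config, seed)`` pairs produce bit-identical output.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence([int(seed), 29])
    rng_growth, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    sst_series, forcing, truth = simulate_environment(config, seed)
    idx = forcing.index
    months = idx.month.to_numpy()
    years = idx.year.to_numpy()

    # --- per-year extensions and monthly growth increments -----------
    year_list = np.arange(years[0], years[-1] + 1)
    z = rng_growth.normal(size=len(year_list))
    sig = config.extension_sigma
    ext = config.mean_extension_mm_yr * np.exp(sig * z - 0.5 * sig * sig)
    if config.extension_ba_sensitivity != 0.0:
        f_ann = pd.Series(forcing.values, index=idx).groupby(idx.year).mean()
        anom = f_ann.reindex(year_list).to_numpy() - config.ba_baseline
        ext = ext + config.extension_ba_sensitivity * anom
    if np.any(ext <= 0):
        raise ConfigError("simulated annual extension became non-positive")
    ext_by_year = dict(zip(year_list.tolist(), ext.tolist()))

    weights = _intra_annual_weights(config)
    monthly_growth = np.array(
        [ext_by_year[y] / 12.0 * weights[m - 1] for y, m in zip(years, months)]
    )
    if config.sampling_interval_mm >= monthly_growth.min() * 12.0:
        raise ResolutionError(
            "sampling interval too coarse to resolve the slowest simulated growth"
        )

    # depth of the *old* edge of month j, measured from the living surface
    total_depth = monthly_growth.sum()
    edge_depth = np.concatenate([[total_depth], total_depth - np.cumsum(monthly_growth)])
    edge_depth[-1] = 0.0
    edge_time = idx.asi8.astype(float)  # old edge of month j is at ordinal j
    edge_time = np.concatenate([edge_time, [edge_time[-1] + 1.0]])

    def depth_at_time(t: np.ndarray) -> np.ndarray:
        # np.interp needs increasing x only; depth may decrease with time
        return np.interp(t, edge_time, edge_depth)

    mids = forcing.mid_ordinals()

    # --- sample the proxies on the depth grid ------------------------
    depths = np.arange(0.0, total_depth + 0.5 * config.sampling_interval_mm,
                       config.sampling_interval_mm)
    # invert depth -> time (depth increases as time decreases downcore)
    t_of_depth = np.interp(depths, edge_depth[::-1], edge_time[::-1])

    # Sr/Ca and Mg/Ca inherit the monthly SST (noise included), linearly
    # interpolated between month midpoints; the Ba forcing and density are
    # smooth in time, so they are evaluated continuously at each sample's
    # exact time (identical to the monthly truth at the midpoints)
    sst_monthly = sst_series.values
    ref_peak = month_mid(period_of(years[0], config.ba_seasonal_peak_month))
    ref_warm = month_mid(period_of(years[0], config.warmest_month))

    def ba_continuous(t: np.ndarray) -> np.ndarray:
        dec_year = 1970.0 + t / 12.0
        knot_years = np.array([y for y, _ in config.ba_trend_knots], dtype=float)
        knot_levels = np.array([v for _, v in config.ba_trend_knots], dtype=float)
        trend = np.interp(dec_year, knot_years, knot_levels) if len(knot_years) else 0.0
        out = (config.ba_baseline + trend
               + config.ba_seasonal_amplitude * np.cos(2 * np.pi * (t - ref_peak) / 12.0))
        for ev in config.spike_events:
            onset = month_mid(period_of(ev.year, ev.month)) + ev.lag_months
            k = t - onset
            # the response builds over the onset month (linear ramp to the
            # peak), then decays; at month midpoints this agrees with the
            # monthly spike kernel of inject_spike
            ramp = np.clip(k + 1.0, 0.0, 1.0)
            if ev.decay_months == 0:
                tail = np.clip(1.0 - k, 0.0, 1.0)
                out = out + ev.magnitude * np.where(k < 0, ramp, tail)
            else:
                decay = np.exp(-np.maximum(k, 0.0) / ev.decay_months)
                out = out + ev.magnitude * np.where(k < 0, ramp, decay)
        return out

    profiles = {
        "sr_ca": lambda t: np.interp(
            t, mids, config.srca_intercept + config.srca_slope * sst_monthly),
        "mg_ca": lambda t: np.interp(
            t, mids, config.mgca_intercept + config.mgca_slope * sst_monthly),
        "ba_ca": ba_continuous,
        "density": lambda t: config.density_mean
        + config.density_amplitude * np.cos(2 * np.pi * (t - ref_warm) / 12.0),
    }
    rsds = {"sr_ca": config.rsd_sr, "mg_ca": config.rsd_mg, "ba_ca": config.rsd_ba,
            "density": 0.0}
    cores: dict[str, DepthSeries] = {}
    for name in ("sr_ca", "mg_ca", "ba_ca", "density"):
        clean = profiles[name](t_of_depth)
        noise = rng_noise.normal(size=depths.size)
        vals = clean * (1.0 + rsds[name] * noise)
        cores[name] = DepthSeries(depths, vals, proxy_name=name, analytical_rsd=rsds[name] or None)

    # --- truth: tie points and annual extensions ----------------------
    sst_ser = sst_series.data

    def extremum_tie(window_months: list[pd.Period], minimum: bool) -> TiePoint | None:
        window = [p for p in window_months if forcing.start <= p <= forcing.end]
        if len(window) < len(window_months):
            return None
        vals = sst_ser.loc[window[0]:window[-1]].to_numpy()
        pick = window[int(np.argmin(vals) if minimum else np.argmax(vals))]
        depth = float(depth_at_time(np.array([month_mid(pick)]))[0])
        return TiePoint(depth, pick, "winter" if minimum else "summer")

    cool, warm = config.coolest_month, config.warmest_month
    for year in range(years[0], years[-1] + 2):
        w = [period_of(year, cool) + k for k in range(-2, 3)]
        tp = extremum_tie(w, minimum=True)
        if tp is not None:
            truth.winter_tiepoints.append(tp)
        s = [period_of(year, warm) + k for k in range(-2, 3)]
        tp = extremum_tie(s, minimum=False)
        if tp is not None:
            truth.summer_tiepoints.append(tp)
    truth.winter_tiepoints.sort(key=lambda t: t.depth_mm)
    truth.summer_tiepoints.sort(key=lambda t: t.depth_mm)

    wt = sorted(truth.winter_tiepoints, key=lambda t: t.date.ordinal)
    for a, b in zip(wt[:-1], wt[1:]):
        truth.annual_extensions[int(a.date.year)] = float(a.depth_mm - b.depth_mm)

    return cores, truth
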