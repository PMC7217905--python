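"""End-to-end pipeline: simulate/ingest -> chronology -> decomposition ->
event detection -> SiZer -> growth -> mixing, driven by one JSON config.

The configuration has three blocks:

* ``simulate``: a :class:`~coralproxy.synthetic.SyntheticCoreConfig` mapping
  (mutually exclusive alternative: ``inputs`` with file paths for the
  depth/monthly/event/water CSV tables);
* ``params``: stage parameters, all optional, all logged with the value
  actually used;
* ``out_dir`` and ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronology, decomposition, events, growth, io, mixing, sizer
from .core import EventCatalog, EventRecord
from .errors import ConfigError
from .synthetic import SyntheticCoreConfig, simulate_core

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_PARAMS", "run_pipeline"]

DEFAULT_PARAMS: dict = {
    "bandwidth_cpd": decomposition.DEFAULT_BANDWIDTH_CPD,
    "exclude_months": 0,
    "k_sigma": 0.0,
    "max_lag_months": 4,
    "alpha": 0.05,
    "sizer_bandwidth_low": 2.0,
    "sizer_bandwidth_high": 25.0,
    "sizer_bandwidth_num": 21,
    "boundary_year": 1996,
    "min_separation_mm": 4.8,
}


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Period):
        return str(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Run every configured stage; write stage outputs and a summary JSON.

    Returns the summary dict. Raises :class:`ConfigError` before any stage
    runs if the configuration is unusable.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    cfg = dict(config)
    if out_dir is None:
        out_dir = cfg.get("out_dir")
    if out_dir is None:
        raise ConfigError("no output directory configured")
    out = Path(out_dir)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    for k, v in params.items():
        logger.info("param %s = %r", k, v)

    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' block")

    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "params": params}

    # ------------------------------------------------------------------
    # stage 1: obtain the core
    catalog: EventCatalog | None = None
    water_samples = None
    if "simulate" in cfg:
        sim_cfg = SyntheticCoreConfig.from_dict(cfg["simulate"] or {})
        cores, truth = simulate_core(sim_cfg, seed=seed)
        sst = truth.sst
        for name, ds in cores.items():
            io.write_depth_series(ds, out / f"core_{name}.csv")
        io.write_monthly_series(sst, out / "sst.csv")
        io.write_monthly_series(truth.ba_forcing, out / "ba_forcing.csv")
        (out / "truth.json").write_text(truth.to_json())
        # the simulator's spike events double as the documented catalogue
        catalog = EventCatalog(
            [
                EventRecord(
                    date=pd.Period(year=ev.year, month=ev.month, freq="M"),
                    category="flood",
                    label=f"synthetic event {i}",
                )
                for i, ev in enumerate(sim_cfg.spike_events)
            ]
        )
        collection = sim_cfg.collection
    else:
        inputs = cfg["inputs"]
        cores = {}
        for name in ("sr_ca", "mg_ca", "ba_ca", "density"):
            if name in inputs:
                cores[name] = io.read_depth_series(inputs[name], name)
        if "sr_ca" not in cores or "ba_ca" not in cores:
            raise ConfigError("inputs must provide at least sr_ca and ba_ca tables")
        sst = io.read_monthly_series(inputs["sst"], units="degC") if "sst" in inputs else None
        if "events" in inputs:
            catalog = io.read_event_catalog(inputs["events"])
        if "water_samples" in inputs:
            water_samples = io.read_water_samples(inputs["water_samples"])
        if "collection_date" in cfg:
            y, m = (int(v) for v in str(cfg["collection_date"]).split("-"))
            collection = pd.Period(year=y, month=m, freq="M")
        elif sst is not None:
            collection = sst.end
        else:
            raise ConfigError("collection_date required when no SST series is given")

    # ------------------------------------------------------------------
    # stage 2: chronology
    maxima = chronology.detect_extrema(
        cores["sr_ca"], params["min_separation_mm"], kind="maxima")
    minima = chronology.detect_extrema(
        cores["sr_ca"], params["min_separation_mm"], kind="minima")
    tiepoints = chronology.build_tiepoints(
        maxima, minima, sst=sst, collection_date=collection,
        instrumental_start=(sst.start if sst is not None else None),
    )
    model = chronology.build_age_model(tiepoints, collection)
    io.write_table(
        [
            {"depth_mm": t.depth_mm, "year": t.date.year, "month": t.date.month,
             "kind": t.kind}
            for t in tiepoints
        ],
        out / "tiepoints.csv",
        columns=("depth_mm", "year", "month", "kind"),
    )
    ba_monthly = chronology.resample_monthly(cores["ba_ca"], model, units="umol/mol")
    io.write_monthly_series(ba_monthly, out / "ba_ca_monthly.csv")

    # ------------------------------------------------------------------
    # stage 3: decomposition
    dec = decomposition.decompose(
        ba_monthly, bandwidth_cpd=params["bandwidth_cpd"],
        exclude_months=int(params["exclude_months"]),
    )
    msc = decomposition.mean_seasonal_cycle(dec.detrended)
    annual = decomposition.annual_means(dec.lowpass)
    io.write_monthly_series(dec.lowpass, out / "ba_ca_lowpass.csv")
    io.write_monthly_series(dec.detrended, out / "ba_ca_detrended.csv")
    io.write_table(msc.to_frame(), out / "ba_ca_msc.csv")
    io.write_table(
        pd.DataFrame({"year": annual.index, "value": annual.to_numpy()}),
        out / "ba_ca_lowpass_annual.csv",
    )

    # ------------------------------------------------------------------
    # stage 4: high peaks and event matching
    peaks = events.detect_high_peaks(dec.detrended, msc, k_sigma=params["k_sigma"])
    count_a, count_b = events.count_peaks_by_period(peaks, params["boundary_year"])
    io.write_table(
        [
            {"year": p.month.year, "month": p.month.month, "value": p.value,
             "exceedance": p.exceedance}
            for p in peaks
        ],
        out / "peaks.csv",
        columns=("year", "month", "value", "exceedance"),
    )
    summary["peaks"] = {
        "total": len(peaks),
        "period_A": count_a,
        "period_B": count_b,
        "boundary_year": params["boundary_year"],
    }
    if catalog is not None:
        matches, unmatched_events, unmatched_peaks = events.match_events(
            peaks, catalog, max_lag_months=int(params["max_lag_months"]))
        io.write_table(
            [
                {
                    "event_year": m.record.date.year,
                    "event_month": m.record.date.month,
                    "peak_year": m.peak.month.year,
                    "peak_month": m.peak.month.month,
                    "lag_months": m.lag_months,
                    "category": m.record.category,
                }
                for m in matches
            ],
            out / "event_matches.csv",
            columns=("event_year", "event_month", "peak_year", "peak_month",
                     "lag_months", "category"),
        )
        summary["event_matches"] = {
            "matched": len(matches),
            "unmatched_events": len(unmatched_events),
            "lags": [m.lag_months for m in matches],
        }

    # ------------------------------------------------------------------
    # stage 5: SiZer trend shifts
    bands = sizer.default_bandwidths(
        params["sizer_bandwidth_low"], params["sizer_bandwidth_high"],
        int(params["sizer_bandwidth_num"]))
    smap = sizer.sizer_map(annual, bandwidths=bands, alpha=params["alpha"])
    shifts = sizer.find_shift_points(smap)
    ambiguous = [p for p in sizer.find_shift_points(smap, include_ambiguous=True)
                 if p.ambiguous]
    io.write_table(smap.to_frame(), out / "sizer_map.csv")
    summary["sizer"] = {
        "shift_points": [
            {"interval": list(p.interval), "direction": p.direction,
             "n_bandwidths": len(p.bandwidths)}
            for p in shifts
        ],
        "ambiguous_intervals": sorted({tuple(p.interval) for p in ambiguous}),
    }

    # ------------------------------------------------------------------
    # stage 6: growth and calcification
    winters = [t for t in tiepoints if t.kind == "winter"]
    growth_summary = {}
    if len(winters) >= 2 and "density" in cores:
        ext = growth.annual_extension(winters)
        dens = growth.annual_density(cores["density"], model)
        records = growth.growth_records(ext, dens)
        io.write_table(
            [
                {"year": r.year, "extension_mm": r.extension_mm,
                 "density_g_cm3": r.density_g_cm3,
                 "calcification_g_cm2": r.calcification_g_cm2}
                for r in records
            ],
            out / "growth.csv",
            columns=("year", "extension_mm", "density_g_cm3", "calcification_g_cm2"),
        )
        regs = growth.growth_vs_lowpass(records, annual,
                                        boundary_year=int(params["boundary_year"]))
        for var, by_period in regs.items():
            growth_summary[var] = {
                label: {
                    "r": reg.correlation.r,
                    "p": reg.correlation.p,
                    "n": reg.correlation.n,
                    "slope": reg.slope,
                    "slope_se": reg.slope_se,
                }
                for label, reg in by_period.items()
            }
        summary["growth"] = growth_summary

    # ------------------------------------------------------------------
    # stage 7: water-sample mixing
    if water_samples:
        fit = mixing.ba_salinity_fit(water_samples)
        summary["mixing"] = {
            "slope": fit.slope, "intercept": fit.intercept, "r": fit.r,
            "p": fit.p, "n": fit.n, "marine_endmember": fit.marine_endmember,
        }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return summary
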