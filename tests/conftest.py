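"""Shared fixtures: simulated cores and replicate pipeline runs.

The expensive 20-replicate chronology/peak-recovery sweep is computed once
per session and shared by the recovery tests and the acceptance suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from coralproxy import chronology as ch
from coralproxy.decomposition import decompose, mean_seasonal_cycle
from coralproxy.events import detect_high_peaks
from coralproxy.growth import annual_extension
from coralproxy.synthetic import SyntheticCoreConfig, simulate_core

N_REPLICATES = 20


@pytest.fixture(scope="session")
def default_config() -> SyntheticCoreConfig:
    return SyntheticCoreConfig()


@pytest.fixture(scope="session")
def noise_free_config() -> SyntheticCoreConfig:
    return SyntheticCoreConfig(
        extension_sigma=0.0, sst_noise_c=0.0, rsd_ba=0.0, rsd_sr=0.0, rsd_mg=0.0
    )


@pytest.fixture(scope="session")
def noise_free_core(noise_free_config):
    return simulate_core(noise_free_config, seed=0)


@dataclass
class Replicate:
    """One simulated core pushed through chronology, decomposition, peaks."""

    truth: object
    tiepoints: list
    winter_dates_ok: int = 0
    winter_dates_total: int = 0
    extension_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_extension: float = 0.0
    truth_mean_extension: float = 0.0
    peak_recall: float = 0.0


def _run_replicate(cfg: SyntheticCoreConfig, seed: int) -> Replicate:
    cores, truth = simulate_core(cfg, seed=seed)
    maxima = ch.detect_extrema(cores["sr_ca"], kind="maxima")
    minima = ch.detect_extrema(cores["sr_ca"], kind="minima")
    tps = ch.build_tiepoints(maxima, minima, sst=truth.sst,
                             collection_date=cfg.collection)
    model = ch.build_age_model(tps, cfg.collection)
    rep = Replicate(truth=truth, tiepoints=tps)

    winters = sorted((t for t in tps if t.kind == "winter"), key=lambda t: t.depth_mm)
    truth_w = sorted(truth.winter_tiepoints, key=lambda t: t.depth_mm)
    for det in winters:
        near = min(truth_w, key=lambda t: abs(t.date.ordinal - det.date.ordinal))
        rep.winter_dates_total += 1
        rep.winter_dates_ok += abs(near.date.ordinal - det.date.ordinal) <= 1

    ext = annual_extension(winters)
    errs = [
        abs(float(ext.loc[y]) - v)
        for y, v in truth.annual_extensions.items()
        if y in ext.index
    ]
    rep.extension_errors = np.asarray(errs)
    rep.mean_extension = float(ext.mean())
    rep.truth_mean_extension = float(np.mean(list(truth.annual_extensions.values())))

    ba = ch.resample_monthly(cores["ba_ca"], model, units="umol/mol")
    dec = decompose(ba)
    msc = mean_seasonal_cycle(dec.detrended)
    peaks = detect_high_peaks(dec.detrended, msc, k_sigma=3.0)
    months = [p.month for p in peaks]
    hits = sum(
        1
        for t in truth.peak_months
        if any(abs(m.ordinal - t.ordinal) <= 1 for m in months)
    )
    rep.peak_recall = hits / len(truth.peak_months)
    return rep


@pytest.fixture(scope="session")
def replicates(default_config) -> list[Replicate]:
    return [_run_replicate(default_config, seed) for seed in range(N_REPLICATES)]
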