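"""Tie-point chronology: extrema, dating, resampling, thermometry."""

import numpy as np
import pandas as pd
import pytest

from coralproxy import chronology as ch
from coralproxy.core import DepthSeries, MonthlySeries, TiePoint, period_of
from coralproxy.errors import CalibrationError, ChronologyError
from coralproxy.synthetic import SyntheticCoreConfig, simulate_core


class TestDetectExtrema:
    def test_cosine_maxima_spacing(self):
        depth = np.arange(0, 96, 0.25)
        values = np.cos(2 * np.pi * depth / 9.6)
        ds = DepthSeries(depth, values, proxy_name="sr_ca")
        maxima = ch.detect_extrema(ds, min_separation_mm=4.0, kind="maxima")
        assert np.diff(maxima) == pytest.approx(np.full(len(maxima) - 1, 9.6), abs=0.3)

    def test_monotone_ramp_has_no_extrema(self):
        depth = np.arange(0, 48, 0.25)
        ds = DepthSeries(depth, np.linspace(9.0, 10.0, len(depth)), proxy_name="sr_ca")
        with pytest.raises(ChronologyError):
            ch.detect_extrema(ds, kind="maxima")

    def test_noise_free_core_maxima_match_truth_winters(self, noise_free_core):
        cores, truth = noise_free_core
        maxima = ch.detect_extrema(cores["sr_ca"], kind="maxima")
        truth_depths = np.sort([t.depth_mm for t in truth.winter_tiepoints])
        assert len(maxima) == len(truth_depths)
        assert np.max(np.abs(maxima - truth_depths)) <= 0.25


class TestBuildTiepoints:
    def test_fixed_months_without_sst(self):
        tps = ch.build_tiepoints(
            [3.0, 12.5], [8.0], sst=None, collection_date=period_of(2014, 10))
        assert [t.date for t in tps] == [
            period_of(2014, 2), period_of(2013, 8), period_of(2013, 2)]
        assert [t.kind for t in tps] == ["winter", "summer", "winter"]

    def test_dates_strictly_decrease_with_depth(self):
        tps = ch.build_tiepoints(
            [3.0, 12.5, 22.0], [8.0, 17.0], sst=None,
            collection_date=period_of(2014, 10))
        ordinals = [t.date.ordinal for t in tps]
        assert all(b < a for a, b in zip(ordinals[:-1], ordinals[1:]))

    def test_extrema_beyond_instrumental_span_rejected(self):
        # SST covers two winters but an explicit instrumental start claims
        # the whole record is instrumental: the third maximum cannot be dated
        sst = MonthlySeries.from_start(
            period_of(2012, 6),
            25 - 3.8 * np.cos(2 * np.pi * (np.arange(29) % 12 + 6 - 8) / 12),
        )
        with pytest.raises(ChronologyError):
            ch.build_tiepoints(
                [3.0, 12.5, 22.0], [8.0, 17.0], sst=sst,
                instrumental_start=period_of(1960, 1),
                collection_date=period_of(2014, 10))

    def test_noise_free_dates_match_truth_exactly(self, noise_free_core, noise_free_config):
        cores, truth = noise_free_core
        maxima = ch.detect_extrema(cores["sr_ca"], kind="maxima")
        minima = ch.detect_extrema(cores["sr_ca"], kind="minima")
        tps = ch.build_tiepoints(maxima, minima, sst=truth.sst,
                                 collection_date=noise_free_config.collection)
        det = sorted((t for t in tps if t.kind == "winter"), key=lambda t: t.depth_mm)
        tru = sorted(truth.winter_tiepoints, key=lambda t: t.depth_mm)
        assert [t.date for t in det] == [t.date for t in tru]


class TestResampleMonthly:
    def _uniform_model(self):
        tps = [
            TiePoint(0.0, period_of(2014, 2), "winter"),
            TiePoint(96.0, period_of(2004, 2), "winter"),
        ]
        return ch.build_age_model(tps, period_of(2014, 10))

    def test_linear_profile_gives_linear_series(self):
        model = self._uniform_model()
        depth = np.arange(0, 96.25, 0.25)
        ds = DepthSeries(depth, 2.0 + 0.05 * depth, proxy_name="ba_ca")
        monthly = ch.resample_monthly(ds, model)
        diffs = np.diff(monthly.values)
        assert diffs == pytest.approx(np.full(len(diffs), diffs[0]), abs=1e-9)

    def test_constant_profile_gives_constant_series(self):
        model = self._uniform_model()
        depth = np.arange(0, 96.25, 0.25)
        ds = DepthSeries(depth, np.full(len(depth), 3.8), proxy_name="ba_ca")
        monthly = ch.resample_monthly(ds, model)
        assert np.ptp(monthly.values) == pytest.approx(0.0, abs=1e-12)

    def test_no_overshoot_beyond_sample_range(self, noise_free_core):
        cores, truth = noise_free_core
        model = ch.build_age_model(
            truth.winter_tiepoints + truth.summer_tiepoints,
            period_of(2014, 10))
        monthly = ch.resample_monthly(cores["ba_ca"], model)
        assert monthly.values.max() <= cores["ba_ca"].values.max() + 1e-12
        assert monthly.values.min() >= cores["ba_ca"].values.min() - 1e-12

    def test_smooth_forcing_recovered_within_two_percent_of_seasonal_amplitude(self):
        # spike-free forcing is smooth, so the depth->month->depth round trip
        # must reproduce it almost exactly
        cfg = SyntheticCoreConfig(
            extension_sigma=0.0, sst_noise_c=0.0,
            rsd_ba=0.0, rsd_sr=0.0, rsd_mg=0.0, spike_events=())
        cores, truth = simulate_core(cfg, seed=0)
        # the exact tie points isolate the resampling error itself
        model = ch.build_age_model(
            truth.winter_tiepoints + truth.summer_tiepoints, cfg.collection)
        monthly = ch.resample_monthly(cores["ba_ca"], model)
        got, want = monthly.overlap(truth.ba_forcing)
        err = np.max(np.abs(got.values - want.values))
        assert err < 0.02 * cfg.ba_seasonal_amplitude


class TestThermometry:
    def _sst(self, n=396, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        months = np.arange(n)
        vals = 25 + 3.8 * np.cos(2 * np.pi * (months % 12 + 1 - 8) / 12)
        return MonthlySeries.from_start(
            period_of(1981, 11), vals + rng.normal(0, noise, n), units="degC")

    def test_exact_linear_calibration(self):
        sst = self._sst()
        proxy = MonthlySeries(pd.Series(10.0 - 0.06 * sst.values, index=sst.index))
        cal = ch.calibrate_sst_proxy(proxy, sst)
        assert cal.slope == pytest.approx(-0.06, abs=1e-12)
        assert cal.intercept == pytest.approx(10.0, abs=1e-10)
        assert cal.r == pytest.approx(-1.0)

    def test_uncorrelated_proxy_has_small_r(self):
        sst = self._sst()
        rng = np.random.default_rng(99)
        proxy = MonthlySeries(pd.Series(rng.normal(9, 0.1, len(sst)), index=sst.index))
        cal = ch.calibrate_sst_proxy(proxy, sst)
        assert abs(cal.r) < 0.3
        assert cal.n == 396

    def test_short_overlap_rejected(self):
        sst = self._sst(n=12)
        proxy = MonthlySeries(pd.Series(10 - 0.06 * sst.values, index=sst.index))
        with pytest.raises(CalibrationError):
            ch.calibrate_sst_proxy(proxy, sst)

    def test_reconstruct_inverts_calibration(self):
        sst = self._sst(noise=0.3)
        proxy = MonthlySeries(pd.Series(10.0 - 0.06 * sst.values, index=sst.index))
        cal = ch.calibrate_sst_proxy(proxy, sst)
        recon = ch.reconstruct_sst(proxy, cal)
        assert recon.values == pytest.approx(sst.values, abs=1e-8)

    def test_reconstruct_simple_arithmetic(self):
        cal = ch.ProxyCalibration(slope=-0.06, intercept=10.0, r=-1.0, n=100)
        assert cal.invert(8.8) == pytest.approx(20.0)

    def test_delta_srca_zero_when_proxy_matches_prediction(self):
        sst = self._sst()
        cal = ch.ProxyCalibration(slope=-0.06, intercept=10.0, r=-1.0, n=len(sst))
        proxy = MonthlySeries(pd.Series(cal.predict(sst.values), index=sst.index))
        delta = ch.delta_srca(proxy, cal, sst)
        assert delta.values == pytest.approx(np.zeros(len(sst)), abs=1e-12)

    def test_delta_srca_flags_offset_months(self):
        sst = self._sst()
        cal = ch.ProxyCalibration(slope=-0.06, intercept=10.0, r=-1.0, n=len(sst))
        vals = cal.predict(sst.values)
        vals[100:103] += 0.1  # growth-disturbance anomaly
        proxy = MonthlySeries(pd.Series(vals, index=sst.index))
        delta = ch.delta_srca(proxy, cal, sst)
        top = np.argsort(np.abs(delta.values))[-3:]
        assert sorted(top) == [100, 101, 102]
        assert delta.values[100] == pytest.approx(0.1)


class TestChronologyRecoveryWithNoise:
    def test_tie_dates_within_one_month(self, replicates):
        ok = sum(r.winter_dates_ok for r in replicates)
        tot = sum(r.winter_dates_total for r in replicates)
        assert ok / tot >= 0.95
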