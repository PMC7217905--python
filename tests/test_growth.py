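"""Annual extension, density, calcification, and growth-forcing regression."""

import numpy as np
import pandas as pd
import pytest

from coralproxy.core import DepthSeries, TiePoint, period_of
from coralproxy.errors import ChronologyError, DegenerateDataError
from coralproxy.growth import (
    AnnualGrowthRecord,
    annual_density,
    annual_extension,
    calcification_rate,
    growth_records,
    growth_vs_lowpass,
)
from coralproxy import chronology as ch


def winter(depth, year):
    return TiePoint(depth, period_of(year, 2), "winter")


class TestAnnualExtension:
    def test_uniform_spacing(self):
        tps = [winter(0.0, 2014), winter(9.6, 2013), winter(19.2, 2012)]
        ext = annual_extension(tps)
        assert list(ext.index) == [2012, 2013]
        assert ext.to_numpy() == pytest.approx([9.6, 9.6])

    def test_year_attribution(self):
        # the interval between winter Y and winter Y+1 is labelled Y
        tps = [winter(0.0, 2014), winter(8.0, 2013)]
        ext = annual_extension(tps)
        assert list(ext.index) == [2013]
        assert ext.loc[2013] == pytest.approx(8.0)

    def test_inconsistent_depth_order_rejected(self):
        tps = [winter(9.6, 2014), winter(0.0, 2013)]
        with pytest.raises(ChronologyError):
            annual_extension(tps)

    def test_noise_free_core_extensions_match_truth(self, noise_free_core,
                                                    noise_free_config):
        cores, truth = noise_free_core
        maxima = ch.detect_extrema(cores["sr_ca"], kind="maxima")
        minima = ch.detect_extrema(cores["sr_ca"], kind="minima")
        tps = ch.build_tiepoints(maxima, minima, sst=truth.sst,
                                 collection_date=noise_free_config.collection)
        ext = annual_extension([t for t in tps if t.kind == "winter"])
        for year, true_ext in truth.annual_extensions.items():
            assert abs(float(ext.loc[year]) - true_ext) <= 0.25

    def test_mean_extension_recovered_within_two_percent(self, replicates):
        for rep in replicates:
            assert abs(rep.mean_extension / rep.truth_mean_extension - 1) < 0.02

    def test_extension_sum_equals_winter_span(self, replicates):
        rep = replicates[0]
        winters = sorted((t for t in rep.tiepoints if t.kind == "winter"),
                         key=lambda t: t.depth_mm)
        ext = annual_extension(winters)
        span = winters[-1].depth_mm - winters[0].depth_mm
        assert float(ext.sum()) == pytest.approx(span, abs=1e-9)


class TestAnnualDensity:
    def _model(self):
        return ch.build_age_model(
            [winter(0.0, 2014), winter(96.0, 2004)], period_of(2014, 10))

    def test_constant_profile(self):
        depth = np.arange(0, 96.25, 0.25)
        ds = DepthSeries(depth, np.full(len(depth), 1.3), proxy_name="density")
        dens = annual_density(ds, self._model())
        assert np.all(dens.to_numpy() == pytest.approx(1.3))

    def test_sinusoidal_profile_annual_mean_near_profile_mean(self):
        depth = np.arange(0, 96.25, 0.25)
        ds = DepthSeries(
            depth, 1.25 + 0.08 * np.sin(2 * np.pi * depth / 9.6),
            proxy_name="density")
        dens = annual_density(ds, self._model())
        assert dens.to_numpy() == pytest.approx(np.full(len(dens), 1.25), rel=0.01)

    def test_partial_years_omitted(self):
        depth = np.arange(0, 50.25, 0.25)  # covers only ~5 of the 10 model years
        ds = DepthSeries(depth, np.full(len(depth), 1.3), proxy_name="density")
        dens = annual_density(ds, self._model())
        assert 2004 not in dens.index
        assert len(dens) < 10


class TestCalcification:
    def test_unit_arithmetic(self):
        ext = pd.Series([10.0], index=[2000])
        dens = pd.Series([1.2], index=[2000])
        assert calcification_rate(ext, dens).loc[2000] == pytest.approx(1.2)

    def test_typical_values(self):
        ext = pd.Series([9.6], index=[2000])
        dens = pd.Series([1.25], index=[2000])
        assert calcification_rate(ext, dens).loc[2000] == pytest.approx(1.2)

    def test_zero_extension_rejected(self):
        ext = pd.Series([0.0], index=[2000])
        dens = pd.Series([1.2], index=[2000])
        with pytest.raises(DegenerateDataError):
            calcification_rate(ext, dens)

    def test_identity_on_records(self):
        rng = np.random.default_rng(3)
        years = np.arange(2000, 2020)
        ext = pd.Series(rng.uniform(6, 12, 20), index=years)
        dens = pd.Series(rng.uniform(1.0, 1.5, 20), index=years)
        for rec in growth_records(ext, dens):
            assert rec.calcification_g_cm2 / rec.density_g_cm3 * 10 == pytest.approx(
                rec.extension_mm, abs=1e-12)


class TestGrowthVsLowpass:
    def _records_from_calc(self, years, calc, density=1.25):
        return [
            AnnualGrowthRecord(int(y), float(c * 10 / density), density, float(c))
            for y, c in zip(years, calc)
        ]

    def test_exact_linear_response(self):
        years = np.arange(1970, 2010)
        rng = np.random.default_rng(0)
        ba = 3.8 + rng.normal(0, 0.2, len(years))
        calc = 2.4 - 0.3 * ba
        recs = self._records_from_calc(years, calc)
        regs = growth_vs_lowpass(recs, pd.Series(ba, index=years), boundary_year=1996)
        for label in ("A", "B"):
            reg = regs["calcification"][label]
            assert reg.slope == pytest.approx(-0.3, abs=1e-10)
            assert reg.correlation.r == pytest.approx(-1.0)

    def test_noisy_linear_response_slope_within_two_se(self):
        from coralproxy.decomposition import annual_means, decompose
        from coralproxy.synthetic import SyntheticCoreConfig, simulate_environment

        cfg = SyntheticCoreConfig()
        _, forcing, _ = simulate_environment(cfg, seed=11)
        ann = annual_means(decompose(forcing).lowpass)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            signal = -0.3 * (ann.to_numpy() - ann.mean())
            calc = 1.2 + signal + rng.normal(0, np.std(signal) / 2, len(ann))
            recs = self._records_from_calc(ann.index, calc)
            regs = growth_vs_lowpass(recs, ann)
            ok += all(
                abs(reg.slope - (-0.3)) <= 2 * reg.slope_se
                for reg in regs["calcification"].values()
            )
        assert ok >= 18

    def test_independent_growth_and_forcing_mostly_uncorrelated(self):
        years = np.arange(1969, 1996)  # 27 years, like period A
        small_r = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            ba = 3.8 + rng.normal(0, 0.2, len(years))
            calc = 1.2 + rng.normal(0, 0.1, len(years))
            recs = self._records_from_calc(years, calc)
            regs = growth_vs_lowpass(recs, pd.Series(ba, index=years),
                                     boundary_year=1996)
            small_r += abs(regs["calcification"]["A"].correlation.r) < 0.5
        assert small_r >= 18

    def test_short_period_skipped(self):
        years = np.arange(1994, 1998)
        rng = np.random.default_rng(1)
        ba = 3.8 + rng.normal(0, 0.2, len(years))
        recs = self._records_from_calc(years, 1.2 + rng.normal(0, 0.1, len(years)))
        regs = growth_vs_lowpass(recs, pd.Series(ba, index=years), boundary_year=1996)
        assert "A" not in regs["calcification"]  # only 2 years before 1996
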