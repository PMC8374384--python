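"""Breath editing, interpolation, binning, maximal values, stage averages."""

import numpy as np
import pandas as pd
import pytest

from trainability import gas_exchange as gx
from trainability import synthetic
from trainability.incremental_test import StepProtocol


def make_series(vo2, time=None, hr=None):
    vo2 = np.asarray(vo2, dtype=float)
    t = np.arange(vo2.size, dtype=float) * 2.5 if time is None else np.asarray(time, float)
    return gx.BreathSeries(
        time=t, vo2=vo2, vco2=0.9 * vo2, ve=vo2 / 80.0, hr=hr
    )


def oracle_outlier_flags(vo2, window, mult):
    """Brute-force windowed mean/SD outlier check (independent of the
    implementation's vectorization/edge choices only in style)."""
    flags = []
    half = window // 2
    for i in range(len(vo2)):
        neigh = [vo2[j] for j in range(max(0, i - half), min(len(vo2), i + half + 1)) if j != i]
        mu = np.mean(neigh)
        thr = mult * np.std(neigh, ddof=1)
        flags.append(bool(np.isfinite(thr) and abs(vo2[i] - mu) > thr))
    return np.array(flags)


class TestCleanBreaths:
    def test_spike_removed_others_kept(self):
        vo2 = np.full(101, 2000.0)
        vo2[50] = 5000.0
        cleaned = gx.clean_breaths(make_series(vo2), window_breaths=30, sd_multiplier=2.0)
        assert len(cleaned) == 100
        assert np.all(cleaned.vo2 == 2000.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        vo2 = 2000 + rng.normal(0, 80, 200)
        vo2[[20, 90, 150]] += [500, -450, 600]
        flags = oracle_outlier_flags(vo2, 30, 2.0)
        cleaned = gx.clean_breaths(make_series(vo2), 30, 2.0)
        np.testing.assert_array_equal(cleaned.vo2, vo2[~flags])

    @pytest.mark.parametrize("mult", [2.0, np.inf])
    def test_identical_values_unchanged(self, mult):
        s = make_series(np.full(60, 1800.0))
        out = gx.clean_breaths(s, 30, mult)
        np.testing.assert_array_equal(out.vo2, s.vo2)

    def test_infinite_multiplier_keeps_everything(self, rng):
        vo2 = 2000 + rng.normal(0, 300, 80)
        out = gx.clean_breaths(make_series(vo2), 30, np.inf)
        assert len(out) == 80

    def test_short_series_errors(self):
        with pytest.raises(ValueError, match="fewer than"):
            gx.clean_breaths(make_series(np.full(10, 2000.0)), window_breaths=30)

    def test_idempotent_when_scatter_below_threshold(self, profile):
        """Cleaning is idempotent once no breath exceeds the local
        threshold: spike-contaminated but otherwise smooth data cleans
        to a fixed point in one pass.  (On broadband Gaussian scatter a
        2-SD rule re-flags the tails of each freshly truncated
        distribution, so exact idempotence cannot hold there.)"""
        series = synthetic.gen_breath_series(profile, seed=0, noise_sd=0.0, spike_rate=0.0)
        vo2 = series.vo2.copy()
        vo2[[60, 200, 340]] += [900.0, -700.0, 800.0]
        spiked = gx.BreathSeries(series.time, vo2, series.vco2, series.ve, series.hr)
        once = gx.clean_breaths(spiked, 30, 5.0)
        twice = gx.clean_breaths(once, 30, 5.0)
        np.testing.assert_array_equal(once.vo2, twice.vo2)
        assert len(once) == len(spiked) - 3


class TestInterpolate:
    def test_linear_midpoint(self):
        s = gx.BreathSeries(time=[0.0, 2.0], vo2=[100, 200], vco2=[90, 180], ve=[3, 6])
        out = gx.interpolate_1s(s)
        assert out["vo2"][1] == pytest.approx(150.0)
        assert out["vo2"][0] == 100.0 and out["vo2"][-1] == 200.0

    def test_identity_on_1hz_input(self):
        t = np.arange(20.0)
        vo2 = 1000 + 10 * t
        s = gx.BreathSeries(time=t, vo2=vo2, vco2=vo2 * 0.9, ve=vo2 / 80)
        out = gx.interpolate_1s(s)
        np.testing.assert_allclose(out["vo2"], vo2)
        assert out.step == 1.0

    def test_constant_series(self):
        s = gx.BreathSeries(time=[0.0, 4.0], vo2=[100, 100], vco2=[90, 90], ve=[3, 3])
        np.testing.assert_array_equal(gx.interpolate_1s(s)["vo2"], np.full(5, 100.0))

    def test_single_record_errors(self):
        s = gx.BreathSeries(time=[0.0], vo2=[100], vco2=[90], ve=[3])
        with pytest.raises(ValueError):
            gx.interpolate_1s(s)


def uniform(vo2, step=1.0, start=0.0):
    return gx.UniformSeries(start_time=start, step=step, channels={"vo2": np.asarray(vo2, float)})


class TestBinAverage:
    def test_constant_two_bins(self):
        out = gx.bin_average(uniform(np.full(60, 2000.0)), 30)
        np.testing.assert_array_equal(out["vo2"], [2000.0, 2000.0])
        assert out.step == 30.0

    def test_ramp_mean(self):
        out = gx.bin_average(uniform(np.arange(1.0, 31.0)), 30)
        assert out["vo2"][0] == pytest.approx(15.5)

    def test_partial_trailing_bin_kept(self):
        out = gx.bin_average(uniform(np.full(45, 2000.0)), 30)
        np.testing.assert_array_equal(out["vo2"], [2000.0, 2000.0])

    def test_bin1_is_identity(self, profile):
        series = synthetic.gen_breath_series(profile, seed=3)
        interp = gx.interpolate_1s(series)
        out = gx.bin_average(interp, 1)
        np.testing.assert_allclose(out["vo2"], interp["vo2"])

    def test_requires_1s_series(self):
        with pytest.raises(ValueError):
            gx.bin_average(uniform([1.0, 2.0], step=5.0), 30)


class TestVo2max:
    @pytest.mark.parametrize(
        "bins, expected",
        [([1800, 2400, 2300], 2400.0), ([2000, 2000], 2000.0), ([1500], 1500.0)],
    )
    def test_examples(self, bins, expected):
        assert gx.vo2max_from_bins(uniform(bins, step=30.0)) == expected

    def test_max_at_least_mean(self, rng):
        vals = 2000 + rng.normal(0, 100, 40)
        s = uniform(vals, step=30.0)
        assert gx.vo2max_from_bins(s) >= float(np.mean(vals))

    def test_plateau_recovered_within_noise(self, profile):
        """Known plateau recovered within breath-noise SD/sqrt(30)."""
        errs = []
        for seed in range(10):
            series = synthetic.gen_breath_series(profile, seed=seed)
            bins = gx.bin_average(gx.interpolate_1s(gx.clean_breaths(series)), 30)
            errs.append(gx.vo2max_from_bins(bins) - profile.vo2max_true)
        assert np.mean(np.abs(errs)) < 3 * 80.0 / np.sqrt(30)


class TestAttainment:
    def test_all_three_met(self):
        mv = gx.MaximalValues(vo2max=2280, hr_max=195, rer_max=1.26, po_peak=190, la_max=9.4)
        rep = gx.check_attainment(mv, age=30)
        assert rep.hr_criterion and rep.rer_criterion and rep.lactate_criterion
        assert rep.attained

    def test_none_met(self):
        mv = gx.MaximalValues(vo2max=2280, hr_max=150, rer_max=1.05, po_peak=190, la_max=5.0)
        assert not gx.check_attainment(mv, age=30).attained

    def test_two_of_three_suffice(self):
        mv = gx.MaximalValues(vo2max=2280, hr_max=150, rer_max=1.20, po_peak=190, la_max=9.0)
        rep = gx.check_attainment(mv, age=30)
        assert not rep.hr_criterion and rep.rer_criterion and rep.lactate_criterion
        assert rep.attained

    def test_missing_lactate_fails_criterion_quietly(self):
        mv = gx.MaximalValues(vo2max=2280, hr_max=195, rer_max=1.26, po_peak=190, la_max=None)
        rep = gx.check_attainment(mv, age=30)
        assert not rep.lactate_criterion and rep.attained

    def test_symmetric_reading_rejects_overshoot(self):
        mv = gx.MaximalValues(vo2max=2280, hr_max=205, rer_max=1.0, po_peak=190)
        assert gx.check_attainment(mv, age=30).hr_criterion
        assert not gx.check_attainment(mv, age=30, symmetric_hr=True).hr_criterion


class TestStageEndAverages:
    def test_constant_stage(self, protocol):
        n = int(protocol.stage_end(2))
        s = uniform(np.full(n, 2000.0))
        df = gx.stage_end_averages(s, protocol)
        assert list(df["power_w"]) == [50.0, 75.0]
        assert np.all(df["vo2"] == 2000.0)

    def test_ramp_oracle_enumeration(self, protocol):
        """Half-open [end-30, end) window: direct enumeration oracle."""
        n = int(protocol.stage_end(1))
        t = np.arange(n, dtype=float)
        vo2 = 1000.0 + t  # linear ramp
        df = gx.stage_end_averages(uniform(vo2), protocol)
        end = protocol.stage_end(1)
        expected = np.mean([1000.0 + s for s in range(int(end) - 30, int(end))])
        assert df["vo2"][0] == pytest.approx(expected)

    def test_two_stages_distinct_constants(self, protocol):
        n1 = int(protocol.stage_end(1))
        n2 = int(protocol.stage_end(2))
        vo2 = np.concatenate([np.full(n1, 1500.0), np.full(n2 - n1, 1900.0)])
        df = gx.stage_end_averages(uniform(vo2), protocol)
        assert list(df["vo2"]) == [1500.0, 1900.0]

    def test_short_stage_errors(self):
        proto = StepProtocol(stage_duration=20.0)
        with pytest.raises(ValueError, match="shorter"):
            gx.stage_end_averages(uniform(np.full(200, 1000.0)), proto)
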