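"""Peak power, segmented lactate regression, slopes, prescriptions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trainability import incremental_test as it
from trainability import synthetic


def spec_curve(noise_sd=0.0, seed=0):
    """Three-segment curve: flat at 1.0 to 100 W, +0.02/W to 175 W,
    +0.15/W above; sampled every 25 W from 25 to 250."""
    rng = np.random.default_rng(seed)
    p = np.arange(25.0, 251.0, 25.0)
    la = 1.0 + 0.02 * np.maximum(p - 100, 0) + 0.13 * np.maximum(p - 175, 0)
    la = la + rng.normal(0, noise_sd, p.size)
    return it.LactateCurve(power=p, lactate=np.maximum(la, 0.05))


def bruteforce_fit(curve, lattice_w=1.0, min_gap=None):
    """Per-candidate lstsq over the same lattice: the independent oracle."""
    p, y = curve.power, curve.lactate
    if min_gap is None:
        min_gap = float(np.min(np.diff(p[1:])))
    grid = np.arange(p[1] + lattice_w, p[-2] + 0.5 * lattice_w, lattice_w)
    best = None
    for b1 in grid:
        for b2 in grid:
            if b2 - b1 < min_gap - 1e-9:
                continue
            X = np.column_stack(
                [np.ones_like(p), p, np.maximum(p - b1, 0), np.maximum(p - b2, 0)]
            )
            c, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((X @ c - y) ** 2))
            key = (round(rss, 12), b1, b2)
            if best is None or key < best[0]:
                best = (key, b1, b2)
    return best[1], best[2]


class TestPoPeak:
    @pytest.mark.parametrize(
        "t_in, expected", [(90.0, 162.5), (180.0, 175.0), (0.0, 150.0)]
    )
    def test_linearization(self, protocol, t_in, expected):
        assert it.po_peak(protocol, t_in, 150.0) == pytest.approx(expected)

    def test_negative_time_errors(self, protocol):
        with pytest.raises(ValueError):
            it.po_peak(protocol, -1.0, 150.0)

    @given(st.floats(0, 180), st.floats(0, 180))
    def test_monotone_in_time(self, t1, t2):
        proto = it.StepProtocol()
        lo, hi = sorted([t1, t2])
        assert it.po_peak(proto, lo, 150.0) <= it.po_peak(proto, hi, 150.0)


class TestLactateBreakpoints:
    def test_noise_free_recovery(self):
        thr = it.fit_lactate_breakpoints(spec_curve())
        assert abs(thr.ltp1_po - 100.0) <= 2.0
        assert abs(thr.ltp2_po - 175.0) <= 2.0
        assert thr.rss == pytest.approx(0.0, abs=1e-12)

    def test_segment_slopes_recovered(self):
        thr = it.fit_lactate_breakpoints(spec_curve())
        assert thr.slopes[0] == pytest.approx(0.0, abs=1e-9)
        assert thr.slopes[1] == pytest.approx(0.02, abs=1e-9)
        assert thr.slopes[2] == pytest.approx(0.15, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        curve = spec_curve(noise_sd=0.15, seed=seed)
        thr = it.fit_lactate_breakpoints(curve, lattice_w=5.0)
        b1, b2 = bruteforce_fit(curve, lattice_w=5.0)
        assert thr.ltp1_po == pytest.approx(b1)
        assert thr.ltp2_po == pytest.approx(b2)

    @pytest.mark.parametrize("seed", range(4))
    def test_continuity_at_breakpoints(self, seed):
        thr = it.fit_lactate_breakpoints(spec_curve(noise_sd=0.1, seed=seed))
        for b in (thr.ltp1_po, thr.ltp2_po):
            left = thr.predict(b - 1e-9)
            right = thr.predict(b + 1e-9)
            assert abs(float(left) - float(right)) < 1e-6

    def test_noisy_mean_recovery(self):
        """Gaussian noise SD 0.1: mean recovered breakpoints near truth."""
        b1s, b2s = [], []
        for seed in range(30):
            thr = it.fit_lactate_breakpoints(spec_curve(noise_sd=0.1, seed=seed))
            b1s.append(thr.ltp1_po)
            b2s.append(thr.ltp2_po)
        assert abs(np.mean(b1s) - 100.0) < 10.0
        assert abs(np.mean(b2s) - 175.0) < 10.0

    def test_straight_line_errors(self):
        p = np.arange(25.0, 251.0, 25.0)
        curve = it.LactateCurve(power=p, lactate=1.0 + 0.02 * p)
        with pytest.raises(it.NoBreakpointError):
            it.fit_lactate_breakpoints(curve)

    def test_flat_curve_errors(self):
        p = np.arange(25.0, 251.0, 25.0)
        with pytest.raises(it.NoBreakpointError):
            it.fit_lactate_breakpoints(it.LactateCurve(p, np.full(p.size, 1.0)))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="6"):
            it.fit_lactate_breakpoints(
                it.LactateCurve([0.0, 50, 100, 150, 200], [1, 1, 1.5, 3, 6])
            )

    def test_generator_truth_recovered(self):
        """Noise-free generator curves: truth recovered for varied subjects."""
        for k, (sex, vo2) in enumerate([("M", 2600.0), ("F", 2000.0), ("F", 1700.0)]):
            prof = synthetic.gen_profile(f"S{k}", sex, 30.0, vo2, seed=k)
            curve = synthetic.gen_lactate_curve(prof, noise_sd=0.0)
            thr = it.fit_lactate_breakpoints(curve)
            assert thr.ltp1_po == pytest.approx(prof.ltp1_w, abs=1.0)
            assert thr.ltp2_po == pytest.approx(prof.ltp2_w, abs=1.0)


class TestSlopesAndMapping:
    def test_map_exact_line(self):
        pairs = [(p, 10.0 * p + 500.0) for p in (50, 75, 100, 125)]
        assert it.map_po_to_vo2(pairs, 150.0) == pytest.approx(2000.0)
        assert it.map_po_to_vo2(pairs, 100.0) == pytest.approx(1500.0)

    def test_map_two_points(self):
        assert it.map_po_to_vo2([(100, 1450.0), (125, 1687.5)], 150.0) == pytest.approx(1925.0)

    def test_oues_exact(self):
        ve = np.linspace(20, 100, 40)
        vo2 = 1500 * np.log10(ve) + 200
        a, b = it.oues(vo2, ve)
        assert a == pytest.approx(1500.0)
        assert b == pytest.approx(200.0)

    def test_oues_constant_ve_errors(self):
        with pytest.raises(ValueError):
            it.oues([1000.0, 1100.0], [50.0, 50.0])

    def test_oues_log_scaling_identity(self):
        ve = np.linspace(20, 100, 40)
        vo2 = 1500 * np.log10(ve) + 200
        a1, b1 = it.oues(vo2, ve)
        a2, b2 = it.oues(vo2, 10 * ve)
        assert a2 == pytest.approx(a1)
        assert b2 == pytest.approx(b1 - a1)

    def test_vo2_po_slope(self):
        pairs = [(p, 9.5 * p + 450.0) for p in (50, 75, 100, 125, 150)]
        slope, _ = it.vo2_po_slope(pairs)
        assert slope == pytest.approx(9.5)
        shifted = [(p, v + 300.0) for p, v in pairs]
        assert it.vo2_po_slope(shifted)[0] == pytest.approx(9.5)

    def test_vo2_po_two_points(self):
        assert it.vo2_po_slope([(100, 1450.0), (125, 1687.5)])[0] == pytest.approx(9.5)

    def test_hr_vo2_slope(self):
        vo2_ml = np.array([1000.0, 1500, 2000, 2500])
        hr = 30.0 * vo2_ml / 1000.0 + 60.0
        pairs = np.column_stack([vo2_ml, hr])
        assert it.hr_vo2_slope(pairs)[0] == pytest.approx(30.0)
        assert it.hr_vo2_slope(pairs[::-1])[0] == pytest.approx(30.0)

    def test_hr_vo2_constant_hr(self):
        pairs = np.column_stack([[1000.0, 2000.0, 3000.0], [150.0, 150.0, 150.0]])
        assert it.hr_vo2_slope(pairs)[0] == pytest.approx(0.0)


class TestPrescriptions:
    def hiit(self):
        pw = np.array([50.0, 75, 100, 125])
        return it.prescribe_hiit(np.column_stack([pw, 0.5 * pw + 60.0]), 200.0)

    def test_interval_and_warmup_powers(self):
        rx = self.hiit()
        assert rx.interval_power == pytest.approx(240.0)
        assert rx.warmup_power == pytest.approx(160.0)

    def test_total_duration_43_min(self):
        assert self.hiit().total_duration_s == pytest.approx(43 * 60.0)

    def test_non_positive_slope_errors(self):
        pw = np.array([50.0, 75, 100])
        with pytest.raises(ValueError):
            it.prescribe_hiit(np.column_stack([pw, 150.0 - 0.1 * pw]), 200.0)

    def test_interval_windows_structure(self):
        wins = self.hiit().interval_windows()
        assert wins[0] == (600.0, 840.0)
        assert len(wins) == 4
        assert wins[-1][1] == 600 + 4 * 240 + 3 * 240

    @pytest.mark.parametrize("ltp1, power", [(120.0, 108.0), (100.0, 90.0)])
    def test_mict_power(self, ltp1, power):
        rx = it.prescribe_mict(ltp1)
        assert rx.mict_power == pytest.approx(power)
        assert rx.total_duration_s == 3600.0
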