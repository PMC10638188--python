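"""Gas-exchange preprocessing: Haldane, energy conversion, smoothing,
gap filling, trimming and power smoothing."""

import numpy as np
import pytest

from bioen.preprocessing import (fill_gaps, haldane_inspiratory,
                                 mr_ae_from_gas, preprocess_trial,
                                 smooth_lowess, smooth_power, trim_resample)


class TestHaldane:
    def test_identical_composition_is_identity(self):
        vi = haldane_inspiratory(80.0, fio2=0.2093, fico2=0.0004,
                                 feo2=0.2093, feco2=0.0004)
        assert vi == pytest.approx(80.0)

    def test_worked_example(self):
        vi = haldane_inspiratory(100.0, fio2=0.2093, fico2=0.0004,
                                 feo2=0.16, feco2=0.05)
        assert vi == pytest.approx(100.0 * 0.79 / 0.7903, abs=1e-3)

    def test_oxygen_uptake_positive_for_physiological_breaths(self):
        # expired CO2 below the absorbed O2 (RQ <= 1) guarantees VO2 > 0
        rng = np.random.default_rng(2)
        for _ in range(200):
            feo2 = rng.uniform(0.12, 0.205)
            feco2 = rng.uniform(0.7, 1.0) * (0.2093 - feo2)
            ve = rng.uniform(20.0, 180.0)
            vi = haldane_inspiratory(ve, feo2=feo2, feco2=feco2)
            assert 0.2093 * vi - feo2 * ve > 0.0

    def test_nonphysical_fractions_rejected(self):
        with pytest.raises(ValueError):
            haldane_inspiratory(100.0, feo2=1.2, feco2=0.05)


class TestMrAeFromGas:
    @pytest.mark.parametrize("vo2, rq, expected", [
        (0.0, 0.8, 0.0),
        (1.0, 1.0, (1.232 + 3.8149) * 4184 / 60),
        (4.0, 0.85, (1.232 * 0.85 + 3.8149) * 4.0 * 4184 / 60),
    ])
    def test_caloric_equivalent_line(self, vo2, rq, expected):
        assert mr_ae_from_gas(vo2, rq) == pytest.approx(expected)

    def test_linear_in_vo2_affine_in_rq(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v, r, a = rng.uniform(0.5, 5.0), rng.uniform(0.7, 1.3), \
                rng.uniform(0.5, 2.0)
            assert mr_ae_from_gas(a * v, r) == pytest.approx(
                a * mr_ae_from_gas(v, r), rel=1e-12)
        # affine in rq: second difference vanishes
        y1, y2, y3 = (mr_ae_from_gas(2.0, r) for r in (0.8, 0.9, 1.0))
        assert y3 - 2 * y2 + y1 == pytest.approx(0.0, abs=1e-9)

    def test_unphysiological_rq_warns(self):
        with pytest.warns(UserWarning):
            mr_ae_from_gas(1.0, 1.5)


class TestLowess:
    def test_reproduces_constants_exactly(self):
        t = np.sort(np.random.default_rng(4).uniform(0, 300, 150))
        out = smooth_lowess(t, np.full(t.size, 7.5))
        assert np.allclose(out, 7.5, atol=1e-10)

    def test_reproduces_lines_exactly(self):
        t = np.sort(np.random.default_rng(5).uniform(0, 300, 150))
        v = 0.3 * t - 12.0
        assert np.allclose(smooth_lowess(t, v), v, atol=1e-8)

    def test_noise_reduction_away_from_step(self):
        rng = np.random.default_rng(6)
        t = np.arange(0.0, 600.0, 1.5)
        clean = np.where(t < 300.0, 100.0, 300.0)
        noisy = clean + rng.normal(0.0, 20.0, t.size)
        sm = smooth_lowess(t, noisy)
        away = np.abs(t - 300.0) > 40.0
        sd_in = np.std(noisy[away] - clean[away])
        sd_out = np.std(sm[away] - clean[away])
        assert sd_out <= 0.5 * sd_in

    def test_double_smoothing_nearly_idempotent(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 400.0, 2.0)
        v = 200 + 50 * np.sin(t / 80.0) + rng.normal(0, 5, t.size)
        once = smooth_lowess(t, v)
        twice = smooth_lowess(t, once)
        assert np.abs(twice - once).max() < 0.01 * np.ptp(v)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            smooth_lowess(np.arange(5.0), np.arange(5.0))


class TestFillGaps:
    def test_constant_series_filled_with_constant(self):
        v = np.full(100, 5.0)
        v[40:50] = np.nan
        out = fill_gaps(v)
        assert np.allclose(out, 5.0)

    def test_sinusoid_reconstruction(self):
        t = np.arange(0.0, 400.0, 1.0)
        v = np.sin(2 * np.pi * t / 200.0)  # period much longer than the gap
        masked = v.copy()
        masked[180:205] = np.nan
        out = fill_gaps(masked, t=t)
        assert np.abs(out[180:205] - v[180:205]).max() < 0.05

    def test_no_gaps_returns_identical_values(self):
        v = np.random.default_rng(8).normal(size=50)
        assert np.array_equal(fill_gaps(v), v)

    def test_oversized_gap_warns_but_fills(self):
        v = np.full(200, 3.0)
        v[50:100] = np.nan  # 49 s gap at 1 Hz
        with pytest.warns(UserWarning):
            out = fill_gaps(v, t=np.arange(200.0))
        assert np.isfinite(out).all()


class TestTrimResample:
    def test_trim_and_grid_arithmetic(self):
        t = np.linspace(0.0, 400.0, 500)
        tg, vg = trim_resample(t, np.ones_like(t))
        assert tg[0] == pytest.approx(100.0)
        assert tg[-1] == pytest.approx(340.0)
        assert tg.size == 121
        assert np.allclose(np.diff(tg), 2.0)

    def test_linear_ramp_unchanged_by_resampling(self):
        t = np.sort(np.random.default_rng(9).uniform(0, 500, 800))
        t[0], t[-1] = 0.0, 500.0
        v = 1.7 * t + 3.0
        tg, vg = trim_resample(t, v)
        assert np.allclose(vg, 1.7 * tg + 3.0, atol=1e-9)

    def test_grid_count_formula(self):
        for span in (170.0, 401.0, 333.3):
            t = np.linspace(0.0, span, 700)
            tg, = trim_resample(t)[:1]
            assert tg.size == int(np.floor((span - 160.0) / 2.0)) + 1

    def test_non_monotone_and_short_series_rejected(self):
        with pytest.raises(ValueError):
            trim_resample(np.array([0.0, 2.0, 1.0, 3.0]))
        with pytest.raises(ValueError):
            trim_resample(np.linspace(0, 150, 100))


class TestSmoothPower:
    def test_constant_segment_unchanged_and_mean_applied(self):
        t = np.arange(0.0, 120.0, 1.0)
        p = np.where(t < 60.0, 250.0, 0.0)
        p[t >= 60.0] = np.where((t[t >= 60.0] % 2) == 0, 240.0, 260.0)
        sm = smooth_power(t, p, [60.0])
        assert np.allclose(sm[t < 60.0], 250.0)
        assert np.allclose(sm[t >= 60.0], 250.0)

    def test_segment_work_preserved(self):
        rng = np.random.default_rng(10)
        t = np.arange(0.0, 300.0, 1.0)
        p = rng.uniform(100.0, 300.0, t.size)
        bounds = [100.0, 200.0]
        sm = smooth_power(t, p, bounds)
        for a, b in ((0.0, 100.0), (100.0, 200.0), (200.0, 300.0)):
            m = (t >= a) & (t < b)
            assert sm[m].sum() == pytest.approx(p[m].sum(), rel=1e-9)


class TestPipeline:
    def test_synthetic_breath_record_round_trip(self):
        """A steady-state gas profile at known VO2/RQ comes back through the
        full pipeline at the right aerobic metabolic rate."""
        rng = np.random.default_rng(11)
        t = np.cumsum(rng.uniform(1.2, 2.2, 400))
        t -= t[0]
        ve_stpd = np.full(t.size, 60.0)
        # choose expired fractions for VO2 = 2.4 L/min, RQ = 0.9 at 60 L/min
        feo2 = np.full(t.size, 0.16581)
        feco2 = np.full(t.size, 0.03640)
        ve_btps = ve_stpd / 0.826
        power_t = np.arange(0.0, t[-1], 1.0)
        power = np.full(power_t.size, 200.0)
        trial = preprocess_trial(t, ve_btps, ve_stpd, feo2, feco2,
                                 power_t, power, [])
        assert np.allclose(np.diff(trial.t), 2.0)
        vi = haldane_inspiratory(60.0, feo2=0.16581, feco2=0.03640)
        vo2 = 0.2093 * vi - 0.16581 * 60.0
        vco2 = 0.03640 * 60.0 - 0.0004 * vi
        expected = mr_ae_from_gas(vo2, vco2 / vo2)
        assert np.allclose(trial.y, expected, rtol=1e-6)
        assert np.allclose(trial.u1, 200.0)
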