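import numpy as np
import pytest

from glioquant import dce
from glioquant.aif import AIFModel, parker_aif

TR = 4.0
ANGLES = np.array([6.0, 9.0, 15.0])


class TestVFA:
    def test_noiseless_recovery(self):
        s = dce.spgr_signal(1000.0, 1000.0, ANGLES, TR)
        fit = dce.fit_t1_vfa(s, ANGLES, TR)
        assert fit.valid
        assert fit.t1_ms == pytest.approx(1000.0, rel=1e-4 * 1e-2)
        assert fit.m0 == pytest.approx(1000.0, rel=1e-6)

    def test_two_angles_reproduce_three_angle_result(self):
        s3 = dce.spgr_signal(1400.0, 800.0, ANGLES, TR)
        f3 = dce.fit_t1_vfa(s3, ANGLES, TR)
        s2 = dce.spgr_signal(1400.0, 800.0, ANGLES[:2], TR)
        f2 = dce.fit_t1_vfa(s2, ANGLES[:2], TR)
        assert f2.t1_ms == pytest.approx(f3.t1_ms, rel=1e-9)

    def test_unidentifiable_signals_degenerate(self):
        # signals proportional to tan(angle) collapse the regressor to a
        # single abscissa: E1 is unidentifiable and the fit is flagged
        s = 100.0 * np.tan(np.deg2rad(ANGLES))
        fit = dce.fit_t1_vfa(s, ANGLES, TR)
        assert not fit.valid

    def test_out_of_range_e1_invalid(self):
        # signals rising steeply with angle push the regression slope past 1
        fit = dce.fit_t1_vfa(np.array([10.0, 40.0, 200.0]), ANGLES, TR)
        assert not fit.valid

    def test_identical_angles_rejected(self):
        with pytest.raises(ValueError):
            dce.fit_t1_vfa(np.array([1.0, 2.0]), np.array([9.0, 9.0]), TR)


class TestConcentration:
    def test_baseline_signal_gives_zero(self):
        s0 = dce.spgr_signal(1000.0, 500.0, 15.0, TR)
        c = dce.signal_to_concentration(np.full(10, s0), s0, 1000.0, TR, 15.0, 6.3)
        np.testing.assert_allclose(c, 0.0, atol=1e-12)

    @pytest.mark.parametrize("conc", [0.1, 0.5, 2.0])
    def test_forward_then_invert_roundtrip(self, conc):
        t10, m0, r1c = 1200.0, 900.0, 6.3
        r1 = 1000.0 / t10 + r1c * conc  # 1/s
        s_base = dce.spgr_signal(t10, m0, 15.0, TR)
        s_t = dce.spgr_signal(1000.0 / r1, m0, 15.0, TR)
        c = dce.signal_to_concentration(np.array([s_t]), s_base, t10, TR, 15.0, r1c)
        assert c[0] == pytest.approx(conc, abs=1e-9)

    def test_doubling_relaxivity_halves_concentration(self):
        t10, m0 = 1000.0, 700.0
        r1 = 1000.0 / t10 + 6.3 * 0.8
        s_base = dce.spgr_signal(t10, m0, 15.0, TR)
        s_t = np.array([dce.spgr_signal(1000.0 / r1, m0, 15.0, TR)])
        c1 = dce.signal_to_concentration(s_t, s_base, t10, TR, 15.0, 6.3)
        c2 = dce.signal_to_concentration(s_t, s_base, t10, TR, 15.0, 12.6)
        assert c1[0] == pytest.approx(2.0 * c2[0], rel=1e-12)

    def test_uninvertible_frame_marked_nan(self):
        s_base = dce.spgr_signal(1000.0, 700.0, 15.0, TR)
        huge = np.array([s_base * 50.0])  # beyond the SPGR range
        c = dce.signal_to_concentration(huge, s_base, 1000.0, TR, 15.0, 6.3)
        assert np.isnan(c[0])


class TestExtendedTofts:
    def _curves(self, ktrans, kep, vp, aif):
        t = np.arange(60) * 5.0
        cp = aif.plasma_concentration(t)
        return t, cp, dce.tofts_forward(t, cp, ktrans, kep, vp)

    def test_zero_tissue_curve(self, aif):
        t, cp, _ = self._curves(0.1, 0.5, 0.02, aif)
        fit = dce.fit_extended_tofts(np.zeros_like(cp), cp, t)
        assert fit.valid and fit.ktrans == 0.0 and fit.vp == 0.0

    def test_noiseless_recovery_within_one_percent(self, aif):
        t, cp, ct = self._curves(0.1, 0.5, 0.02, aif)
        fit = dce.fit_extended_tofts(ct, cp, t)
        assert fit.valid
        assert fit.ktrans == pytest.approx(0.1, rel=0.01)
        assert fit.kep == pytest.approx(0.5, rel=0.01)
        assert fit.vp == pytest.approx(0.02, rel=0.01)
        assert fit.ve == pytest.approx(fit.ktrans / fit.kep, rel=1e-9)

    def test_pure_plasma_voxel(self, aif):
        t = np.arange(60) * 5.0
        cp = aif.plasma_concentration(t)
        fit = dce.fit_extended_tofts(0.02 * cp, cp, t)
        assert fit.vp == pytest.approx(0.02, abs=1e-6)
        assert fit.ktrans == pytest.approx(0.0, abs=1e-6)

    def test_matches_lattice_oracle(self, aif):
        """Fit lands on the generating lattice point of an exhaustive search."""
        t = np.arange(60) * 5.0
        cp = aif.plasma_concentration(t)
        kt_grid = np.arange(0.02, 0.32, 0.02)
        kep_grid = np.arange(0.1, 1.6, 0.1)
        vp_grid = np.arange(0.0, 0.11, 0.01)
        rng = np.random.default_rng(7)
        for _ in range(5):
            kt = float(rng.choice(kt_grid))
            kep = float(rng.choice(kep_grid))
            vp = float(rng.choice(vp_grid))
            ct = dce.tofts_forward(t, cp, kt, kep, vp)
            # lattice oracle
            best = None
            for a in kt_grid:
                for b in kep_grid:
                    for c in vp_grid:
                        sse = np.sum((dce.tofts_forward(t, cp, a, b, c) - ct) ** 2)
                        if best is None or sse < best[0]:
                            best = (sse, a, b, c)
            fit = dce.fit_extended_tofts(ct, cp, t)
            assert abs(fit.ktrans - best[1]) <= 0.02 + 1e-9
            assert abs(fit.kep - best[2]) <= 0.1 + 1e-9
            assert abs(fit.vp - best[3]) <= 0.01 + 1e-9

    def test_too_few_frames_rejected(self, aif):
        t = np.arange(3) * 5.0
        with pytest.raises(ValueError):
            dce.fit_extended_tofts(np.zeros(3), np.ones(3), t)


class TestCurveMetrics:
    def _triangle(self):
        # rise 0 -> 1 over 0-30 s, fall back to 0 at 90 s, dt = 5 s
        t = np.arange(0.0, 95.0, 5.0)
        c = np.where(t <= 30, t / 30.0, 1.0 - (t - 30.0) / 60.0)
        return t, c

    def test_triangle_closed_form(self):
        t, c = self._triangle()
        m = dce.compute_curve_metrics(c, t, window_s=60.0)
        assert m.valid
        assert m.peak == 1.0
        # arrival at t = 5 s (first frame above 0.1), peak at 30 s
        assert m.ttp == pytest.approx(25.0)
        # trapezoid integral over [5, 65] of the piecewise-linear curve
        rise = (c[1] + 1.0) / 2.0 * 25.0
        c65 = 1.0 - 35.0 / 60.0
        fall = (1.0 + c65) / 2.0 * 35.0
        assert m.auc == pytest.approx(rise + fall, rel=1e-12)
        assert m.wash_in == pytest.approx((1.0 / 6.0) / 5.0, rel=1e-12)
        assert m.wash_out == pytest.approx(1.0 / 60.0, rel=1e-9)

    def test_monotone_curve_nonpositive_washout(self):
        t = np.arange(10) * 5.0
        c = np.linspace(0, 2, 10)
        m = dce.compute_curve_metrics(c, t)
        assert m.wash_out <= 0.0

    def test_scaling_homogeneity(self):
        t, c = self._triangle()
        m1 = dce.compute_curve_metrics(c, t)
        m2 = dce.compute_curve_metrics(2 * c, t)
        assert m2.peak == pytest.approx(2 * m1.peak)
        assert m2.auc == pytest.approx(2 * m1.auc)
        assert m2.wash_in == pytest.approx(2 * m1.wash_in)
        assert m2.wash_out == pytest.approx(2 * m1.wash_out)
        assert m2.ttp == m1.ttp

    def test_flat_curve_invalid(self):
        m = dce.compute_curve_metrics(np.full(10, 3.0), np.arange(10) * 5.0)
        assert not m.valid


class TestCBV:
    def test_ratio_definition(self, aif):
        t = np.arange(60) * 5.0
        cb = aif.blood_concentration(t)
        assert dce.compute_cbv(0.04 * cb, aif.plasma_concentration(t), t, aif.hematocrit) == pytest.approx(4.0)

    def test_equal_curves_give_100(self, aif):
        t = np.arange(60) * 5.0
        cb = aif.blood_concentration(t)
        assert dce.compute_cbv(cb, aif.plasma_concentration(t), t, aif.hematocrit) == pytest.approx(100.0)

    def test_plasma_voxel_against_numeric_oracle(self, aif):
        # ct = vp * cp with vp = 0.02 and Hct = 0.45:
        # cbv = 100 * vp / (1 - Hct) by direct integration
        t = np.arange(60) * 5.0
        cp = aif.plasma_concentration(t)
        ct = 0.02 * cp
        expected = 100.0 * np.trapezoid(ct, t) / np.trapezoid(cp * (1 - 0.45), t)
        got = dce.compute_cbv(ct, cp, t, hematocrit=0.45)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.02 * 100.0 / 0.55, rel=1e-9)

    def test_zero_aif_rejected(self):
        t = np.arange(10) * 5.0
        with pytest.raises(ValueError):
            dce.compute_cbv(np.ones(10), np.zeros(10), t)


class TestAIF:
    def test_zero_before_onset_and_positive_after(self):
        t = np.arange(0, 300, 1.0)
        cp = parker_aif(t, AIFModel(t_onset_s=10.0))
        assert cp[0] == 0.0
        assert np.all(cp[t <= 10.0] == 0.0)
        assert np.all(cp >= 0.0)
        assert cp[t > 15.0].max() > 3.0  # first-pass peak of several mmol/L
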