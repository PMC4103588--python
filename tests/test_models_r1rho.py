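"""Analytic R1rho models: geometry, frozen examples, numeric cross-checks."""

import math

import numpy as np
import pytest

from dispfit.models import numeric, r1rho
from dispfit.units import ppm_to_rad_per_s


def geom(omega1=2000.0, omega_a=0.0, dw=0.0, pA=1.0):
    return r1rho.spin_lock_geometry(omega1, omega_a, dw, pA)


class TestGeometry:
    def test_on_resonance_tilt_is_right_angle(self):
        assert geom(omega_a=0.0).theta == pytest.approx(math.pi / 2)

    def test_vanishing_lock_tilts_to_pole(self):
        g = r1rho.spin_lock_geometry(1e-9, 500.0, 0.0, 1.0)
        assert g.theta == pytest.approx(0.0, abs=1e-10)
        g = r1rho.spin_lock_geometry(1e-9, -500.0, 0.0, 1.0)
        assert g.theta == pytest.approx(math.pi, abs=1e-10)

    def test_equal_offset_and_lock_gives_45_degrees(self):
        g = r1rho.spin_lock_geometry(800.0, 800.0, 0.0, 1.0)
        assert g.theta == pytest.approx(math.pi / 4)

    def test_population_average_offset(self):
        g = r1rho.spin_lock_geometry(1000.0, 100.0, 200.0, 0.9)
        assert g.omega_avg == pytest.approx(0.9 * 100 + 0.1 * 300)
        assert g.omega_eff_sq == pytest.approx(g.omega_avg**2 + 1000.0**2)

    def test_non_positive_lock_rejected(self):
        with pytest.raises(ValueError):
            r1rho.spin_lock_geometry(0.0, 100.0, 0.0, 1.0)


class TestNoRex:
    def test_on_resonance_returns_transverse_rate(self):
        assert r1rho.r1rho_norex(1.5, 10.0, geom(omega_a=0.0)) == pytest.approx(10.0)

    def test_far_off_resonance_returns_longitudinal_rate(self):
        g = r1rho.spin_lock_geometry(1.0, 1e6, 0.0, 1.0)
        assert r1rho.r1rho_norex(1.5, 10.0, g) == pytest.approx(1.5, abs=1e-6)

    def test_hand_evaluated_45_degrees(self):
        g = r1rho.spin_lock_geometry(800.0, 800.0, 0.0, 1.0)
        assert r1rho.r1rho_norex(1.5, 10.0, g) == pytest.approx(5.75)


class TestM61:
    def test_no_exchange_returns_baseline(self):
        assert r1rho.r1rho_m61(8.0, 0.0, 2000.0, geom()) == 8.0

    def test_strong_lock_quenches_exchange(self):
        g = geom(omega1=1e7)
        assert r1rho.r1rho_m61(8.0, 4e4, 2000.0, g) == pytest.approx(8.0, abs=1e-3)

    def test_hand_evaluated_example(self):
        # 8 + 4e4*2000/(2000^2 + 2000^2) = 18
        g = geom(omega1=2000.0)
        assert r1rho.r1rho_m61(8.0, 4.0e4, 2000.0, g) == pytest.approx(18.0)


class TestDPL94:
    def test_reduces_to_m61_on_resonance(self):
        g = geom(omega1=1500.0, omega_a=0.0)
        m61 = r1rho.r1rho_m61(8.0, 3e4, 2500.0, g)
        dpl = r1rho.r1rho_dpl94(1.5, 8.0, 3e4, 2500.0, g)
        assert dpl == m61  # exact: sin^2 = 1, cos^2 = 0 at theta = pi/2

    def test_weak_lock_far_off_resonance_returns_r1(self):
        g = r1rho.spin_lock_geometry(1.0, 1e5, 0.0, 1.0)
        assert r1rho.r1rho_dpl94(1.5, 8.0, 3e4, 2500.0, g) == pytest.approx(1.5, abs=1e-4)

    def test_fast_exchange_matches_numeric(self):
        # kex >= 10*dw sweep: 5 % agreement with the propagated reference
        r1, r2, pA, T = 1.5, 10.0, 0.95, 0.1
        dw = ppm_to_rad_per_s(1.0, 600.0, "15N")
        kex = 12.0 * dw
        phi = pA * (1 - pA) * dw * dw
        for om1_hz in (400.0, 1000.0, 2000.0):
            for off_hz in (-300.0, 0.0, 400.0):
                om1 = 2 * math.pi * om1_hz
                oa = 2 * math.pi * off_hz
                g = r1rho.spin_lock_geometry(om1, oa, dw, pA)
                an = r1rho.r1rho_dpl94(r1, r2, phi, kex, g)
                ns = numeric.ns_r1rho_2site(r1, r2, r2, pA, kex, dw, oa, om1, T)
                assert abs(an - ns) / ns < 0.05


class TestTP02:
    def test_pure_state_returns_rotating_frame_baseline(self):
        g = geom(omega1=1000.0, omega_a=600.0)
        base = r1rho.r1rho_norex(1.5, 10.0, g)
        assert r1rho.r1rho_tp02(1.5, 10.0, 1.0, 2000.0, 500.0, g) == pytest.approx(base)

    def test_fast_exchange_agrees_with_dpl94(self):
        r1, r2, pA = 1.5, 10.0, 0.95
        dw = ppm_to_rad_per_s(1.0, 600.0, "15N")
        kex = 15.0 * dw
        phi = pA * (1 - pA) * dw * dw
        for om1 in (3000.0, 8000.0):
            g = r1rho.spin_lock_geometry(om1, 1000.0, dw, pA)
            tp = r1rho.r1rho_tp02(r1, r2, pA, kex, dw, g)
            dp = r1rho.r1rho_dpl94(r1, r2, phi, kex, g)
            assert abs(tp - dp) / dp < 0.05

    def test_skewed_regime_matches_numeric(self):
        r1, r2, T = 1.5, 10.0, 0.1
        for pA in (0.95, 0.99):
            for kex in (500.0, 2000.0, 1e4):
                dw = ppm_to_rad_per_s(3.0, 600.0, "15N")
                for om1_hz, off_hz in [(400.0, 0.0), (1000.0, 300.0), (2000.0, 500.0)]:
                    om1, oa = 2 * math.pi * om1_hz, 2 * math.pi * off_hz
                    g = r1rho.spin_lock_geometry(om1, oa, dw, pA)
                    an = r1rho.r1rho_tp02(r1, r2, pA, kex, dw, g)
                    ns = numeric.ns_r1rho_2site(r1, r2, r2, pA, kex, dw, oa, om1, T)
                    assert abs(an - ns) / ns < 0.10


class TestMP05:
    def test_pure_state_returns_baseline(self):
        g = geom(omega1=1000.0, omega_a=600.0)
        base = r1rho.r1rho_norex(1.5, 10.0, g)
        assert r1rho.r1rho_mp05(1.5, 10.0, 1.0, 2000.0, 500.0, g) == pytest.approx(base)

    def test_reduces_to_tp02_when_correction_negligible(self):
        # strongly skewed, tiny shift: the second-order term vanishes
        g = geom(omega1=5000.0, omega_a=200.0, dw=1.0, pA=1.0 - 1e-9)
        tp = r1rho.r1rho_tp02(1.5, 10.0, 1.0 - 1e-9, 2000.0, 1.0, g)
        mp = r1rho.r1rho_mp05(1.5, 10.0, 1.0 - 1e-9, 2000.0, 1.0, g)
        assert mp == pytest.approx(tp, rel=1e-8)

    def test_broad_regime_beats_tp02_against_numeric(self):
        r1, r2, T = 1.5, 10.0, 0.1
        worst_tp = worst_mp = 0.0
        for pA in (0.8, 0.85, 0.9):
            for kex in (1000.0, 3000.0, 1e4):
                dw = ppm_to_rad_per_s(3.0, 600.0, "15N")
                for om1_hz, off_hz in [(500.0, 0.0), (1500.0, 300.0), (800.0, 800.0)]:
                    om1, oa = 2 * math.pi * om1_hz, 2 * math.pi * off_hz
                    g = r1rho.spin_lock_geometry(om1, oa, dw, pA)
                    ns = numeric.ns_r1rho_2site(r1, r2, r2, pA, kex, dw, oa, om1, T)
                    tp = r1rho.r1rho_tp02(r1, r2, pA, kex, dw, g)
                    mp = r1rho.r1rho_mp05(r1, r2, pA, kex, dw, g)
                    worst_tp = max(worst_tp, abs(tp - ns) / ns)
                    worst_mp = max(worst_mp, abs(mp - ns) / ns)
        assert worst_mp < worst_tp


class TestBoundsAndContinuity:
    def test_outputs_finite_and_positive_over_domain(self):
        r1, r2 = 1.5, 10.0
        dw = ppm_to_rad_per_s(2.0, 600.0, "15N")
        for pA in (0.7, 0.95, 0.999):
            for kex in (10.0, 1e3, 1e5):
                for oa in (-5000.0, 0.0, 5000.0):
                    g = r1rho.spin_lock_geometry(1500.0, oa, dw, pA)
                    for fn in (
                        lambda: r1rho.r1rho_dpl94(r1, r2, pA * (1 - pA) * dw**2, kex, g),
                        lambda: r1rho.r1rho_tp02(r1, r2, pA, kex, dw, g),
                        lambda: r1rho.r1rho_mp05(r1, r2, pA, kex, dw, g),
                    ):
                        v = fn()
                        assert np.isfinite(v) and v > 0

    def test_theta_continuity_through_resonance(self):
        # outputs continuous in the offset through zero
        r1, r2, pA, kex = 1.5, 10.0, 0.95, 3000.0
        dw = ppm_to_rad_per_s(2.0, 600.0, "15N")
        offsets = np.linspace(-50.0, 50.0, 41)
        vals = [
            r1rho.r1rho_tp02(r1, r2, pA, kex, dw, r1rho.spin_lock_geometry(1500.0, o, dw, pA))
            for o in offsets
        ]
        assert np.max(np.abs(np.diff(vals))) < 0.01
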