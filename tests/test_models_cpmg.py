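"""Analytic CPMG models: frozen examples, limits and numeric cross-checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dispfit.models import cpmg, numeric
from dispfit.units import ppm_to_rad_per_s

NU = np.array([50.0, 100.0, 200.0, 400.0, 800.0])


class TestVanishingExchange:
    """Every model must return the baseline exactly when exchange vanishes."""

    def test_norex_flat(self):
        out = cpmg.r2eff_norex(10.0, NU)
        assert np.all(out == 10.0)

    def test_lm63_zero_amplitude(self):
        assert np.all(cpmg.r2eff_lm63(10.0, 0.0, 2000.0, NU) == 10.0)

    @pytest.mark.parametrize("pA,dw", [(1.0, 500.0), (0.9, 0.0)])
    def test_cr72_no_exchange(self, pA, dw):
        assert np.all(cpmg.r2eff_cr72(10.0, 10.0, pA, 1500.0, dw, NU) == 10.0)

    @pytest.mark.parametrize("pA,dw", [(1.0, 500.0), (0.9, 0.0)])
    def test_it99_no_exchange(self, pA, dw):
        assert np.all(cpmg.r2eff_it99(10.0, pA, 1500.0, dw, NU) == 10.0)

    @pytest.mark.parametrize("k_ab,dw", [(0.0, 500.0), (5.0, 0.0)])
    def test_tsmfk01_no_exchange(self, k_ab, dw):
        assert np.all(cpmg.r2eff_tsmfk01(10.0, k_ab, dw, NU) == 10.0)

    def test_mmq_cr72_no_exchange(self):
        for et in ("CPMG_SQ", "CPMG_ZQ", "CPMG_DQ", "CPMG_MQ"):
            out = cpmg.r2eff_mmq_cr72(10.0, 10.0, 1.0, 1500.0, 500.0, 100.0, NU, et)
            assert np.all(out == 10.0), et


class TestLM63:
    def test_slow_pulsing_limit(self):
        # R20 + phi_ex/kex as nu -> 0
        out = cpmg.r2eff_lm63(10.0, 57600.0, 2000.0, np.array([1e-3]))
        assert out[0] == pytest.approx(38.8, abs=1e-3)

    def test_frozen_midpoint(self):
        # direct evaluation at nu = 100: x = 5, 10 + 28.8*(1 - tanh(5)/5)
        out = cpmg.r2eff_lm63(10.0, 57600.0, 2000.0, np.array([100.0]))
        assert out[0] == pytest.approx(33.04, abs=0.01)

    def test_fast_pulsing_approaches_baseline(self):
        out = cpmg.r2eff_lm63(10.0, 57600.0, 2000.0, np.array([1e6]))
        assert out[0] == pytest.approx(10.0, abs=1e-3)

    @given(
        phi=st.floats(1e2, 1e6),
        kex=st.floats(100, 5e4),
        r20=st.floats(1, 50),
    )
    def test_monotone_non_increasing_in_nu(self, phi, kex, r20):
        nu = np.linspace(25, 2000, 40)
        out = cpmg.r2eff_lm63(r20, phi, kex, nu)
        assert np.all(np.diff(out) <= 1e-10)

    def test_kex_zero_with_amplitude_rejected(self):
        with pytest.raises(ValueError):
            cpmg.r2eff_lm63(10.0, 100.0, 0.0, NU)


class TestCR72:
    def test_matches_numeric_reference_in_validity_regime(self):
        # kex >= 2*dw: the closed form tracks the propagated reference to 2 %
        T = 0.04
        nus = np.arange(4, 64, 4) * 12.5
        for pA in (0.9, 0.95, 0.99):
            for kex, dw_ppm, field in [(2000.0, 1.0, 800.0), (1e4, 3.0, 600.0)]:
                dw = ppm_to_rad_per_s(dw_ppm, field, "15N")
                assert kex >= 2 * dw
                an = cpmg.r2eff_cr72(10.0, 10.0, pA, kex, dw, nus)
                ns = np.array(
                    [numeric.ns_cpmg_2site(10.0, 10.0, pA, kex, dw, nu, T) for nu in nus]
                )
                assert np.max(np.abs(an - ns) / ns) < 0.02

    def test_fast_exchange_consistency_with_lm63(self):
        # kex >= 20*dw: |CR72 - LM63| / Rex <= 5 % across the grid
        dw = ppm_to_rad_per_s(1.0, 600.0, "15N")
        kex = 25.0 * dw
        pA = 0.9
        nu = np.linspace(50, 1000, 20)
        cr = cpmg.r2eff_cr72(10.0, 10.0, pA, kex, dw, nu)
        lm = cpmg.r2eff_lm63(10.0, pA * (1 - pA) * dw**2, kex, nu)
        rex = pA * (1 - pA) * dw**2 / kex
        assert np.max(np.abs(cr - lm)) / rex < 0.05

    def test_finite_difference_gradients_finite(self):
        # smoothness smoke test on the open domain
        base = dict(r20a=10.0, r20b=10.0, pA=0.95, kex=2000.0, dw=800.0)
        f0 = cpmg.r2eff_cr72(**base, nu_cpmg=NU)
        for key in ("pA", "kex", "dw", "r20a"):
            stepped = dict(base)
            h = max(abs(stepped[key]), 1.0) * 1e-7
            stepped[key] += h
            grad = (cpmg.r2eff_cr72(**stepped, nu_cpmg=NU) - f0) / h
            assert np.all(np.isfinite(grad))

    def test_large_kex_small_nu_stays_finite(self):
        out = cpmg.r2eff_cr72(10.0, 10.0, 0.95, 9e5, 2000.0, np.array([25.0]))
        assert np.isfinite(out[0])


class TestIT99:
    def test_fast_pulsing_approaches_baseline(self):
        dw = ppm_to_rad_per_s(2.0, 600.0, "15N")
        out = cpmg.r2eff_it99(10.0, 0.95, 3000.0, dw, np.array([1e5]))
        assert out[0] == pytest.approx(10.0, abs=1e-2)

    def test_skewed_regime_matches_numeric(self):
        # pA = 0.95, kex = 1e4, dw = 3 ppm at 600 MHz: within 10 %
        T = 0.04
        nus = np.arange(8, 88, 8) * 12.5
        dw = ppm_to_rad_per_s(3.0, 600.0, "15N")
        an = cpmg.r2eff_it99(10.0, 0.95, 1e4, dw, nus)
        ns = np.array(
            [numeric.ns_cpmg_2site(10.0, 10.0, 0.95, 1e4, dw, nu, T) for nu in nus]
        )
        assert np.max(np.abs(an - ns) / ns) < 0.10


class TestTSMFK01:
    def test_sinc_limit_small_argument(self):
        dw = 1e-12
        out = cpmg.r2eff_tsmfk01(10.0, 5.0, dw, np.array([1000.0]))
        assert out[0] == pytest.approx(10.0, abs=1e-9)

    def test_envelope_is_baseline_plus_forward_rate(self):
        # many sinc oscillations average around R2A0 + k_AB
        dw = ppm_to_rad_per_s(4.0, 600.0, "15N")
        out = cpmg.r2eff_tsmfk01(10.0, 2.0, dw, np.array([10.0]))
        assert 10.0 < out[0] <= 12.0 + 1e-9

    def test_slow_exchange_matches_numeric(self):
        # pA = 0.99, small kex: agree with the propagated reference to 10 %
        T = 0.04
        nus = np.arange(8, 88, 8) * 12.5
        dw = ppm_to_rad_per_s(4.0, 600.0, "15N")
        pA, kex = 0.99, 100.0
        an = cpmg.r2eff_tsmfk01(10.0, (1 - pA) * kex, dw, nus)
        ns = np.array(
            [numeric.ns_cpmg_2site(10.0, 10.0, pA, kex, dw, nu, T) for nu in nus]
        )
        assert np.max(np.abs(an - ns) / ns) < 0.10


class TestMMQCR72:
    def test_zq_with_zero_proton_shift_equals_sq(self):
        dw = ppm_to_rad_per_s(2.0, 600.0, "15N")
        sq = cpmg.r2eff_mmq_cr72(10.0, 10.0, 0.95, 2000.0, dw, 0.0, NU, "CPMG_SQ")
        zq = cpmg.r2eff_mmq_cr72(10.0, 10.0, 0.95, 2000.0, dw, 0.0, NU, "CPMG_ZQ")
        np.testing.assert_allclose(zq, sq, rtol=0, atol=0)

    def test_dq_equals_sq_at_summed_shift(self):
        dw = ppm_to_rad_per_s(2.0, 600.0, "15N")
        dwh = ppm_to_rad_per_s(1.0, 600.0, "15N")
        dq = cpmg.r2eff_mmq_cr72(10.0, 10.0, 0.95, 2000.0, dw, dwh, NU, "CPMG_DQ")
        sq = cpmg.r2eff_cr72(10.0, 10.0, 0.95, 2000.0, dw + dwh, NU)
        np.testing.assert_allclose(dq, sq, rtol=1e-12)

    def test_mq_matches_numeric_in_validity_regime(self):
        T = 0.04
        nus = np.arange(4, 44, 4) * 25.0
        for pA, kex, dwp, dwhp in [(0.95, 2000.0, 2.0, 0.5), (0.9, 1e4, 3.0, 1.0)]:
            dw = ppm_to_rad_per_s(dwp, 600.0, "15N")
            dwh = ppm_to_rad_per_s(dwhp, 600.0, "1H")
            an = cpmg.r2eff_mmq_cr72(10.0, 10.0, pA, kex, dw, dwh, nus, "CPMG_MQ")
            ns = np.array(
                [
                    numeric.ns_mmq_2site(10.0, 10.0, pA, kex, dw, dwh, nu, T, "CPMG_MQ")
                    for nu in nus
                ]
            )
            assert np.max(np.abs(an - ns) / np.abs(ns)) < 0.05
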