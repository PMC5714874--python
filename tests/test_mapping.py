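"""Micro-to-macro mapping: NLS fit, Hill relation, Collins-Kimball."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlbind.mapping import (HillParams, TheoryQuantities, collins_kimball,
                            fit_hill, fit_kon_macro, hill, reaction_volume,
                            relative_difference, scaling_factors,
                            smoluchowski_rate)
from rlbind.ode import MacroKinetics, analytic_C


class TestFitKonMacro:
    KOFF, R0, L0 = 0.1, 1.0, 1.0

    def _series(self, kon, n=200, t_max=10.0):
        t = np.linspace(0.0, t_max, n)
        return t, analytic_C(t, MacroKinetics(kon, self.KOFF, self.R0, self.L0))

    def test_noiseless_self_recovery(self):
        t, c = self._series(2.0)
        fit = fit_kon_macro(t, c, self.KOFF, self.R0, self.L0)
        assert fit.converged
        assert fit.kon_macro_hat == pytest.approx(2.0, rel=1e-6)

    def test_recovery_under_multiplicative_noise(self):
        r = np.random.default_rng(8)
        estimates = []
        for _ in range(100):
            t, c = self._series(2.0)
            noisy = c * (1.0 + 0.01 * r.standard_normal(c.size))
            fit = fit_kon_macro(t, noisy, self.KOFF, self.R0, self.L0)
            estimates.append(fit.kon_macro_hat)
        assert np.median(estimates) == pytest.approx(2.0, rel=0.05)

    def test_invariant_to_time_resampling(self):
        t1, c1 = self._series(0.7, n=150)
        t2, c2 = self._series(0.7, n=600, t_max=6.0)
        f1 = fit_kon_macro(t1, c1, self.KOFF, self.R0, self.L0)
        f2 = fit_kon_macro(t2, c2, self.KOFF, self.R0, self.L0)
        assert f1.kon_macro_hat == pytest.approx(f2.kon_macro_hat, rel=1e-6)

    def test_requires_transient_coverage(self):
        with pytest.raises(ValueError, match="10 data points"):
            fit_kon_macro([0, 1], [0, 0.1], self.KOFF, self.R0, self.L0)


class TestHill:
    def test_noiseless_recovery(self):
        k = np.logspace(4, 8, 12)
        pts = np.column_stack([k, hill(k, HillParams(10.0, 1e6))])
        est = fit_hill(pts)
        assert est.a == pytest.approx(10.0, rel=1e-6)
        assert est.b == pytest.approx(1e6, rel=1e-6)

    def test_half_saturation_identity(self):
        p = HillParams(10.0, 1e6)
        assert float(hill(1e6, p)) == pytest.approx(5.0)

    def test_saturation_limit(self):
        p = HillParams(10.0, 1e6)
        assert float(hill(1e10, p)) == pytest.approx(10.0, rel=1e-4)

    def test_linear_regime_warns(self):
        k = np.array([1.0, 2.0, 4.0, 8.0])
        pts = np.column_stack([k, hill(k, HillParams(10.0, 1e6))])
        with pytest.warns(UserWarning, match="linear regime"):
            fit_hill(pts)


class TestTheory:
    def test_smoluchowski_printed_parameters(self):
        # contact distance 8.7 nm, diffusivity sum 190 µm²/s
        assert smoluchowski_rate(0.005, 0.0037, 90.0, 100.0) == pytest.approx(
            20.772, abs=2e-3)

    def test_smoluchowski_linear_in_diffusivity(self):
        assert smoluchowski_rate(0.01, 0.01, 20, 20) == pytest.approx(
            2 * smoluchowski_rate(0.01, 0.01, 10, 10))
        assert smoluchowski_rate(0.0, 0.0, 10, 10) == 0.0

    def test_reaction_volume_value_and_cubic_scaling(self):
        assert reaction_volume(0.005, 0.0037) == pytest.approx(2.758e-6,
                                                               rel=1e-3)
        assert reaction_volume(0.01, 0.0074) == pytest.approx(
            8 * reaction_volume(0.005, 0.0037))

    def test_collins_kimball_limits(self):
        assert collins_kimball(20.0, 1e12) == pytest.approx(20.0, rel=1e-9)
        assert collins_kimball(20.0, 20.0) == pytest.approx(10.0)

    def test_collins_kimball_reproduces_reported_on_rate(self):
        # with the reaction volume reduced to 79%, the theory lands at
        # the O-SOL operating point near 2 µm³/s
        ks = smoluchowski_rate(0.005, 0.0037, 90.0, 100.0)
        kappa = 0.79 * reaction_volume(0.005, 0.0037) * 1e6
        assert collins_kimball(ks, kappa) == pytest.approx(1.97, abs=0.01)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0),
           st.floats(1.001, 10.0))
    def test_collins_kimball_monotone_and_bounded(self, ks, kappa, factor):
        base = collins_kimball(ks, kappa)
        assert base <= min(ks, kappa) + 1e-12
        assert collins_kimball(ks * factor, kappa) >= base
        assert collins_kimball(ks, kappa * factor) >= base


class TestScalingFactors:
    THEORY = TheoryQuantities(r_R=0.005, r_L=0.0037, D_R=90.0, D_L=100.0)

    def test_exact_collins_kimball_case(self):
        hp = HillParams(self.THEORY.ks, self.THEORY.ks / self.THEORY.Vr)
        fs, fr = scaling_factors(hp, self.THEORY)
        assert fs == pytest.approx(1.0, rel=1e-12)
        assert fr == pytest.approx(1.0, rel=1e-12)

    def test_arithmetic_example(self):
        t = TheoryQuantities(r_R=0.005, r_L=0.0037, D_R=90.0, D_L=100.0)
        hp = HillParams(t.ks / 2.0, 1e7)
        fs, fr = scaling_factors(hp, t)
        assert fs == pytest.approx(0.5)
        assert fr == pytest.approx(t.ks / 2.0 / (1e7 * t.Vr))

    def test_round_trip_closure(self):
        """Scaled Collins-Kimball -> Hill fit -> scaling factors is the
        identity on (fs, fr)."""
        fs_true, fr_true = 0.87, 0.73
        t = TheoryQuantities(r_R=0.005, r_L=0.0037, D_R=90.0, D_L=100.0,
                             fs=fs_true, fr=fr_true)
        k = np.logspace(4, np.log10(2.5e7), 9)
        pts = np.column_stack([k, [t.kon_macro(x) for x in k]])
        hp = fit_hill(pts)
        fs, fr = scaling_factors(hp, t)
        assert fs == pytest.approx(fs_true, rel=1e-6)
        assert fr == pytest.approx(fr_true, rel=1e-6)


class TestRelativeDifference:
    def test_identical_series_vanish(self):
        b = np.array([0.0, 1.0, 2.0, 4.0])
        out = relative_difference(b, b)
        assert np.isnan(out[0])
        assert np.allclose(out[1:], 0.0)

    def test_factor_two(self):
        a = np.array([1.0, 2.0, 3.0])
        out = relative_difference(a, 2 * a)
        assert np.allclose(out, 0.5)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(np.zeros(3), np.zeros(4))
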