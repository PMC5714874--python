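"""Closed-form mass-action solution vs an independent numerical oracle."""

import numpy as np
import pytest

from rlbind.ode import (AnalyticKinetics, MacroKinetics, analytic_C,
                        equilibrium_C, integrate_ode)

REF = MacroKinetics(kon_macro=1.0, koff_macro=0.1, R0=1.0, L0=1.0)


class TestAnalyticSolution:
    def test_initial_condition_is_zero(self):
        for kin in (REF, MacroKinetics(3.7, 0.02, 0.4, 2.2)):
            assert float(analytic_C(0.0, kin)) == 0.0

    def test_reference_equilibrium_value(self):
        # quadratic-root arithmetic: C+/- = 1.05 -/+ sqrt(0.1025)
        assert equilibrium_C(REF) == pytest.approx(0.7298438, abs=1e-6)

    def test_reference_transient_value(self):
        # frozen from the adaptive integrator (rtol 1e-10)
        assert float(analytic_C(1.0, REF)) == pytest.approx(0.479861, abs=1e-5)
        assert float(analytic_C(1.0, REF)) == pytest.approx(
            integrate_ode(REF, np.array([1.0]))[0], rel=1e-8)

    def test_long_time_limit_is_equilibrium(self):
        assert float(analytic_C(1e9, REF)) == pytest.approx(
            equilibrium_C(REF), rel=1e-12)

    def test_monotone_nondecreasing_from_zero(self):
        t = np.linspace(0.0, 50.0, 400)
        c = analytic_C(t, REF)
        assert c[0] == 0.0
        assert np.all(np.diff(c) >= -1e-14)

    def test_degenerate_equal_roots(self):
        # koff = 0 and R0 = L0: the generic formula is 0/0 there
        kin = MacroKinetics(2.0, 0.0, 1.5, 1.5)
        t = np.linspace(0.001, 5.0, 60)
        assert np.allclose(analytic_C(t, kin), integrate_ode(kin, t),
                           rtol=1e-7, atol=1e-12)
        assert float(analytic_C(1e12, kin)) == pytest.approx(1.5, rel=1e-9)

    def test_zero_on_rate_means_no_complexes(self):
        kin = MacroKinetics(0.0, 0.1, 1.0, 1.0)
        assert np.all(analytic_C(np.linspace(0, 10, 11), kin) == 0.0)


class TestEquilibrium:
    def test_no_binding_limit(self):
        assert equilibrium_C(MacroKinetics(1e-14, 0.1, 1.0, 2.0)) < 1e-12

    def test_irreversible_limit_binds_the_scarcer_species(self):
        assert equilibrium_C(
            MacroKinetics(1.0, 0.0, 0.7, 2.0)) == pytest.approx(0.7)
        assert equilibrium_C(
            MacroKinetics(1.0, 0.0, 2.0, 0.7)) == pytest.approx(0.7)

    def test_detailed_balance_identity(self):
        r = np.random.default_rng(42)
        for _ in range(50):
            kin = MacroKinetics(10 ** r.uniform(-2, 2), 10 ** r.uniform(-3, 1),
                                10 ** r.uniform(-2, 2), 10 ** r.uniform(-2, 2))
            c = equilibrium_C(kin)
            residual = (kin.kon_macro * (kin.R0 - c) * (kin.L0 - c)
                        - kin.koff_macro * c)
            scale = max(1.0, kin.kon_macro * kin.R0 * kin.L0)
            assert abs(residual) / scale < 1e-12

    def test_root_ordering_and_product_identity(self):
        ak = AnalyticKinetics.from_kinetics(REF)
        assert ak.C_minus <= min(REF.R0, REF.L0) <= ak.C_plus
        assert ak.C_minus * ak.C_plus == pytest.approx(
            ak.gamma / ak.alpha, rel=1e-12)


class TestConservation:
    def test_free_species_stay_nonnegative(self):
        t = np.linspace(0.001, 100.0, 500)
        for kin in (REF, MacroKinetics(5.0, 0.01, 0.3, 3.0)):
            c = analytic_C(t, kin)
            assert np.all(kin.R0 - c >= -1e-12)
            assert np.all(kin.L0 - c >= -1e-12)

    def test_integrator_grid_validation(self):
        with pytest.raises(ValueError):
            integrate_ode(REF, np.array([1.0, 0.5]))
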