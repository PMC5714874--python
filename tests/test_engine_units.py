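"""Elementary engine operations: time step, diffusion, boundaries,
neighbor lists, binding/unbinding trials, down-scaling."""

import dataclasses

import numpy as np
import pytest

from rlbind.engine import (ConfigurationError, LigandState, ReceptorState,
                           SimulationConfig, attempt_binding,
                           attempt_unbinding, apply_cell_boundary,
                           apply_outer_boundary, build_neighbor_list,
                           compute_time_step, diffusion_step,
                           downscale_config)


class TestComputeTimeStep:
    def test_y_sol_default_rates(self):
        cfg = SimulationConfig(variant="Y-SOL", kon_micro=1e6, koff_micro=0.1)
        spec = compute_time_step(cfg)
        # ds_R = binding-sphere radius 3.5 nm, D_R = 90 µm²/s, d = 3
        assert spec.dt_R == pytest.approx(0.0035 ** 2 / (6 * 90), rel=1e-12)
        assert spec.dt_L == pytest.approx(0.0037 ** 2 / (6 * 100), rel=1e-12)
        assert spec.dt == pytest.approx(2.268e-8, rel=1e-3)
        assert spec.p_on == pytest.approx(1e6 * spec.dt)

    def test_membrane_receptor_uses_2d_diffusion_time(self):
        cfg = SimulationConfig(variant="Y-MEM", kon_micro=1e6, koff_micro=0.1)
        spec = compute_time_step(cfg)
        # d = 2 and D_R = 0.05 µm²/s on the membrane
        assert spec.dt_R == pytest.approx(0.0035 ** 2 / (4 * 0.05), rel=1e-12)
        # the ligand still limits the global step
        assert spec.dt == pytest.approx(spec.dt_L, rel=1e-12)

    def test_rate_term_can_govern_the_step(self):
        cfg = SimulationConfig(variant="Y-SOL", kon_micro=1e10,
                               koff_micro=0.1)
        assert compute_time_step(cfg).dt == pytest.approx(1e-10)

    def test_override_beyond_diffusion_bound_rejected(self):
        cfg = SimulationConfig(variant="O-SOL", dt_override=1.0)
        with pytest.raises(ConfigurationError, match="dt_override"):
            compute_time_step(cfg)

    def test_probabilities_are_valid(self):
        spec = compute_time_step(SimulationConfig(variant="O-SOL",
                                                  kon_micro=2.5e7))
        assert 0 < spec.p_on <= 1
        assert 0 < spec.p_off <= 1


class TestDiffusionStep:
    def test_exact_step_magnitude_3d(self, rng):
        x0 = np.zeros(3)
        expected = np.sqrt(6 * 90 * 1e-8)
        for _ in range(20):
            x1 = diffusion_step(x0, 3, 90.0, 1e-8, rng)
            assert np.linalg.norm(x1 - x0) == pytest.approx(expected,
                                                            rel=1e-12)

    def test_isotropy_of_directions(self, rng):
        n = 20_000
        step = np.sqrt(6 * 90 * 1e-8)
        total = np.zeros(3)
        for _ in range(n):
            total += diffusion_step(np.zeros(3), 3, 90.0, 1e-8, rng)
        assert np.all(np.abs(total / n) < 0.01 * step)

    def test_membrane_step_stays_on_the_sphere(self, rng):
        R = 0.5
        x = np.array([0.0, 0.0, R])
        for _ in range(50):
            x = diffusion_step(x, 2, 0.05, 1e-6, rng, R_cell=R)
            assert np.linalg.norm(x) == pytest.approx(R, abs=1e-9)

    def test_membrane_step_magnitude_uses_d2(self, rng):
        R = 0.5
        x0 = np.array([0.0, 0.0, R])
        x1 = diffusion_step(x0, 2, 0.05, 1e-6, rng, R_cell=R)
        # chord length equals the tangent step up to curvature correction
        expected = np.sqrt(4 * 0.05 * 1e-6)
        assert np.linalg.norm(x1 - x0) == pytest.approx(expected, rel=1e-4)


class TestBoundaries:
    def test_interior_position_unchanged(self, rng):
        x = np.array([0.3, 0.0, 0.0])
        assert np.array_equal(apply_outer_boundary(x, 1.0, rng), x)

    def test_reinsertion_lands_on_the_boundary_sphere(self, rng):
        for _ in range(50):
            out = apply_outer_boundary(np.array([1.2, 0.0, 0.0]), 1.0, rng)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)

    def test_reinsertion_is_uniform_on_the_sphere(self, rng):
        z = np.array([apply_outer_boundary(np.array([2.0, 0, 0]), 1.0,
                                           rng)[2]
                      for _ in range(10_000)])
        from scipy.stats import kstest
        assert kstest(z, "uniform", args=(-1, 2)).pvalue > 0.001

    def test_cell_reflection(self):
        assert np.allclose(
            apply_cell_boundary(np.array([0.4, 0.0, 0.0]), 0.5),
            [0.6, 0.0, 0.0])
        x_on = np.array([0.5, 0.0, 0.0])
        assert np.allclose(apply_cell_boundary(x_on, 0.5), x_on)
        x_out = np.array([0.7, 0.0, 0.0])
        assert np.array_equal(apply_cell_boundary(x_out, 0.5), x_out)

    def test_pathological_reflection_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_cell_boundary(np.array([1e-4, 0, 0]), 0.5, R_env=0.6)


class TestNeighborList:
    def test_matches_brute_force_contact_pairs(self, rng):
        mols = [(rng.uniform(-1, 1, 3), rng.uniform(0.02, 0.08))
                for _ in range(50)]
        cutoff = 0.05
        nl = build_neighbor_list(mols, cutoff)
        for i, (ci, ri) in enumerate(mols):
            brute = {j for j, (cj, rj) in enumerate(mols) if j != i
                     and np.linalg.norm(ci - cj) < ri + rj + cutoff}
            assert brute <= set(nl.query(i))  # superset contract

    def test_empty_system(self):
        assert build_neighbor_list([], 0.1).anchors.shape[0] == 0

    def test_distant_pair_not_neighbors(self):
        nl = build_neighbor_list([(np.zeros(3), 0.01),
                                  (np.array([5.0, 0, 0]), 0.01)], 0.1)
        assert nl.query(0) == [] and nl.query(1) == []


class TestBindingTrials:
    def _pair(self, dist=0.0087):
        rec = ReceptorState(id=0, position=np.zeros(3),
                            site_occupancy=[None])
        lig = LigandState(id=7, position=np.array([dist, 0.0, 0.0]),
                          radius=0.0037)
        return rec, lig

    def test_certain_binding_on_contact(self, rng):
        rec, lig = self._pair()
        assert attempt_binding(rec, 0, lig, 1.0, rng, site_radius=0.005)
        assert rec.site_occupancy[0] == 7
        assert lig.bound_to == (0, 0)
        # snapped to point contact
        assert np.linalg.norm(lig.position) == pytest.approx(0.0087)

    def test_zero_probability_never_binds(self, rng):
        rec, lig = self._pair()
        for _ in range(200):
            assert not attempt_binding(rec, 0, lig, 0.0, rng,
                                       site_radius=0.005)
        assert lig.bound_to is None

    def test_precondition_violations_raise(self, rng):
        rec, lig = self._pair()
        lig2 = LigandState(id=8, position=lig.position.copy(), radius=0.0037)
        attempt_binding(rec, 0, lig, 1.0, rng, site_radius=0.005)
        with pytest.raises(RuntimeError):
            attempt_binding(rec, 0, lig, 1.0, rng, site_radius=0.005)
        with pytest.raises(RuntimeError):  # monovalent receptor is full
            attempt_binding(rec, 0, lig2, 1.0, rng, site_radius=0.005)
        far = LigandState(id=9, position=np.array([1.0, 0, 0]),
                          radius=0.0037)
        rec2 = ReceptorState(id=1, position=np.zeros(3),
                             site_occupancy=[None])
        with pytest.raises(RuntimeError, match="contact"):
            attempt_binding(rec2, 0, far, 1.0, rng, site_radius=0.005)

    def test_unbinding_trials(self, rng):
        rec, lig = self._pair()
        attempt_binding(rec, 0, lig, 1.0, rng, site_radius=0.005)
        for _ in range(100):
            assert not attempt_unbinding(rec, 0, 0.0, rng, ligand=lig)
        assert attempt_unbinding(rec, 0, 1.0, rng, ligand=lig)
        assert rec.site_occupancy[0] is None and lig.bound_to is None
        with pytest.raises(RuntimeError):
            attempt_unbinding(rec, 0, 1.0, rng)


class TestDownscaling:
    def test_printed_factor_ten(self):
        cfg = SimulationConfig(N_R_phys=100_000, N_L_phys=100_000,
                               R_cell=5.0)
        scaled = downscale_config(cfg, 1e-2)
        assert scaled.N_R == 1000          # 10^5 receptors -> order 10^3
        assert scaled.R_cell_scaled == pytest.approx(0.5)   # 5 µm / 10

    def test_identity_at_s_one(self):
        cfg = SimulationConfig()
        same = downscale_config(cfg, 1.0)
        assert same.N_R == cfg.N_R_phys
        assert same.R_env_scaled == pytest.approx(cfg.R_env)

    @pytest.mark.parametrize("s", [1.0, 0.1, 1e-2, 1e-3])
    def test_bulk_concentration_is_preserved(self, s):
        cfg = SimulationConfig(N_L_phys=100_000)
        scaled = downscale_config(cfg, s)
        conc_phys = cfg.N_L_phys / cfg.free_volume_phys
        conc_scaled = scaled.N_L / scaled.free_volume
        assert conc_scaled == pytest.approx(conc_phys, rel=1e-9)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            downscale_config(SimulationConfig(), 0.0)

    def test_non_integral_count_rounds_with_warning(self):
        cfg = SimulationConfig(N_R_phys=12345, N_L_phys=100_000)
        with pytest.warns(UserWarning, match="rounded"):
            downscale_config(cfg, 1e-2).N_R
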