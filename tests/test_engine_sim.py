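"""Whole-simulation behavior: limits, conservation, determinism,
equilibrium consistency with the mass-action model."""

import dataclasses

import numpy as np
import pytest

from rlbind import SimulationConfig, run_simulation
from rlbind.experiments import fit_trajectories, run_replicates
from rlbind.ode import MacroKinetics, equilibrium_C


def with_(cfg, **kw):
    return dataclasses.replace(cfg, **kw)


class TestLimits:
    def test_zero_on_rate_never_forms_complexes(self, toy_o_sol):
        traj = run_simulation(with_(toy_o_sol, kon_micro=0.0, t_end=0.1,
                                    sample_interval=0.01))
        assert np.all(traj.n_complex == 0)
        assert np.all(traj.n_bound_ligands == 0)

    def test_irreversible_binding_saturates_receptors(self, toy_o_sol):
        # koff = 0, ligand excess: every receptor ends up occupied
        cfg = with_(toy_o_sol, koff_micro=0.0, kon_micro=1e5,
                    N_R_phys=50, N_L_phys=150, t_end=2.5,
                    sample_interval=0.05)
        traj = run_simulation(cfg)
        assert traj.n_complex[-1] == 50
        # complexes never dissolve on the way
        assert np.all(np.diff(traj.n_complex) >= 0)


class TestConservation:
    def test_molecule_counts_constant(self, toy_o_sol):
        cfg = with_(toy_o_sol, t_end=0.5, sample_interval=0.01,
                    kon_micro=1e5)
        traj = run_simulation(cfg)
        assert np.all(traj.n_bound_ligands + traj.n_free_L == cfg.N_L)
        assert np.all(traj.n_complex + traj.n_free_R == cfg.N_R)

    def test_monovalent_complex_equals_bound_ligand_count(self, toy_o_sol):
        traj = run_simulation(with_(toy_o_sol, t_end=0.5,
                                    sample_interval=0.01, kon_micro=1e5))
        assert np.array_equal(traj.n_complex, traj.n_bound_ligands)


class TestReproducibility:
    def test_identical_seed_identical_trajectory(self, toy_o_sol):
        cfg = with_(toy_o_sol, t_end=0.2, sample_interval=0.01)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.n_complex, b.n_complex)
        assert np.array_equal(a.n_bound_ligands, b.n_bound_ligands)

    def test_different_seed_diverges(self, toy_o_sol):
        cfg = with_(toy_o_sol, t_end=0.5, sample_interval=0.01)
        a = run_simulation(cfg)
        b = run_simulation(with_(cfg, seed=cfg.seed + 1))
        assert not np.array_equal(a.n_complex, b.n_complex)


class TestEquilibriumConsistency:
    def test_long_time_mean_matches_fitted_ode_equilibrium(self, toy_o_sol):
        """Monovalent soluble toy system: the tail mean complex count
        agrees with C- of the mass-action model evaluated at the fitted
        kon_macro, within 3 SEM over 5 seeds."""
        trajs = run_replicates(toy_o_sol, 5)
        fit = fit_trajectories(trajs)
        V = trajs[0].free_volume
        kin = MacroKinetics(fit.kon_macro_hat, toy_o_sol.koff_micro,
                            toy_o_sol.N_R / V, toy_o_sol.N_L / V)
        expected = equilibrium_C(kin) * V
        tail = np.array([tr.n_complex[tr.times > 1.5].mean()
                         for tr in trajs])
        sem = tail.std(ddof=1) / np.sqrt(tail.size)
        assert abs(tail.mean() - expected) <= 3.0 * max(sem, 0.5)
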