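"""Shared fixtures: toy-scale configurations that resolve the physics in
seconds (enlarged molecules, reduced counts)."""

import dataclasses

import numpy as np
import pytest

from rlbind import SimulationConfig, YMorphology


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture
def toy_o_sol():
    """Spherical soluble receptors with enlarged molecules.

    r_R = 30 nm, r_L = 20 nm, D = 10 µm²/s each, 100 + 100 molecules in
    ~30 µm³ of free volume: the Collins-Kimball benchmark conditions.
    """
    return SimulationConfig(
        variant="O-SOL", kon_micro=1e4, koff_micro=0.1,
        D_R=10.0, D_L=10.0, N_R_phys=100, N_L_phys=100, s=1.0,
        R_cell=0.15, R_env=1.9302, o_binding_radius=0.03, r_L=0.02,
        t_end=2.0, sample_interval=0.02, seed=101)


@pytest.fixture
def toy_y_morphology():
    """Y morphology scaled up 5x for fast toy simulations."""
    return YMorphology(stem_length=0.035, arm_length=0.035,
                       arm_half_angle=50.0, body_sphere_radius=0.010,
                       binding_sphere_radius=0.0175)


@pytest.fixture
def toy_y_sol(toy_y_morphology):
    return SimulationConfig(
        variant="Y-SOL", kon_micro=1e5, koff_micro=0.1,
        D_R=10.0, D_L=10.0, N_R_phys=60, N_L_phys=120, s=1.0,
        R_cell=0.15, R_env=1.9302, r_L=0.0185,
        morphology=toy_y_morphology,
        t_end=1.5, sample_interval=0.05, seed=7)


def with_(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
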