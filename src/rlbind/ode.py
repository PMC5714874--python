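"""Macroscopic mass-action model of reversible receptor-ligand binding.

The reaction R + L <=> C with on-rate ``kon`` (µm³/s) and off-rate
``koff`` (1/s) reduces, with C(0) = 0 and the conservation relations
R(t) = R0 - C(t), L(t) = L0 - C(t), to the single Riccati equation

    dC/dt = alpha*C^2 - beta*C + gamma,
    alpha = kon,  beta = koff + kon*(R0 + L0),  gamma = kon*R0*L0,

whose closed-form solution in terms of the roots C± of the right-hand
side is

    C(t) = C- * C+ * (1 - e^{x t}) / (C- - C+ * e^{x t}),
    x = alpha * (C+ - C-),

monotonically approaching the equilibrium C- from below.  Concentrations
are in 1/µm³ throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["MacroKinetics", "AnalyticKinetics", "analytic_C",
           "equilibrium_C", "integrate_ode"]

# x = alpha*(C+ - C-) * t beyond which C(t) is C- to double precision
_EXP_OVERFLOW = 700.0
# relative discriminant below which the equal-root limit is used
_DEGENERATE_REL = 1e-12


@dataclass(frozen=True)
class MacroKinetics:
    """Macroscopic rate parameters and initial concentrations."""

    kon_macro: float   # µm³/s
    koff_macro: float  # 1/s
    R0: float          # 1/µm³
    L0: float          # 1/µm³

    def __post_init__(self) -> None:
        if self.kon_macro < 0 or self.koff_macro < 0:
            raise ValueError("rates must be non-negative")
        if self.R0 < 0 or self.L0 < 0:
            raise ValueError("initial concentrations must be non-negative")

    @property
    def Ka(self) -> float:
        """Association constant kon/koff (µm³)."""
        return self.kon_macro / self.koff_macro


@dataclass(frozen=True)
class AnalyticKinetics:
    """Constants of the closed-form solution."""

    alpha: float    # µm³/s
    beta: float     # 1/s
    gamma: float    # 1/(µm³ s)
    C_plus: float   # 1/µm³
    C_minus: float  # 1/µm³

    @classmethod
    def from_kinetics(cls, kin: MacroKinetics) -> "AnalyticKinetics":
        alpha = kin.kon_macro
        beta = kin.koff_macro + kin.kon_macro * (kin.R0 + kin.L0)
        gamma = kin.kon_macro * kin.R0 * kin.L0
        if alpha == 0.0:
            return cls(0.0, beta, gamma, np.inf, 0.0)
        mid = beta / (2.0 * alpha)
        disc = mid * mid - gamma / alpha
        disc = max(disc, 0.0)
        c_plus = mid + np.sqrt(disc)
        # stable small root via the product identity C- * C+ = gamma/alpha
        c_minus = (gamma / alpha) / c_plus if c_plus > 0 else 0.0
        return cls(alpha, beta, gamma, c_plus, c_minus)


def analytic_C(t, kin: MacroKinetics):
    """Closed-form complex concentration C(t) (1/µm³), C(0) = 0.

    Vectorized over ``t``; numerically stable for large t (returns the
    equilibrium C-) and handles the degenerate equal-root case
    (koff = 0, R0 = L0) by its analytic limit
    C(t) = C* - C*/(1 + alpha C* t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    ak = AnalyticKinetics.from_kinetics(kin)
    if ak.alpha == 0.0 or ak.gamma == 0.0:
        return np.zeros_like(t)

    cp, cm = ak.C_plus, ak.C_minus
    if not np.isfinite(cp):
        # alpha -> 0 pseudo-first-order limit: dC/dt = gamma - beta*C
        return (ak.gamma / ak.beta) * -np.expm1(-ak.beta * t)
    if cp - cm <= _DEGENERATE_REL * cp:
        # equal roots: dC/dt = alpha (C - C*)^2
        cstar = 0.5 * (cp + cm)
        return cstar - cstar / (1.0 + ak.alpha * cstar * t)

    x = ak.alpha * (cp - cm) * t
    # multiply through by e^{-x}: C = cm*cp*(e^{-x} - 1)/(cm*e^{-x} - cp)
    out = np.empty_like(t)
    big = x > _EXP_OVERFLOW
    out[big] = cm
    e = np.exp(-x[~big])
    out[~big] = cm * cp * (e - 1.0) / (cm * e - cp)
    return out + 0.0  # normalizes -0.0 at t = 0


def equilibrium_C(kin: MacroKinetics) -> float:
    """Equilibrium complex concentration C- (1/µm³).

    Satisfies the detailed-balance identity
    kon*(R0 - C)*(L0 - C) = koff*C exactly (to round-off).
    """
    return float(AnalyticKinetics.from_kinetics(kin).C_minus)


def integrate_ode(kin: MacroKinetics, t_grid) -> np.ndarray:
    """Adaptive numerical solution of dC/dt = alpha C² - beta C + gamma.

    Serves as an independent cross-check oracle for :func:`analytic_C`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    ak = AnalyticKinetics.from_kinetics(kin)

    def rhs(_t, c):
        return ak.alpha * c * c - ak.beta * c + ak.gamma

    t0 = 0.0 if t_grid[0] > 0 else t_grid[0]
    sol = solve_ivp(rhs, (t0, t_grid[-1]), [0.0], t_eval=t_grid,
                    method="LSODA", rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]
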