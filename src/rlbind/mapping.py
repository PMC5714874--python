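"""Mapping between microscopic and macroscopic binding rates.

The agent-based simulation is parameterized by the per-contact reaction
propensity ``kon_micro`` (1/s); the well-mixed mass-action model by the
rate constant ``kon_macro`` (µm³/s).  The bridge has three parts:

1. ``fit_kon_macro`` -- nonlinear least-squares fit of the closed-form
   mass-action solution to a simulated complex-concentration time
   series, with ``koff`` held fixed (it is the same microscopically and
   macroscopically), so ``kon_macro`` is the only free parameter.
2. ``fit_hill`` -- the empirical relation kon_macro(kon_micro) follows a
   Hill function a*k/(b+k) with upper limit ``a`` and half-saturation
   constant ``b``.
3. Collins-Kimball theory -- for spherical reactants in solution,
   kon_macro = ks*kappa/(ks+kappa) with the Smoluchowski diffusion-
   limited rate ks = 4*pi*(rR+rL)*(DR+DL) and the intrinsic rate
   kappa = Vr*kon_micro, Vr = (4/3)*pi*(rR+rL)^3.  Deviations of the
   simulation from the ideal theory are summarized by the scaling
   factors fs = a/ks (on ks) and fr = fs*ks/(b*Vr) (on Vr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .ode import MacroKinetics, analytic_C

__all__ = [
    "FitResult", "HillParams", "TheoryQuantities",
    "fit_kon_macro", "fit_hill", "hill",
    "smoluchowski_rate", "reaction_volume", "collins_kimball",
    "scaling_factors", "relative_difference",
]


@dataclass(frozen=True)
class FitResult:
    kon_macro_hat: float  # µm³/s
    sse: float            # (1/µm³)²
    n_points: int
    converged: bool


@dataclass(frozen=True)
class HillParams:
    a: float  # µm³/s, upper limit of kon_macro
    b: float  # 1/s, half-saturation constant in kon_micro

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Hill parameters must be positive")


@dataclass(frozen=True)
class TheoryQuantities:
    """Collins-Kimball quantities for a receptor-ligand pair."""

    r_R: float   # µm
    r_L: float   # µm
    D_R: float   # µm²/s
    D_L: float   # µm²/s
    fs: float = 1.0
    fr: float = 1.0

    @property
    def ks(self) -> float:
        return smoluchowski_rate(self.r_R, self.r_L, self.D_R, self.D_L)

    @property
    def Vr(self) -> float:
        return reaction_volume(self.r_R, self.r_L)

    def kappa(self, kon_micro: float) -> float:
        """Intrinsic reaction rate kappa = fr*Vr*kon_micro (µm³/s)."""
        return self.fr * self.Vr * kon_micro

    def kon_macro(self, kon_micro: float) -> float:
        """Scaled Collins-Kimball prediction fs*ks*kappa/(fs*ks+kappa)."""
        return collins_kimball(self.fs * self.ks, self.kappa(kon_micro))


def fit_kon_macro(times, concentrations, koff: float, R0: float, L0: float,
                  initial_guess: float | None = None) -> FitResult:
    """Least-squares estimate of kon_macro from a C(t) series.

    ``koff`` is fixed, not fitted.  The single parameter is optimized on
    a log scale so the iterate can never go negative.  The default
    initial guess is the secant estimate from the early-time slope,
    dC/dt(0) ~ kon*R0*L0.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be matching 1-d arrays")
    if t.size < 10:
        raise ValueError("need at least 10 data points spanning the transient")
    if R0 <= 0 or L0 <= 0:
        raise ValueError("R0 and L0 must be positive")

    if initial_guess is None:
        head = slice(1, max(3, t.size // 10))
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = c[head] / t[head]
        slope = np.nanmedian(slopes)
        initial_guess = slope / (R0 * L0) if slope > 0 else 1.0
    if not initial_guess > 0:
        raise ValueError("initial_guess must be positive")

    def resid(x):
        kin = MacroKinetics(float(np.exp(x[0])), koff, R0, L0)
        return analytic_C(t, kin) - c

    sol = least_squares(resid, x0=[np.log(initial_guess)], method="lm",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
    kon_hat = float(np.exp(sol.x[0]))
    sse = float(np.sum(sol.fun ** 2))
    return FitResult(kon_hat, sse, t.size, bool(sol.success))


def hill(kon_micro, params: HillParams):
    """Hill relation kon_macro = a*kon_micro/(b + kon_micro)."""
    k = np.asarray(kon_micro, dtype=float)
    return params.a * k / (params.b + k)


def fit_hill(points) -> HillParams:
    """Fit (a, b) of the Hill relation to (kon_micro, kon_macro) pairs.

    Warns if all points lie in the linear regime (kon_micro << b), where
    the upper limit ``a`` is unidentifiable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (kon_micro, kon_macro) points")
    k, km = pts[:, 0], pts[:, 1]
    if np.any(k <= 0) or np.any(km <= 0):
        raise ValueError("rates must be positive")

    a0 = 1.2 * km.max()
    b0 = float(k[np.argmin(np.abs(km - 0.5 * a0))])

    def resid(x):
        a, b = np.exp(x)
        return a * k / (b + k) - km

    sol = least_squares(resid, x0=np.log([a0, b0]), method="lm",
                        xtol=1e-14, ftol=1e-14, max_nfev=1000)
    a, b = np.exp(sol.x)
    if k.max() < 0.1 * b:
        import warnings
        warnings.warn(
            "all points lie in the linear regime kon_micro << b; the "
            "upper limit a is not identifiable", stacklevel=2)
    return HillParams(float(a), float(b))


def smoluchowski_rate(r_R: float, r_L: float, D_R: float, D_L: float) -> float:
    """Diffusion-controlled rate ks = 4*pi*(rL+rR)*(DL+DR) (µm³/s)."""
    if min(r_R, r_L) < 0 or min(D_R, D_L) < 0:
        raise ValueError("radii and diffusivities must be non-negative")
    return 4.0 * np.pi * (r_R + r_L) * (D_R + D_L)


def reaction_volume(r_R: float, r_L: float) -> float:
    """Contact-shell volume Vr = (4/3)*pi*(rR+rL)^3 (µm³)."""
    if min(r_R, r_L) < 0:
        raise ValueError("radii must be non-negative")
    return (4.0 / 3.0) * np.pi * (r_R + r_L) ** 3


def collins_kimball(ks: float, kappa: float) -> float:
    """Interpolated rate ks*kappa/(ks+kappa) (µm³/s)."""
    if ks < 0 or kappa < 0 or ks + kappa == 0:
        raise ValueError("ks and kappa must be non-negative, not both zero")
    return ks * kappa / (ks + kappa)


def scaling_factors(hill_params: HillParams,
                    theory: TheoryQuantities) -> tuple[float, float]:
    """Scaling factors (fs, fr) relating a fitted Hill curve to theory.

    fs = a/ks rescales the diffusion-limited plateau; fr = fs*ks/(b*Vr)
    rescales the reaction volume (fr < 1 reflects the loss of reactive
    configurations to excluded volume).
    """
    ks, vr = theory.ks, theory.Vr
    if ks <= 0 or vr <= 0:
        raise ValueError("theory requires positive ks and Vr")
    fs = hill_params.a / ks
    fr = fs * ks / (hill_params.b * vr)
    return fs, fr


def relative_difference(traj_A, traj_B) -> np.ndarray:
    """Per-sample relative difference (B - A)/B of bound-ligand series.

    ``traj_A`` and ``traj_B`` are Trajectory objects or arrays on a
    shared time grid; for the membrane-vs-solution comparison pass the
    membrane variant as A and the soluble variant as B so the series is
    normalized by the soluble value.  Samples with zero denominator
    (e.g. t = 0) are returned as NaN.
    """
    a = np.asarray(getattr(traj_A, "n_bound_ligands", traj_A), dtype=float)
    b = np.asarray(getattr(traj_B, "n_bound_ligands", traj_B), dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectories must share a time grid")
    ta = getattr(traj_A, "times", None)
    tb = getattr(traj_B, "times", None)
    if ta is not None and tb is not None and not np.allclose(ta, tb):
        raise ValueError("trajectories must share a time grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (b - a) / b
    out[b == 0] = np.nan
    return out
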