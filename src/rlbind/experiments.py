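"""Experiment orchestration: replicate ensembles, rate scans, valency
comparisons.

A *scan* runs replicate simulations over a grid of microscopic binding
rates for one or more model variants, fits the macroscopic rate
``kon_macro`` to the pooled mean trajectory of each grid cell, then fits
the Hill relation kon_macro(kon_micro) and derives the Collins-Kimball
scaling factors (fs, fr) per variant.

Seeding is deterministic: replicate ``r`` of any cell uses
``base_seed + r``, so every published number is re-derivable from the
plan alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mapping
from .engine import ConfigurationError, SimulationConfig, Trajectory, run_simulation

__all__ = ["ExperimentPlan", "run_replicates", "pool_trajectories",
           "fit_trajectories", "run_scan", "compare_valency"]

# studied range of microscopic binding rates (1/s)
KON_MICRO_RANGE = (1e4, 2.5e7)
DEFAULT_GRID = (1e4, 1e5, 5e5, 1e6, 5e6, 1e7, 2.5e7)


@dataclass(frozen=True)
class ExperimentPlan:
    """A scan/comparison experiment over variants, valencies and rates."""

    base_config: SimulationConfig
    kon_micro_grid: tuple = DEFAULT_GRID
    replicates: int = 5
    variants: tuple = ("O-SOL",)
    valencies: tuple = (1,)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        lo, hi = KON_MICRO_RANGE
        outside = [k for k in self.kon_micro_grid if not lo <= k <= hi]
        if outside:
            import warnings
            warnings.warn(
                f"kon_micro values outside the studied range "
                f"[{lo:g}, {hi:g}] 1/s: {outside}", stacklevel=2)
        for v in self.variants:
            if v not in ("O-SOL", "O-MEM", "Y-SOL", "Y-MEM"):
                raise ConfigurationError(f"unknown variant {v!r}")
        for va in self.valencies:
            if va not in (1, 2):
                raise ConfigurationError("valency must be 1 or 2")


def run_replicates(config: SimulationConfig, n: int,
                   base_seed: int | None = None) -> list[Trajectory]:
    """Run ``n`` replicate simulations with seeds base_seed + r."""
    seed0 = config.seed if base_seed is None else base_seed
    out = []
    for r in range(n):
        out.append(run_simulation(dataclasses.replace(config, seed=seed0 + r)))
    return out


def pool_trajectories(trajectories: list[Trajectory]) -> Trajectory:
    """Mean trajectory of replicates sharing a time grid."""
    t0 = trajectories[0]
    for tr in trajectories[1:]:
        if not np.allclose(tr.times, t0.times):
            raise ValueError("replicates do not share a time grid")
    mean = lambda attr: np.mean([getattr(tr, attr) for tr in trajectories],
                                axis=0)
    return Trajectory(
        times=t0.times.copy(),
        n_complex=mean("n_complex"),
        n_bound_ligands=mean("n_bound_ligands"),
        n_free_R=mean("n_free_R"),
        n_free_L=mean("n_free_L"),
        free_volume=t0.free_volume,
        config=t0.config,
        stats={"pooled_from": len(trajectories)},
    )


def fit_trajectories(trajectories: list[Trajectory],
                     koff: float | None = None) -> mapping.FitResult:
    """kon_macro fit to the pooled mean of replicate trajectories."""
    pooled = pool_trajectories(trajectories)
    cfg = pooled.config
    if koff is None:
        koff = cfg.koff_micro  # macroscopic off-rate equals microscopic
    V = pooled.free_volume
    return mapping.fit_kon_macro(pooled.times, pooled.conc_complex,
                                 koff, cfg.N_R / V, cfg.N_L / V)


def run_scan(plan: ExperimentPlan):
    """Full micro-to-macro scan.

    Returns ``(scan_frame, summaries)``: one row per (variant, valency,
    kon_micro) with the fitted kon_macro, and per-(variant, valency)
    Hill parameters with Collins-Kimball scaling factors.  Failing grid
    cells are recorded with an error message instead of aborting the
    scan.  Results are also written to ``plan.output_dir`` if set.
    """
    rows = []
    summaries = {}
    for variant in plan.variants:
        for valency in plan.valencies:
            if valency == 2 and not variant.startswith("Y"):
                continue
            points = []
            for kon in plan.kon_micro_grid:
                # keep an explicit D_R unless the dimensionality changes,
                # then fall back to the variant default
                d_r = plan.base_config.D_R
                if variant.endswith("MEM") != plan.base_config.membrane:
                    d_r = None
                cfg = dataclasses.replace(plan.base_config, variant=variant,
                                          valency=valency, kon_micro=kon,
                                          D_R=d_r)
                try:
                    trajs = run_replicates(cfg, plan.replicates)
                    fit = fit_trajectories(trajs)
                    rows.append({
                        "variant": variant, "valency": valency,
                        "kon_micro": kon,
                        "kon_macro_hat": fit.kon_macro_hat,
                        "sse": fit.sse,
                        "n_replicates": plan.replicates,
                        "error": "",
                    })
                    points.append((kon, fit.kon_macro_hat))
                except Exception as exc:  # keep scanning other cells
                    rows.append({
                        "variant": variant, "valency": valency,
                        "kon_micro": kon, "kon_macro_hat": np.nan,
                        "sse": np.nan, "n_replicates": plan.replicates,
                        "error": str(exc),
                    })
            key = f"{variant}-v{valency}"
            if len(points) >= 3:
                hill = mapping.fit_hill(points)
                theory = _theory_for(plan.base_config)
                fs, fr = mapping.scaling_factors(hill, theory)
                summaries[key] = {
                    "a": hill.a, "b": hill.b,
                    "ks": theory.ks, "Vr": theory.Vr,
                    "fs": fs, "fr": fr,
                }
    frame = pd.DataFrame(rows)
    if plan.output_dir:
        out = Path(plan.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "scan.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(_with_provenance(summaries, plan), fh, indent=2)
    return frame, summaries


def _theory_for(config: SimulationConfig) -> mapping.TheoryQuantities:
    """Collins-Kimball inputs: the spherical receptor's binding radius
    (the theory addresses spherical reactants in solution)."""
    return mapping.TheoryQuantities(
        r_R=config.o_binding_radius, r_L=config.r_L,
        D_R=90.0 if config.D_R is None else config.D_R, D_L=config.D_L)


def _with_provenance(payload: dict, plan: ExperimentPlan) -> dict:
    return {
        "results": payload,
        "plan": {
            "kon_micro_grid": list(plan.kon_micro_grid),
            "replicates": plan.replicates,
            "variants": list(plan.variants),
            "valencies": list(plan.valencies),
            "base_seed": plan.base_config.seed,
            "s": plan.base_config.s,
            "koff_micro": plan.base_config.koff_micro,
        },
    }


def compare_valency(plan: ExperimentPlan, kon_micro: float | None = None,
                    doubled_monovalent: bool = False):
    """Bound-ligand kinetics of mono- vs bivalent Y receptors.

    Runs the plan's Y variants at one kon_micro with valency 1 and 2
    (same seed ensemble) and, optionally, the control with twice the
    monovalent receptor count.  Returns a tidy frame of pooled
    bound-ligand counts per (variant, mode, time) plus the
    membrane-vs-solution relative-difference series per mode when both
    Y variants are present.
    """
    kon = kon_micro if kon_micro is not None else plan.base_config.kon_micro
    variants = [v for v in plan.variants if v.startswith("Y")]
    if not variants:
        raise ConfigurationError("compare_valency requires Y variants")
    rows = []
    pooled = {}
    for variant in variants:
        modes = [("monovalent", 1, 1.0), ("bivalent", 2, 1.0)]
        if doubled_monovalent:
            modes.append(("monovalent-2NR", 1, 2.0))
        for mode, valency, nr_factor in modes:
            d_r = plan.base_config.D_R
            if variant.endswith("MEM") != plan.base_config.membrane:
                d_r = None
            cfg = dataclasses.replace(
                plan.base_config, variant=variant, valency=valency,
                kon_micro=kon, D_R=d_r,
                N_R_phys=int(round(plan.base_config.N_R_phys * nr_factor)))
            trajs = run_replicates(cfg, plan.replicates)
            pool = pool_trajectories(trajs)
            pooled[(variant, mode)] = pool
            for t, nb in zip(pool.times, pool.n_bound_ligands):
                rows.append({"variant": variant, "mode": mode,
                             "kon_micro": kon, "time_s": t,
                             "n_bound_ligands": nb,
                             "conc_bound_per_um3": nb / pool.free_volume})
    frame = pd.DataFrame(rows)

    reldiff = {}
    if "Y-SOL" in variants and "Y-MEM" in variants:
        for mode in {m for (_, m) in pooled}:
            sol = pooled[("Y-SOL", mode)]
            mem = pooled[("Y-MEM", mode)]
            reldiff[mode] = mapping.relative_difference(mem, sol)
    if plan.output_dir:
        out = Path(plan.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "valency_comparison.csv", index=False)
    return frame, pooled, reldiff
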