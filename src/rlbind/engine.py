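"""Agent-based simulation of receptor-ligand binding kinetics.

The model system is a spherical environment (radius ``R_env``) with a
cell (radius ``R_cell``) at its center.  Ligands are soluble spheres;
receptors are spherical (``O``) or Y-shaped antibody-like molecules
(``Y``), either soluble (``SOL``, diffusing in 3-D) or membrane-anchored
(``MEM``, diffusing in 2-D on the cell surface).  All molecules take
fixed-length diffusive steps ``Δs = sqrt(2 d D Δt)`` in uniformly random
directions; upon contact of a ligand with a free binding sphere, binding
occurs with probability ``p_on = kon_micro*Δt`` and an occupied site
releases its ligand with probability ``p_off = koff_micro*Δt`` per step.
Molecules cannot interpenetrate (push-back to point contact); the outer
boundary is random-periodic, the cell surface reflecting, so molecule
numbers are conserved.

Because simulating physiological molecule numbers (~1e5) at the time
step required to resolve molecular contacts is intractable, systems are
jointly down-scaled by a factor ``s``: molecule counts and the free
volume scale with ``s`` (bulk concentrations preserved) and the cell
radius with ``sqrt(s)`` (receptor surface density preserved).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import YMorphology

__all__ = [
    "VARIANTS", "SimulationConfig", "StepSpec", "ReceptorState",
    "LigandState", "Trajectory", "compute_time_step", "downscale_config",
    "diffusion_step", "apply_outer_boundary", "apply_cell_boundary",
    "build_neighbor_list", "NeighborList", "attempt_binding",
    "attempt_unbinding", "run_simulation",
]

VARIANTS = ("O-SOL", "O-MEM", "Y-SOL", "Y-MEM")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulation experiment.

    Counts, ``R_env`` and ``R_cell`` are *physiological* values; the
    down-scaling factor ``s`` maps them to the simulated system (see
    module docstring).  Rates in 1/s, lengths in µm, diffusivities in
    µm²/s, times in s.
    """

    variant: str = "O-SOL"
    valency: int = 1
    kon_micro: float = 1e6
    koff_micro: float = 0.1
    D_R: float | None = None       # default: 90 (SOL) or 0.05 (MEM)
    D_L: float = 100.0
    N_R_phys: int = 100_000
    N_L_phys: int = 100_000
    s: float = 1e-2
    R_env: float = 10.9707         # gives 50 µm³ free volume at s=1e-2
    R_cell: float = 5.0
    t_end: float = 1.0
    sample_interval: float | None = None   # default: t_end/200
    seed: int = 1
    dt_override: float | None = None
    morphology: YMorphology = field(default_factory=YMorphology)
    o_binding_radius: float = 0.005        # O-variant binding sphere (µm)
    r_L: float = 0.0037                    # ligand radius (µm)
    contact_tol: float = 1e-4              # binding-eligibility shell (µm)
    start_bound: bool = False
    audit_every: int = 0                   # 0: no brute-force overlap audit

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.valency not in (1, 2):
            raise ConfigurationError("valency must be 1 or 2")
        if self.valency == 2 and not self.variant.startswith("Y"):
            raise ConfigurationError("bivalent binding requires a Y variant")
        if self.D_R is None:
            object.__setattr__(self, "D_R", 0.05 if self.membrane else 90.0)
        bad = [n for n in ("D_R", "D_L", "R_env", "R_cell",
                           "t_end", "o_binding_radius", "r_L")
               if not getattr(self, n) > 0]
        if self.kon_micro < 0:
            bad.append("kon_micro")
        if self.koff_micro < 0:
            bad.append("koff_micro")
        if not (self.N_R_phys > 0 and self.N_L_phys > 0):
            bad.append("molecule counts")
        if not 0 < self.s <= 1:
            bad.append("s")
        if bad:
            raise ConfigurationError(f"invalid (non-positive) fields: {bad}")
        if self.R_cell >= self.R_env:
            raise ConfigurationError("R_cell must be smaller than R_env")
        if self.sample_interval is not None and not self.sample_interval > 0:
            raise ConfigurationError("sample_interval must be positive")

    # -- variant properties -------------------------------------------------
    @property
    def membrane(self) -> bool:
        return self.variant.endswith("MEM")

    @property
    def yshaped(self) -> bool:
        return self.variant.startswith("Y")

    @property
    def d_receptor(self) -> int:
        """Dimensionality of receptor motion (2 on the membrane, else 3)."""
        return 2 if self.membrane else 3

    @property
    def binding_radius(self) -> float:
        return (self.morphology.binding_sphere_radius if self.yshaped
                else self.o_binding_radius)

    # -- down-scaled system -------------------------------------------------
    def _scaled_count(self, n_phys: int) -> int:
        x = self.s * n_phys
        n = int(round(x))
        if abs(x - n) > 1e-9:
            warnings.warn(f"s*N = {x} is not integral; rounded to {n}",
                          stacklevel=3)
        return max(n, 1)

    @property
    def N_R(self) -> int:
        return self._scaled_count(self.N_R_phys)

    @property
    def N_L(self) -> int:
        return self._scaled_count(self.N_L_phys)

    @property
    def R_cell_scaled(self) -> float:
        """sqrt(s)-scaled cell radius (receptor surface density preserved)."""
        return np.sqrt(self.s) * self.R_cell

    @property
    def free_volume_phys(self) -> float:
        return (4.0 / 3.0) * np.pi * (self.R_env ** 3 - self.R_cell ** 3)

    @property
    def free_volume(self) -> float:
        """Down-scaled free volume s*(V_env - V_cell) in µm³."""
        return self.s * self.free_volume_phys

    @property
    def R_env_scaled(self) -> float:
        """Environment radius enclosing exactly the scaled free volume."""
        return (self.R_cell_scaled ** 3
                + self.free_volume / ((4.0 / 3.0) * np.pi)) ** (1.0 / 3.0)


def downscale_config(config: SimulationConfig, s: float) -> SimulationConfig:
    """Apply a down-scaling factor to the physiological system.

    Molecule counts and free volume scale with ``s`` (bulk concentration
    preserved); the cell radius scales with ``sqrt(s)`` (receptor surface
    density preserved).  ``s = 1`` is the identity.
    """
    if not 0 < s <= 1:
        raise ConfigurationError("downscaling factor must satisfy 0 < s <= 1")
    return dataclasses.replace(config, s=s)


@dataclass(frozen=True)
class StepSpec:
    """Time step and derived per-step quantities."""

    dt: float     # s
    dt_R: float   # s
    dt_L: float   # s
    ds_R: float   # µm, receptor step-resolution bound (binding radius)
    ds_L: float   # µm, ligand step-resolution bound (ligand radius)
    p_on: float
    p_off: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_on <= 1.0 and 0.0 <= self.p_off <= 1.0):
            raise ConfigurationError(
                f"per-step probabilities out of range: p_on={self.p_on}, "
                f"p_off={self.p_off}")
        if self.dt > min(self.dt_R, self.dt_L) * (1 + 1e-12):
            raise ConfigurationError(
                "dt exceeds the diffusion-resolution bound min(dt_R, dt_L)")


def compute_time_step(config: SimulationConfig) -> StepSpec:
    """Time step from the fastest rate and the diffusion resolution.

    The diffusive step of each species must not exceed its binding
    resolution (the binding-sphere radius for receptors, the ligand
    radius for ligands): dt_X = ds_X² / (2 d D_X).  The global step is
    dt = min(1/kon_micro, 1/koff_micro, dt_R, dt_L) so that p_on and
    p_off are valid probabilities.
    """
    ds_R = config.binding_radius
    ds_L = config.r_L
    dt_R = ds_R ** 2 / (2.0 * config.d_receptor * config.D_R)
    dt_L = ds_L ** 2 / (2.0 * 3 * config.D_L)
    candidates = [dt_R, dt_L]
    if config.kon_micro > 0:
        candidates.append(1.0 / config.kon_micro)
    if config.koff_micro > 0:
        candidates.append(1.0 / config.koff_micro)
    dt = min(candidates)
    if config.dt_override is not None:
        if config.dt_override > min(dt_R, dt_L):
            raise ConfigurationError(
                "dt_override exceeds the diffusion-resolution bound")
        dt = config.dt_override
    return StepSpec(dt=dt, dt_R=dt_R, dt_L=dt_L, ds_R=ds_R, ds_L=ds_L,
                    p_on=config.kon_micro * dt, p_off=config.koff_micro * dt)


# ---------------------------------------------------------------------------
# state containers


@dataclass
class ReceptorState:
    """One receptor: anchor position, orientation, site occupancy."""

    id: int
    position: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    site_occupancy: list = field(default_factory=lambda: [None])

    @property
    def n_bound(self) -> int:
        return sum(s is not None for s in self.site_occupancy)


@dataclass
class LigandState:
    """One ligand: position, radius, binding status."""

    id: int
    position: np.ndarray
    radius: float = 0.0037
    bound_to: tuple | None = None  # (receptor id, site index)


@dataclass
class Trajectory:
    """Sampled counts of a simulation run.

    ``n_complex`` counts receptors bound to at least one ligand;
    ``n_bound_ligands`` counts ligand molecules in complexes (for
    bivalent receptors a doubly-bound receptor is one complex but two
    bound ligands).  Concentrations are counts per free volume (1/µm³).
    """

    times: np.ndarray
    n_complex: np.ndarray
    n_bound_ligands: np.ndarray
    n_free_R: np.ndarray
    n_free_L: np.ndarray
    free_volume: float
    config: SimulationConfig | None = None
    stats: dict | None = None

    @property
    def conc_complex(self) -> np.ndarray:
        return self.n_complex / self.free_volume

    @property
    def conc_bound_ligands(self) -> np.ndarray:
        return self.n_bound_ligands / self.free_volume

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times,
            "n_complex": self.n_complex,
            "n_bound_ligands": self.n_bound_ligands,
            "n_free_R": self.n_free_R,
            "n_free_L": self.n_free_L,
            "conc_complex_per_um3": self.conc_complex,
        })


# ---------------------------------------------------------------------------
# elementary operations (reference implementations; the compiled kernel
# inlines equivalent logic)


def diffusion_step(position, d: int, D: float, dt: float,
                   rng: np.random.Generator, R_cell: float | None = None):
    """One fixed-length diffusive step Δs = sqrt(2 d D dt).

    ``d = 3``: uniformly random direction in space.  ``d = 2``: uniform
    direction in the tangent plane of the cell sphere at ``position``,
    followed by radial re-projection onto the surface (``R_cell``
    required).
    """
    position = np.asarray(position, dtype=float)
    if d not in (2, 3):
        raise ValueError("dimensionality must be 2 or 3")
    step = np.sqrt(2.0 * d * D * dt)
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    if d == 3:
        return position + step * u
    if R_cell is None:
        raise ValueError("2-D membrane step requires R_cell")
    n = position / np.linalg.norm(position)
    t = u - np.dot(u, n) * n
    t /= np.linalg.norm(t)
    moved = position + step * t
    return moved * (R_cell / np.linalg.norm(moved))


def apply_outer_boundary(position, R_env: float, rng: np.random.Generator):
    """Random-periodic outer boundary.

    A molecule beyond ``R_env`` re-enters at a uniformly random boundary
    point (the caller assigns the fresh identity); otherwise unchanged.
    """
    position = np.asarray(position, dtype=float)
    if np.linalg.norm(position) <= R_env:
        return position
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    return R_env * u


def apply_cell_boundary(position, R_cell: float, R_env: float | None = None):
    """Reflecting cell-surface boundary: mirror radially, |x| -> 2 R_cell - |x|."""
    position = np.asarray(position, dtype=float)
    r = np.linalg.norm(position)
    if r >= R_cell:
        return position
    reflected = position * ((2.0 * R_cell - r) / r)
    if R_env is not None and np.linalg.norm(reflected) > R_env:
        raise ConfigurationError(
            "reflected position exceeds R_env (pathological geometry)")
    return reflected


class NeighborList:
    """Pair index over molecules with spatially extended sphere sets.

    Guarantees that ``query(i)`` returns a superset of all molecules any
    of whose spheres lie within ``cutoff`` of molecule ``i``'s spheres,
    by matching anchor distances against ``reach_i + reach_j + cutoff``.
    """

    def __init__(self, anchors: np.ndarray, reaches: np.ndarray,
                 cutoff: float):
        from scipy.spatial import cKDTree

        self.anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
        self.reaches = np.asarray(reaches, dtype=float)
        self.cutoff = float(cutoff)
        n = self.anchors.shape[0]
        self._nb: list[list[int]] = [[] for _ in range(n)]
        if n > 1:
            tree = cKDTree(self.anchors)
            rmax = float(self.reaches.max()) if n else 0.0
            for i, j in tree.query_pairs(2 * rmax + self.cutoff):
                d = np.linalg.norm(self.anchors[i] - self.anchors[j])
                if d < self.reaches[i] + self.reaches[j] + self.cutoff:
                    self._nb[i].append(j)
                    self._nb[j].append(i)

    def query(self, i: int) -> list[int]:
        return self._nb[i]


def build_neighbor_list(molecules, cutoff: float) -> NeighborList:
    """Neighbor list over molecules given as (anchor, reach) pairs or
    objects with ``position``/``radius`` attributes."""
    anchors = []
    reaches = []
    for m in molecules:
        if hasattr(m, "position"):
            anchors.append(np.asarray(m.position, dtype=float))
            reaches.append(float(getattr(m, "radius", 0.0)))
        else:
            a, r = m
            anchors.append(np.asarray(a, dtype=float))
            reaches.append(float(r))
    if not anchors:
        return NeighborList(np.empty((0, 3)), np.empty(0), cutoff)
    return NeighborList(np.array(anchors), np.array(reaches), cutoff)


def attempt_binding(receptor: ReceptorState, site: int, ligand: LigandState,
                    p_on: float, rng: np.random.Generator,
                    site_center=None, site_radius: float | None = None,
                    contact_tol: float = 1e-4,
                    monovalent: bool = True) -> bool:
    """One acceptance-rejection binding trial at an eligible contact.

    Preconditions (violations raise): the ligand is free, the site is
    unoccupied (for monovalent receptors the whole receptor must be
    unoccupied), and the ligand touches the binding sphere within the
    contact shell.  On success the ligand is snapped to point contact
    and recorded as bound.
    """
    if ligand.bound_to is not None:
        raise RuntimeError("ligand is already bound")
    if receptor.site_occupancy[site] is not None:
        raise RuntimeError("site is already occupied")
    if monovalent and receptor.n_bound > 0:
        raise RuntimeError("monovalent receptor already carries a ligand")
    center = (np.asarray(site_center, dtype=float) if site_center is not None
              else receptor.position)
    radius = site_radius if site_radius is not None else 0.005
    delta = ligand.position - center
    dist = float(np.linalg.norm(delta))
    contact = radius + ligand.radius
    if dist > contact + contact_tol:
        raise RuntimeError("ligand is not in contact with the binding sphere")
    if rng.random() >= p_on:
        return False
    ligand.position = center + delta / dist * contact
    ligand.bound_to = (receptor.id, site)
    receptor.site_occupancy[site] = ligand.id
    return True


def attempt_unbinding(receptor: ReceptorState, site: int, p_off: float,
                      rng: np.random.Generator,
                      ligand: LigandState | None = None) -> bool:
    """One dissociation trial for an occupied site.

    On success the ligand is released at point contact (immediately
    eligible for rebinding; no refractory period).
    """
    if receptor.site_occupancy[site] is None:
        raise RuntimeError("site is not occupied")
    if rng.random() >= p_off:
        return False
    receptor.site_occupancy[site] = None
    if ligand is not None:
        ligand.bound_to = None
    return True


# ---------------------------------------------------------------------------
# full simulation


def _local_geometry(config: SimulationConfig):
    """Local sphere layout (sites first in the collision set).

    Returns (local_sites (K,3), local_colls (M,3), coll_radii (M,),
    reach_receptor).  The receptor reach covers the collision envelope
    under any rotation *including* bound ligands at point contact.
    """
    if config.yshaped:
        tips, colls, radii = config.morphology.local_spheres()
        if not config.membrane:
            # soluble Y: shift the local origin to the collision-sphere
            # centroid so diffusion and rotation act about the body center
            centroid = colls.mean(axis=0)
            tips = tips - centroid
            colls = colls - centroid
        local_sites = tips
    else:
        r = config.o_binding_radius
        if config.membrane:
            c = np.array([[0.0, 0.0, r]])   # tangent to the cell surface
        else:
            c = np.array([[0.0, 0.0, 0.0]])
        local_sites = c
        colls = c.copy()
        radii = np.array([r])
    env = np.linalg.norm(colls, axis=1) + radii
    site_env = (np.linalg.norm(local_sites, axis=1)
                + config.binding_radius + 2.0 * config.r_L)
    reach = float(max(env.max(), site_env.max()))
    return (np.ascontiguousarray(local_sites, dtype=float),
            np.ascontiguousarray(colls, dtype=float),
            np.ascontiguousarray(radii, dtype=float), reach)


def _sample_shell(rng, r_in, r_out, n):
    """Uniform random points in a spherical shell."""
    u = rng.random(n)
    r = (r_in ** 3 + u * (r_out ** 3 - r_in ** 3)) ** (1.0 / 3.0)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return r[:, None] * v


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one agent-based simulation and return its trajectory."""
    from . import _kernel

    spec = compute_time_step(config)
    NR, NL = config.N_R, config.N_L
    R_cell = config.R_cell_scaled
    R_env = config.R_env_scaled
    mem = 1 if config.membrane else 0
    ysh = 1 if config.yshaped else 0
    local_sites, local_colls, coll_radii, reach_R = _local_geometry(config)
    K = local_sites.shape[0]
    M = local_colls.shape[0]
    r_L = config.r_L
    contact = config.binding_radius + r_L

    step_R = np.sqrt(2.0 * config.d_receptor * config.D_R * spec.dt)
    step_L = np.sqrt(6.0 * config.D_L * spec.dt)

    n_steps = max(1, int(round(config.t_end / spec.dt)))
    sample_interval = config.sample_interval or config.t_end / 200.0
    sample_every = max(1, int(round(sample_interval / spec.dt)))
    n_samples = n_steps // sample_every + 1

    rng = np.random.default_rng(config.seed)

    # ---- state arrays ----
    N = NR + NL
    pos = np.empty((N, 3))
    psi = np.zeros(NR)
    quat = np.zeros((NR, 4))
    quat[:, 0] = 1.0
    rot = np.zeros((NR, 3, 3))
    site_world = np.empty((NR, K, 3))
    coll_world = np.empty((NR, M, 3))
    site_occ = np.full((NR, K), -1, dtype=np.int32)
    lb_rec = np.full(NL, -1, dtype=np.int32)
    lb_site = np.full(NL, -1, dtype=np.int32)
    bond_local = np.zeros((NL, 3))

    reach = np.empty(N)
    reach[:NR] = reach_R
    reach[NR:] = r_L

    # ---- placement ----
    from .geometry import sample_uniform_rotation

    def receptor_pose(i, anchor):
        if mem:
            psi[i] = rng.uniform(0.0, 2.0 * np.pi)
            R = np.empty((3, 3))
            _kernel._mem_frame(anchor, R_cell, psi[i], R)
        elif ysh:
            quat[i] = sample_uniform_rotation(rng).rotation
            R = np.empty((3, 3))
            _kernel._quat_to_rot(quat[i], R)
        else:
            R = np.eye(3)
        rot[i] = R
        site_world[i] = anchor + local_sites @ R.T
        coll_world[i] = anchor + local_colls @ R.T
        pos[i] = anchor

    def overlaps_placed(i_new, upto_r, upto_l):
        """Exact overlap of freshly posed receptor i_new vs placed ones."""
        if upto_r > 0:
            placed = coll_world[:upto_r].reshape(-1, 3)     # (upto_r*M, 3)
            pr = np.tile(coll_radii, upto_r)
            for m in range(M):
                d = np.linalg.norm(placed - coll_world[i_new, m], axis=1)
                if np.any(d < pr + coll_radii[m]):
                    return True
        if upto_l > 0:
            for m in range(M):
                d = np.linalg.norm(pos[NR:NR + upto_l]
                                   - coll_world[i_new, m], axis=1)
                if np.any(d < r_L + coll_radii[m]):
                    return True
        return False

    for i in range(NR):
        for _ in range(10000):
            if mem:
                n = rng.standard_normal(3)
                anchor = R_cell * n / np.linalg.norm(n)
            else:
                anchor = _sample_shell(rng, R_cell, R_env, 1)[0]
            receptor_pose(i, anchor)
            if not overlaps_placed(i, i, 0):
                break
        else:
            raise RuntimeError("failed to place receptors without overlap")

    for li in range(NL):
        if config.start_bound and li < NR:
            pos[NR + li] = coll_world[li, 0]  # replaced by the docked pose
            continue
        for _ in range(10000):
            p = _sample_shell(rng, R_cell, R_env, 1)[0]
            d_rec = np.linalg.norm(coll_world.reshape(-1, 3) - p, axis=1)
            if np.any(d_rec < np.tile(coll_radii, NR) + r_L):
                continue
            if li > 0:
                d_lig = np.linalg.norm(pos[NR:NR + li] - p, axis=1)
                if np.any(d_lig < 2 * r_L):
                    continue
            pos[NR + li] = p
            break
        else:
            raise RuntimeError("failed to place ligands without overlap")

    if config.start_bound:
        if NL < NR:
            raise ConfigurationError("start_bound requires N_L >= N_R")
        for i in range(NR):
            # ligand i docked at site 0, contact direction outward
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            if mem:
                u = pos[i] / np.linalg.norm(pos[i])  # radially outward
            site_occ[i, 0] = i
            lb_rec[i] = i
            lb_site[i] = 0
            bond_local[i] = rot[i].T @ u
            pos[NR + i] = site_world[i, 0] + contact * u

    # ---- neighbor machinery ----
    skin = max(0.05, 6.0 * max(step_R, step_L))
    cell_size = 2.0 * reach.max() + skin
    # cap the grid memory; larger cells only add neighbor candidates
    dim = min(max(1, int(2.0 * R_env / cell_size)), 64)
    cell_size = max(cell_size, 2.0 * R_env / dim)
    maxnb = 160
    nb = np.empty((N, maxnb), dtype=np.int32)
    nbcnt = np.zeros(N, dtype=np.int32)
    ref_pos = np.empty((N, 3))
    cell_head = np.full(dim ** 3, -1, dtype=np.int32)
    cell_stamp = np.zeros(dim ** 3, dtype=np.int32)
    nxt = np.empty(N, dtype=np.int32)

    out_complex = np.zeros(n_samples, dtype=np.int64)
    out_bound = np.zeros(n_samples, dtype=np.int64)
    stats = np.zeros(6)

    kernel_seed = int((config.seed * 2654435761 + 97) % 2_147_483_647)
    _kernel.run_core(
        NR, NL, mem, ysh, config.valency,
        n_steps, sample_every, spec.dt, spec.p_on, spec.p_off, step_R, step_L,
        R_cell, R_env, config.binding_radius, r_L, config.contact_tol,
        local_sites, local_colls, coll_radii,
        pos, psi, quat, rot, site_world, coll_world, site_occ,
        lb_rec, lb_site, bond_local,
        reach, skin, nb, nbcnt, ref_pos, cell_head, cell_stamp, nxt,
        dim, cell_size,
        kernel_seed, config.audit_every,
        out_complex, out_bound, stats,
    )
    if stats[5] == 1.0:
        raise RuntimeError("neighbor-list capacity exceeded")
    if stats[5] == 2.0:
        raise RuntimeError("boundary re-insertion failed to find free space")

    times = np.arange(n_samples) * sample_every * spec.dt
    # conservation audit (fatal if molecules were created or destroyed)
    n_bound_now = int(np.sum(lb_rec >= 0))
    if int(np.sum(site_occ >= 0)) != n_bound_now:
        raise RuntimeError("occupancy bookkeeping diverged")
    return Trajectory(
        times=times,
        n_complex=out_complex,
        n_bound_ligands=out_bound,
        n_free_R=NR - out_complex,
        n_free_L=NL - out_bound,
        free_volume=config.free_volume,
        config=config,
        stats={
            "dt": spec.dt, "p_on": spec.p_on, "p_off": spec.p_off,
            "n_steps": n_steps, "bind_events": int(stats[0]),
            "unbind_events": int(stats[1]), "reinsertions": int(stats[2]),
            "rebuilds": int(stats[3]), "max_audit_overlap": float(stats[4]),
            "N_R": NR, "N_L": NL, "R_cell": R_cell, "R_env": R_env,
        },
    )
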