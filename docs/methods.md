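# Methods

## Model system

A spherical environment of radius `R_env` contains a spherical cell of
radius `R_cell` at its centre. Ligands are soluble spheres of radius
`r_L`. Receptors come in two morphologies and two anchoring modes:

- **O** — a single sphere that is simultaneously the binding region and
  the excluded volume (binding and collision sphere coincide).
- **Y** — an antibody-like rigid body: a stem and two arms realized as
  chains of collision spheres, with a binding sphere at each arm tip.
  The binding spheres are also collision-active, so that binding always
  happens by point contact, exactly as for the O variant. (The
  alternative reading — penetrable binding spheres guarded only by the
  2 nm body chain — would make the Y contact criterion systematically
  more permissive than the O one and break the morphology comparison.)
- **SOL** — the receptor diffuses in the 3-D free volume;
  **MEM** — its anchor is constrained to the cell sphere and it
  diffuses in 2-D on that surface, stem pointing along the outward
  normal.

Valency is 1 or 2. A monovalent Y receptor still has two binding
spheres but may hold at most one ligand; a bivalent one may hold two.
A "complex" is a receptor with ≥ 1 bound ligand; "bound ligands" counts
ligand molecules, so a doubly-bound receptor contributes one complex
and two bound ligands.

## Dynamics

Time advances in fixed steps
`Δt = min(1/kon_micro, 1/koff_micro, Δs_R²/(2 d_R D_R), Δs_L²/(6 D_L))`
with resolution lengths `Δs_R` = receptor binding-sphere radius and
`Δs_L = r_L`, so that per-step reaction probabilities are valid and no
molecule moves farther than its own contact resolution. Every step,
all molecules are updated in a fresh uniformly random permutation
(random selection dynamics); each update comprises:

1. a diffusive step of exact length √(2 d D Δt) in a uniformly random
   direction (for MEM receptors: uniform in the local tangent plane,
   then radial re-projection onto the cell sphere);
2. collision response: if the move would overlap another molecule it is
   retracted along its own direction by bisection until point contact
   (gap tolerance 1e-7 µm); pre-move configurations are overlap-free by
   induction, and optional brute-force audits confirm zero overlap
   depth;
3. boundary handling: a soluble molecule crossing `R_env` re-enters at
   a uniformly random boundary point with a fresh identity (binding
   state preserved for complexes — re-entering them unbound would break
   detailed balance); positions inside the cell are mirrored radially
   across the surface;
4. for Y receptors, an orientation resample: a fresh Haar-uniform
   rotation (SOL) or uniform azimuth about the surface normal (MEM),
   accepted only if it creates no overlap. This models rotational
   diffusion as fast compared to Δt; the molecule rotates rigidly
   (no arm hinge);
5. one dissociation trial per occupied site (probability
   `p_off = koff_micro·Δt`; the ligand is released at point contact and
   may rebind immediately);
6. binding trials: every free ligand whose surface lies within the
   contact shell (point contact + tolerance `contact_tol`, default
   1e-4 µm) of a free binding sphere binds with probability
   `p_on = kon_micro·Δt`. Trials are triggered by the move of either
   partner; a successful trial snaps the ligand to exact point contact
   and is rejected if the snap would overlap a third party. Bound
   ligands move rigidly with their receptor.

Interaction partners come from Verlet neighbor lists over a linked-cell
grid; receptor reach radii cover the whole complex including bound
ligands, so the lists remain supersets under rotation and cargo
transport. Lists are rebuilt when any molecule's drift approaches half
the skin distance; teleported molecules (boundary re-insertion, ligand
release) are patched into the lists locally.

Randomness comes from a single xorshift128+ stream seeded from the
config seed (plus an independent numpy stream for initial placement),
making every trajectory bit-reproducible from `(config, seed)` across
platforms.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| stem, arm length | 0.007 | µm | IgG-scale Fab/Fc arms |
| arm half-angle | 50 | deg | open Y conformation |
| body sphere radius | 0.002 | µm | ~2 nm chain radius; 3 spheres/segment keeps the chain contiguous |
| Y binding-sphere radius | 0.0035 | µm | Fv-sized binding region |
| O binding-sphere radius | 0.005 | µm | area-matches the two Y binding spheres (4π·5² ≈ 2·4π·3.5²) |
| r_L | 0.0037 | µm | small antigen |
| D_R (SOL / MEM) | 90 / 0.05 | µm²/s | Stokes–Einstein scale for a free antibody; membrane diffusion is orders of magnitude slower |
| D_L | 100 | µm²/s | Stokes–Einstein-consistent with r_L at 37 °C |
| koff_micro | 0.1 | 1/s | antibody–antigen scale; equal to koff_macro (dissociation is spontaneous at both scales) |
| N_R_phys, N_L_phys | 1e5 | — | B-cell receptor copy number |
| R_cell | 5 | µm | B-cell radius |
| R_env | 10.9707 | µm | free volume 5000 µm³, i.e. exactly 50 µm³ at s = 1e-2 |
| contact_tol | 1e-4 | µm | finite-step contact detectability shell |

With these defaults the contact distance is r_R + r_L = 8.7 nm and the
Smoluchowski rate ks = 4π(r_R+r_L)(D_R+D_L) ≈ 20.8 µm³/s.

**Down-scaling.** `downscale_config(cfg, s)` multiplies molecule counts
and the free volume by `s` (bulk concentrations exactly preserved — the
scaled `R_env` is solved from the free volume rather than scaled as
s^(1/3), which would be exact only for a vanishing cell) and the cell
radius by √s (receptor surface density preserved; s = 1e-2 shrinks the
cell tenfold and the receptor count to 10³). Soluble-variant rate
fits are insensitive to `s`; membrane variants are reported at the `s`
used.

## Fitting and theory layer

`fit_kon_macro` minimizes Σ[C_data − C(t; kon)]² over log(kon) with
`scipy.optimize.least_squares` (LM), koff held fixed; the initial guess
is the early-slope secant dC/dt ≈ kon·R₀L₀. Replicate ensembles are
pooled (mean trajectory) before fitting. `fit_hill` estimates (a, b)
of kon_macro = a·k/(b+k) on log-parameters. The theory layer is exact
arithmetic: ks, Vr = (4/3)π(r_R+r_L)³, Collins–Kimball
ks·κ/(ks+κ), and the scaling factors fs = a/ks, fr = fs·ks/(b·Vr).
The closed-form C(t) is evaluated in an overflow-safe form (e^{-x}
formulation, direct C₋ beyond x = 700) with dedicated limits for the
degenerate equal-root case (koff = 0, R₀ = L₀) and the pseudo-first-
order limit kon → 0.

## Effective reaction volume: what the particle model actually gives

In the reaction-limited regime the macroscopic rate equals
kon_micro × (effective reaction volume). For point particles this
volume is Vr; the particle model replaces it by the per-step flux of
contact events, which depends on the step-to-contact ratio Δs/(r_R+r_L)
(≈ 0.4 here), on excluded volume, and on the contact-shell tolerance.
Measured effective reaction volumes come out within roughly ±20% of the
ideal Vr, varying with the operating point: somewhat below ideal at
moderate microscopic rates and somewhat above it in the
diffusion-influenced regime, where the fitted rate constant also
carries substantial seed-to-seed scatter (the transient shape is only
weakly sensitive to kon_macro once binding is diffusion-limited). Both binding partners' moves trigger trials, which
is the flux-consistent counting for sequential (random-selection)
updates; counting only the ligand's moves would halve the encounter
flux.

## What the test problems emulate — and what they do not

The test suite and the acceptance script run *down-scaled* or
*toy-scale* systems chosen so the binding transient resolves in
seconds-to-minutes on one CPU:

- toy Collins–Kimball benchmark: O-SOL, r_R = 30 nm, r_L = 20 nm,
  D = 10 µm²/s, 100+100 molecules, ~30 µm³;
- toy valency/dimensionality comparisons: 5×-enlarged Y morphology,
  60 receptors + 120 ligands, and O-MEM with 100 receptors on a
  0.3 µm cell;
- headline operating points (`scripts/acceptance.py`): the default
  molecular geometry at s = 1e-3 (100+100 molecules in ~5 µm³), five
  replicates pooled, fit windows 0.25 s (kon_micro = 10⁶/s) and 0.10 s
  (10⁷/s) covering ≈ 90% of the approach to equilibrium.

These systems preserve the model's concentrations and contact physics
but not its absolute molecule numbers; stochastic fluctuations are
correspondingly larger (≈ few % rather than ≈ 1%). Passing tests
demonstrate the mapping machinery and the engine's physics, not the
behaviour of any particular real antibody: the geometry and
diffusivities are literature-scale reconstructions, ligands are
monovalent hard spheres, receptors are rigid, and hydrodynamic
interactions, crowding agents, receptor–receptor binding and multivalent
antigens are all outside the model.

## Known limitations

- The cell-surface boundary reflects molecule *centres*; a ligand may
  formally dip up to r_L into the cell. Receptor bodies likewise are
  not excluded from the cell interior (MEM stems point outward, so in
  practice only the 2 nm base sphere can graze it).
- Soluble complexes diffuse with the receptor's D_R; no size-dependent
  slowdown on binding.
- Membrane receptors do not feel each other's anchors beyond sphere
  overlap; no lipid-mediated interactions.
- The per-step orientation resample corresponds to infinitely fast
  rotational diffusion; slow-rotation regimes are not represented.
- Bisection push-back resolves the first-contact configuration along
  the attempted path; for steps comparable to sphere sizes a grazing
  trajectory could in principle tunnel past a thin obstacle, an event
  the overlap audits have never recorded at the default step sizes.
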