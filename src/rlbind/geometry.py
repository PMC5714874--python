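"""Shape representation of receptors and ligands.

Receptors are modeled as rigid assemblies of spheres in two roles:

* *binding spheres* -- regions whose contact with a ligand enables a
  stochastic binding attempt (Fv-sized for Y-shaped antibodies);
* *collision spheres* -- excluded-volume spheres that no other molecule
  may penetrate.

A spherical receptor (variant ``O``) is a single sphere carrying both
roles.  A Y-shaped receptor (variant ``Y``, an antibody/BCR) is a stem
and two arms realized as chains of collision spheres, with one binding
sphere at each arm tip.  Binding spheres of the Y variant are also
collision-active, so that binding always happens by point contact, as
for the O variant.

All lengths are in micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereShape",
    "YMorphology",
    "Orientation",
    "build_receptor_shape",
    "sample_uniform_rotation",
    "pair_overlap",
    "push_back",
    "quat_rotate",
    "quat_conjugate",
]

_QUAT_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SphereShape:
    """A sphere with a role, in world coordinates (µm)."""

    center: np.ndarray
    radius: float
    role: str  # "binding" or "collision"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")
        if self.role not in ("binding", "collision"):
            raise ValueError(f"unknown sphere role {self.role!r}")


@dataclass(frozen=True)
class YMorphology:
    """Dimensions of a Y-shaped receptor.

    The stem runs along the local +z axis from the base (local origin)
    to the elbow; the two arms leave the elbow at ``arm_half_angle``
    degrees from the stem axis, mirror-symmetric in the local x-z plane.
    Cylindrical stem and arms are realized as chains of collision
    spheres (``spheres_per_segment`` per segment).

    Defaults approximate an IgG-sized antibody: 7 nm stem and arms,
    2 nm body spheres, 3.5 nm binding spheres at the arm tips.
    """

    stem_length: float = 0.007
    arm_length: float = 0.007
    arm_half_angle: float = 50.0
    body_sphere_radius: float = 0.002
    binding_sphere_radius: float = 0.0035
    spheres_per_segment: int = 3

    def __post_init__(self) -> None:
        for name in ("stem_length", "arm_length", "body_sphere_radius",
                     "binding_sphere_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.arm_half_angle < 90:
            raise ValueError("arm_half_angle must be in (0, 90) degrees")
        if self.spheres_per_segment < 1:
            raise ValueError("spheres_per_segment must be >= 1")
        # adjacent chain spheres must overlap or touch so the body is contiguous
        spacing = max(self.stem_length, self.arm_length) / self.spheres_per_segment
        if spacing > 2.0 * self.body_sphere_radius + 1e-12:
            raise ValueError(
                "collision-sphere chain is not contiguous: increase "
                "spheres_per_segment or body_sphere_radius"
            )

    def local_spheres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Local-frame sphere layout.

        Returns ``(binding_centers (2,3), collision_centers (M,3),
        collision_radii (M,))``.  Binding spheres are included in the
        collision set (excluded volume), followed by the body chain.
        """
        half = np.deg2rad(self.arm_half_angle)
        elbow = np.array([0.0, 0.0, self.stem_length])
        arm_dirs = np.array([
            [np.sin(half), 0.0, np.cos(half)],
            [-np.sin(half), 0.0, np.cos(half)],
        ])
        tips = elbow + self.arm_length * arm_dirs

        n = self.spheres_per_segment
        # chain spheres at fractions (i+1/2)/n of each segment
        fracs = (np.arange(n) + 0.5) / n
        chain = [fracs[:, None] * elbow]  # stem: base -> elbow
        for d in arm_dirs:                # arms: elbow -> tip
            chain.append(elbow + fracs[:, None] * (self.arm_length * d))
        body = np.concatenate(chain, axis=0)

        coll_centers = np.concatenate([tips, body], axis=0)
        coll_radii = np.concatenate([
            np.full(2, self.binding_sphere_radius),
            np.full(body.shape[0], self.body_sphere_radius),
        ])
        return tips, coll_centers, coll_radii


@dataclass(frozen=True)
class Orientation:
    """A rigid-body rotation stored as a unit quaternion (w, x, y, z)."""

    rotation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        q = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", q)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components")
        if abs(np.linalg.norm(q) - 1.0) > _QUAT_NORM_TOL:
            raise ValueError("quaternion is not unit-norm")

    def inverse(self) -> "Orientation":
        return Orientation(quat_conjugate(self.rotation))


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion ``q`` (w, x, y, z)."""
    w, u = q[0], q[1:]
    v = np.asarray(v, dtype=float)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def sample_uniform_rotation(rng: np.random.Generator) -> Orientation:
    """Draw an orientation from the uniform (Haar) distribution on SO(3).

    A normalized 4-vector of i.i.d. standard normals is uniform on the
    unit 3-sphere, which double-covers the rotation group uniformly.
    """
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Orientation(q)


def build_receptor_shape(
    variant: str,
    morphology,
    position: np.ndarray,
    orientation: Orientation | None = None,
) -> list[SphereShape]:
    """World-frame sphere set of a receptor.

    ``variant`` is ``"O"`` (spherical; ``morphology`` is the sphere
    radius in µm) or ``"Y"`` (``morphology`` is a :class:`YMorphology`).
    Local positions are rotated by ``orientation`` then translated to
    ``position``.  For the O variant one binding sphere plus a coincident
    collision sphere is returned; for Y, two binding spheres at the arm
    tips plus the (binding-inclusive) collision chain.
    """
    position = np.asarray(position, dtype=float)
    if orientation is None:
        orientation = Orientation()
    q = orientation.rotation

    if variant == "O":
        radius = float(morphology)
        return [
            SphereShape(position, radius, "binding"),
            SphereShape(position, radius, "collision"),
        ]
    if variant == "Y":
        if not isinstance(morphology, YMorphology):
            raise TypeError("Y variant requires a YMorphology")
        tips, coll_centers, coll_radii = morphology.local_spheres()
        shapes = [
            SphereShape(position + quat_rotate(q, tip),
                        morphology.binding_sphere_radius, "binding")
            for tip in tips
        ]
        shapes += [
            SphereShape(position + quat_rotate(q, c), float(r), "collision")
            for c, r in zip(coll_centers, coll_radii)
        ]
        return shapes
    raise ValueError(f"unknown receptor variant {variant!r}")


def pair_overlap(a: SphereShape, b: SphereShape) -> float:
    """Overlap depth of two spheres in µm (0 if separated or touching)."""
    dist = float(np.linalg.norm(a.center - b.center))
    return max(0.0, a.radius + b.radius - dist)


def _max_overlap(moving: list[SphereShape], static: list[SphereShape],
                 shift: np.ndarray) -> float:
    depth = 0.0
    for m in moving:
        c = m.center + shift
        for s in static:
            d = m.radius + s.radius - float(np.linalg.norm(c - s.center))
            if d > depth:
                depth = d
    return depth


def push_back(
    moving_shapes: list[SphereShape],
    static_shapes: list[SphereShape],
    displacement: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Retract a diffusive step to the point of contact.

    Returns ``lam * displacement`` with the largest ``lam`` in [0, 1]
    found by bisection (position tolerance ``tol`` µm) such that the
    moved shapes do not overlap any static shape.  The move is retracted
    along its own direction, never deflected.  Raises if the pre-move
    configuration already overlaps (an engine invariant violation).
    """
    displacement = np.asarray(displacement, dtype=float)
    if _max_overlap(moving_shapes, static_shapes, np.zeros(3)) > 0.0:
        raise RuntimeError("push_back called on an already-overlapping configuration")
    if _max_overlap(moving_shapes, static_shapes, displacement) <= 0.0:
        return displacement
    step = float(np.linalg.norm(displacement))
    lo, hi = 0.0, 1.0
    while (hi - lo) * step > tol:
        mid = 0.5 * (lo + hi)
        if _max_overlap(moving_shapes, static_shapes, mid * displacement) > 0.0:
            hi = mid
        else:
            lo = mid
    return lo * displacement
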