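"""Receptor shape construction, overlap detection, push-back."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlbind.geometry import (Orientation, SphereShape, YMorphology,
                             build_receptor_shape, pair_overlap, push_back,
                             quat_rotate, sample_uniform_rotation)


def _unit_quat(seed):
    r = np.random.default_rng(seed)
    q = r.standard_normal(4)
    return q / np.linalg.norm(q)


class TestBuildReceptorShape:
    def test_o_variant_identity_placement(self):
        shapes = build_receptor_shape("O", 0.005, np.zeros(3))
        binding = [s for s in shapes if s.role == "binding"]
        collision = [s for s in shapes if s.role == "collision"]
        assert len(binding) == 1 and len(collision) == 1
        assert np.allclose(binding[0].center, 0.0)
        assert binding[0].radius == 0.005
        # collision sphere coincides in position and size
        assert np.allclose(collision[0].center, binding[0].center)
        assert collision[0].radius == binding[0].radius

    def test_y_variant_two_symmetric_binding_spheres(self):
        m = YMorphology()
        shapes = build_receptor_shape("Y", m, np.zeros(3))
        tips = [s.center for s in shapes if s.role == "binding"]
        assert len(tips) == 2
        # mirror-symmetric about the stem axis plane (x -> -x)
        assert np.allclose(tips[0] * [-1, 1, 1], tips[1], atol=1e-15)
        # arm tips sit at stem + arm-projection height above the base
        half = np.deg2rad(m.arm_half_angle)
        expected_z = m.stem_length + m.arm_length * np.cos(half)
        assert tips[0][2] == pytest.approx(expected_z)
        assert abs(tips[0][0]) == pytest.approx(m.arm_length * np.sin(half))

    def test_rotation_roundtrip_recovers_identity(self):
        m = YMorphology()
        q = _unit_quat(5)
        o = Orientation(q)
        rotated = build_receptor_shape("Y", m, np.zeros(3), o)
        # rotate back each sphere by the inverse orientation
        inv = o.inverse().rotation
        base = build_receptor_shape("Y", m, np.zeros(3))
        for s_rot, s_base in zip(rotated, base):
            back = quat_rotate(inv, s_rot.center)
            assert np.allclose(back, s_base.center, atol=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_receptor_shape("X", 0.005, np.zeros(3))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_build_is_rotation_equivariant(self, seed):
        """rotate-then-build equals build-then-rotate."""
        m = YMorphology()
        q = _unit_quat(seed)
        built = build_receptor_shape("Y", m, np.zeros(3), Orientation(q))
        base = build_receptor_shape("Y", m, np.zeros(3))
        for s_rot, s_base in zip(built, base):
            assert np.allclose(s_rot.center, quat_rotate(q, s_base.center),
                               atol=1e-12)
            assert s_rot.radius == s_base.radius

    def test_collision_chain_contiguous(self):
        m = YMorphology()
        shapes = build_receptor_shape("Y", m, np.zeros(3))
        coll = [s for s in shapes if s.role == "collision"]
        # every collision sphere overlaps or touches at least one other:
        # the body is a connected excluded volume
        for i, a in enumerate(coll):
            gaps = [np.linalg.norm(a.center - b.center) - a.radius - b.radius
                    for j, b in enumerate(coll) if i != j]
            assert min(gaps) <= 1e-12


class TestUniformRotation:
    def test_unit_norm(self, rng):
        for _ in range(100):
            assert np.linalg.norm(
                sample_uniform_rotation(rng).rotation) == pytest.approx(1.0)

    def test_rotated_axis_is_isotropic(self, rng):
        n = 100_000
        q = rng.standard_normal((n, 4))
        q /= np.linalg.norm(q, axis=1)[:, None]
        z = np.zeros((n, 3))
        for i in range(0, n, 10_000):  # chunked quaternion rotation
            blk = q[i:i + 10_000]
            w, u = blk[:, 0:1], blk[:, 1:]
            v = np.array([0.0, 0.0, 1.0])
            uv = np.cross(u, np.broadcast_to(v, u.shape))
            z[i:i + 10_000] = v + 2.0 * (w * uv + np.cross(u, uv))
        assert np.all(np.abs(z.mean(axis=0)) < 0.01)
        from scipy.stats import kstest
        # polar angle cosine of the rotated axis must be uniform on [-1, 1]
        stat = kstest(z[:, 2], "uniform", args=(-1, 2))
        assert stat.pvalue > 0.001


class TestPairOverlap:
    @pytest.mark.parametrize("dist,expected", [
        (2.0, 0.0),    # point contact
        (1.5, 0.5),    # interpenetration depth
        (3.0, 0.0),    # separated
    ])
    def test_depth(self, dist, expected):
        a = SphereShape(np.zeros(3), 1.0, "collision")
        b = SphereShape(np.array([dist, 0.0, 0.0]), 1.0, "collision")
        assert pair_overlap(a, b) == pytest.approx(expected)


class TestPushBack:
    def _sphere(self, center, r=1.0):
        return SphereShape(np.asarray(center, float), r, "collision")

    def test_head_on_retracts_to_point_contact(self):
        corrected = push_back([self._sphere([0, 0, 0])],
                              [self._sphere([3, 0, 0])],
                              np.array([2.0, 0.0, 0.0]))
        assert np.allclose(corrected, [1.0, 0.0, 0.0], atol=2e-6)
        assert corrected[0] <= 1.0  # never past contact

    def test_no_conflict_returns_displacement_unchanged(self):
        d = np.array([0.5, 0.2, -0.1])
        out = push_back([self._sphere([0, 0, 0])],
                        [self._sphere([5, 5, 5])], d)
        assert np.array_equal(out, d)

    def test_perpendicular_miss_is_not_retracted(self):
        # static at (0,3,0): closest approach sqrt(4+9) > 2 along the path
        out = push_back([self._sphere([0, 0, 0])],
                        [self._sphere([0, 3, 0])],
                        np.array([2.0, 0.0, 0.0]))
        assert np.allclose(out, [2.0, 0.0, 0.0])

    def test_preexisting_overlap_is_an_engine_bug(self):
        with pytest.raises(RuntimeError, match="overlap"):
            push_back([self._sphere([0, 0, 0])],
                      [self._sphere([1, 0, 0])],
                      np.array([1.0, 0.0, 0.0]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_never_longer_never_deflected(self, seed):
        r = np.random.default_rng(seed)
        mover = self._sphere(r.uniform(-1, 1, 3), 0.5)
        static = [self._sphere(mover.center + r.uniform(-2, 2, 3), 0.5)
                  for _ in range(3)]
        static = [s for s in static
                  if np.linalg.norm(s.center - mover.center) > 1.0]
        d = r.uniform(-1.5, 1.5, 3)
        out = push_back([mover], static, d)
        assert np.linalg.norm(out) <= np.linalg.norm(d) + 1e-12
        # collinear with the attempted displacement, same direction
        assert np.linalg.norm(np.cross(out, d)) < 1e-9
        assert np.dot(out, d) >= 0.0


class TestInvariants:
    def test_sphere_requires_positive_radius(self):
        with pytest.raises(ValueError):
            SphereShape(np.zeros(3), 0.0, "binding")

    def test_orientation_requires_unit_norm(self):
        with pytest.raises(ValueError):
            Orientation(np.array([1.0, 1.0, 0.0, 0.0]))

    def test_morphology_rejects_gappy_chain(self):
        with pytest.raises(ValueError, match="contiguous"):
            YMorphology(body_sphere_radius=0.0005, spheres_per_segment=2)
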