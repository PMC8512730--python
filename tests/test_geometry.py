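"""Solenoid geometry, pose symmetry, and voxelization tests."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chiroscat as cs


def _centers(poses):
    return np.array([p.center for p in poses])


class TestNucleosomePoses:
    def test_closed_form_pose(self, default_spec):
        """Nucleosome 3 of the default helix sits at azimuth pi, half a pitch up."""
        poses = cs.nucleosome_poses(default_spec)
        assert len(poses) == 6
        np.testing.assert_allclose(poses[3].center, [-10.0, 0.0, 5.5], atol=1e-12)
        np.testing.assert_allclose(poses[3].axis, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_helix_invariants(self):
        spec = cs.SolenoidSpec(turns=2, phase0=0.3)
        poses = cs.nucleosome_poses(spec)
        cents = _centers(poses)
        assert len(poses) == 12
        np.testing.assert_allclose(np.diff(cents[:, 2]), spec.pitch / 6.0, atol=1e-12)
        np.testing.assert_allclose(np.hypot(cents[:, 0], cents[:, 1]), spec.radius, atol=1e-12)

    def test_degenerate_radius_zero(self):
        """R=0 collapses onto the z axis with one shared frame (achiral stack)."""
        spec = cs.SolenoidSpec(radius=0.0)
        poses = cs.nucleosome_poses(spec)
        cents = _centers(poses)
        np.testing.assert_allclose(cents[:, :2], 0.0, atol=1e-15)
        np.testing.assert_allclose(cents[:, 2], spec.pitch * np.arange(6) / 6.0, atol=1e-12)
        for p in poses:
            np.testing.assert_array_equal(p.axis, [1.0, 0.0, 0.0])
        rotating = cs.nucleosome_poses(replace(spec, rotating_frame_at_axis=True))
        assert any(np.abs(p.axis - [1, 0, 0]).max() > 0.1 for p in rotating)

    def test_handedness_flip_is_exact_xz_mirror(self):
        spec = cs.SolenoidSpec(phase0=0.7, turns=2)
        right = cs.nucleosome_poses(spec)
        left = cs.nucleosome_poses(spec.flipped())
        flip = np.array([1.0, -1.0, 1.0])
        for r, l in zip(right, left):
            np.testing.assert_array_equal(l.center, r.center * flip)
            np.testing.assert_array_equal(l.axis, r.axis * flip)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            cs.SolenoidSpec(radius=-1.0)
        with pytest.raises(ValueError):
            cs.SolenoidSpec(pitch=float("nan"))
        with pytest.raises(ValueError):
            cs.NucleosomeShape(diameter=-11.0)
        with pytest.raises(ValueError):
            cs.NucleosomeShape(kind="cylinder", height=0.0)


class TestRotatePoses:
    def test_identity(self, default_spec):
        poses = cs.nucleosome_poses(default_spec)
        rotated = cs.rotate_poses(poses, 0.0, 0.0, 0.0)
        for p, q in zip(poses, rotated):
            np.testing.assert_allclose(q.center, p.center, atol=1e-12)
            np.testing.assert_allclose(q.axis, p.axis, atol=1e-12)

    def test_half_turn_involution(self, default_spec):
        poses = cs.nucleosome_poses(default_spec)
        twice = cs.rotate_poses(cs.rotate_poses(poses, 0.0, math.pi, 0.0), 0.0, math.pi, 0.0)
        for p, q in zip(poses, twice):
            np.testing.assert_allclose(q.center, p.center, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(0, 2 * math.pi), b=st.floats(0, math.pi), g=st.floats(0, 2 * math.pi)
    )
    def test_rotation_is_isometry(self, a, b, g):
        spec = cs.SolenoidSpec(turns=1)
        poses = cs.nucleosome_poses(spec)
        rotated = cs.rotate_poses(poses, a, b, g)
        d0 = np.linalg.norm(_centers(poses)[:, None] - _centers(poses)[None, :], axis=-1)
        d1 = np.linalg.norm(_centers(rotated)[:, None] - _centers(rotated)[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestOppositeHandedStack:
    def test_mirror_symmetric_composite(self, default_spec):
        comp = cs.stack_opposite_handed(default_spec)
        assert len(comp.segments) == 2
        poses = cs.composite_poses(comp)
        assert len(poses) == 12
        cents = _centers(poses)
        zmid = default_spec.pitch * 11.0 / 12.0
        mirrored = cents * [1, 1, -1] + [0, 0, 2 * zmid]
        a = cents[np.lexsort(cents.T)]
        b = mirrored[np.lexsort(mirrored.T)]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_same_handed_stack_is_not_mirror_symmetric(self, default_spec):
        comp = cs.CompositeModel(
            segments=((default_spec, 0.0, 0.0), (default_spec, default_spec.pitch, 0.0))
        )
        cents = _centers(cs.composite_poses(comp))
        zmid = 0.5 * (cents[:, 2].min() + cents[:, 2].max())
        mirrored = cents * [1, 1, -1] + [0, 0, 2 * zmid]
        a = cents[np.lexsort(cents.T)]
        b = mirrored[np.lexsort(mirrored.T)]
        assert np.abs(a - b).max() > 1.0

    def test_rejects_multi_turn(self, default_spec):
        with pytest.raises(ValueError):
            cs.stack_opposite_handed(replace(default_spec, turns=2))


def _brute_force_sphere_count(radius, n):
    """Independent triple-loop count of centred-lattice cells inside a sphere."""
    d = 2.0 * radius / n
    count = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                x = (i + 0.5 - n / 2.0) * d
                y = (j + 0.5 - n / 2.0) * d
                z = (k + 0.5 - n / 2.0) * d
                if x * x + y * y + z * z <= radius * radius:
                    count += 1
    return count


class TestVoxelize:
    def _sphere_pose(self):
        return cs.NucleosomePose(np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))

    def test_sphere_count_matches_brute_force(self):
        shape = cs.NucleosomeShape(kind="sphere", diameter=11.0)
        model = cs.voxelize([self._sphere_pose()], shape, 11)
        assert model.spacing == pytest.approx(1.0)
        assert model.n_dipoles == _brute_force_sphere_count(5.5, 11)

    def test_sphere_volume_convergence(self):
        """Voxel volume approaches the continuum sphere volume as d shrinks."""
        shape = cs.NucleosomeShape(kind="sphere", diameter=11.0)
        model = cs.voxelize([self._sphere_pose()], shape, 22)
        expected = math.pi / 6.0 * 11.0**3 / model.spacing**3
        assert model.n_dipoles == pytest.approx(expected, rel=0.05)

    def test_cylinder_count(self):
        shape = cs.NucleosomeShape()  # 11 x 5.5 cylinder
        model = cs.voxelize([self._sphere_pose()], shape, 22)  # d = 0.5
        assert model.spacing == pytest.approx(0.5)
        expected = math.pi * 5.5**2 * 5.5 / 0.5**3
        assert model.n_dipoles == pytest.approx(expected, rel=0.05)

    def test_spacing_is_extent_over_dipoles_per_longest(self, default_spec):
        """d = (largest bounding extent of the union)/60, bbox sampled independently."""
        poses = cs.nucleosome_poses(default_spec)
        model = cs.voxelize(poses, default_spec.shape, 60)
        # independent bbox oracle: densely sample every cylinder surface
        u = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        rim = np.stack([np.cos(u), np.sin(u)], axis=1)
        pts = []
        for p in poses:
            e1 = p.reference
            e2 = np.cross(p.axis, e1)
            circ = 5.5 * (rim[:, :1] * e1 + rim[:, 1:] * e2)
            for h in (-2.75, 0.0, 2.75):
                pts.append(p.center + h * p.axis + circ)
        pts = np.concatenate(pts)
        extent = (pts.max(axis=0) - pts.min(axis=0)).max()
        assert model.spacing == pytest.approx(extent / 60.0, rel=1e-3)

    def test_count_scales_with_resolution(self, default_spec):
        poses = cs.nucleosome_poses(default_spec)
        n16 = cs.voxelize(poses, default_spec.shape, 16).n_dipoles
        n32 = cs.voxelize(poses, default_spec.shape, 32).n_dipoles
        assert n32 / n16 == pytest.approx(8.0, rel=0.10)

    def test_pitch_zero_model_has_exact_mirror_symmetries(self):
        spec = cs.SolenoidSpec(pitch=0.0)
        model = cs.voxelize(cs.nucleosome_poses(spec), spec.shape, 12)
        pos = model.positions
        key = {tuple(np.round(p, 9)) for p in pos}
        for sign in ([1, -1, 1], [1, 1, -1]):
            assert {tuple(np.round(p * sign, 9)) for p in pos} == key

    def test_deterministic(self, default_spec):
        poses = cs.nucleosome_poses(default_spec)
        a = cs.voxelize(poses, default_spec.shape, 12)
        b = cs.voxelize(poses, default_spec.shape, 12)
        np.testing.assert_array_equal(a.sites, b.sites)
        assert a.spacing == b.spacing and np.all(a.origin == b.origin)

    def test_empty_occupancy_names_offending_dimension(self):
        """Solids thinner than one lattice cell must fail loudly, not silently."""
        tiny = cs.NucleosomeShape(kind="sphere", diameter=1.0)
        z, x = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
        far_apart = [
            cs.NucleosomePose(np.array([-50.0, 0.0, 0.0]), z, x),
            cs.NucleosomePose(np.array([50.0, 0.0, 0.0]), z, x),
        ]
        with pytest.raises(ValueError, match="diameter"):
            cs.voxelize(far_apart, tiny, 4)


class TestMirrorModel:
    def test_involution(self, mini_helix_model):
        twice = cs.mirror_model(cs.mirror_model(mini_helix_model, "xz"), "xz")
        np.testing.assert_array_equal(twice.sites, mini_helix_model.sites)
        np.testing.assert_allclose(twice.origin, mini_helix_model.origin)

    def test_single_site_reflection(self):
        model = cs.DipoleModel(
            spacing=1.0, origin=np.array([0.0, 2.0, 0.0]), sites=np.array([[0, 0, 0]]), rel_index=1.2
        )
        mirrored = cs.mirror_model(model, "xz")
        np.testing.assert_allclose(mirrored.positions, [[0.0, -2.0, 0.0]])

    def test_mirror_reverses_helix_chirality(self, default_spec):
        right = cs.voxelize(cs.nucleosome_poses(default_spec), default_spec.shape, 10)
        left = cs.voxelize(cs.nucleosome_poses(default_spec.flipped()), default_spec.shape, 10)
        mirrored = cs.mirror_model(right, "xz")
        a = {tuple(np.round(p, 9)) for p in mirrored.positions}
        b = {tuple(np.round(p, 9)) for p in left.positions}
        assert a == b
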