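"""Tests for malposition transforms, insertion shifting and strain bookkeeping."""

import numpy as np
import pytest

from kneesim.anatomy import FrameDefinitions, parametric_geometry
from kneesim.kinematics import JointPose, RigidTransform, rot_y
from kneesim.ligaments import LigamentBundle, LigamentSet
from kneesim.malposition import (
    MalpositionSpec,
    apply_to_insertions,
    direct_geometry_malposition,
    recompute_reference_strains,
    spec_to_transform,
    variation_matrix,
)


@pytest.fixture
def frames():
    return FrameDefinitions()


def _ligset(l0=None):
    bundles = [
        LigamentBundle("A", (5.0, 3.0, -20.0), (2.0, -40.0, -18.0), 1000.0, 0.05, l0=l0),
        LigamentBundle("B", (-4.0, 2.0, 22.0), (-1.0, -38.0, 20.0), 2000.0, -0.1, l0=l0),
    ]
    return LigamentSet(bundles)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self, rng):
        for _ in range(20):
            T = RigidTransform.rotation(rng.normal(size=3), rng.uniform(-90, 90),
                                        pivot=rng.normal(size=3) * 10)
            I = T @ T.inverse()
            assert np.allclose(I.R, np.eye(3), atol=1e-10)
            assert np.allclose(I.t, 0.0, atol=1e-10)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rotation_about_pivot_fixes_pivot(self):
        p = np.array([3.0, -2.0, 7.0])
        T = RigidTransform.rotation([0, 0, 1], 37.0, pivot=p)
        assert np.allclose(T.apply(p), p, atol=1e-12)


class TestSpecToTransform:
    def test_zero_magnitude_is_identity(self, frames):
        T = spec_to_transform(MalpositionSpec(magnitude=0.0), frames)
        assert T.is_identity

    def test_femoral_posterior_shift(self, frames):
        spec = MalpositionSpec("femoral", "translation", "AP", -3.0)
        T = spec_to_transform(spec, frames)
        assert np.allclose(T.t, [-3.0, 0.0, 0.0])
        assert np.allclose(T.R, np.eye(3))

    def test_tibial_internal_twist(self, frames):
        spec = MalpositionSpec("tibial", "rotation", "long", 6.0)
        T = spec_to_transform(spec, frames)
        assert np.allclose(T.R, rot_y(np.deg2rad(6.0)), atol=1e-12)
        assert np.allclose(T.t, 0.0)

    def test_configurable_pivot(self, frames):
        spec = MalpositionSpec("tibial", "rotation", "long", 10.0)
        pivot = np.array([5.0, 0.0, 2.0])
        T = spec_to_transform(spec, frames, pivot=pivot)
        assert np.allclose(T.apply(pivot), pivot, atol=1e-12)

    def test_invalid_spec_fields(self):
        with pytest.raises(ValueError):
            MalpositionSpec(component="patellar")
        with pytest.raises(ValueError):
            MalpositionSpec(axis="diagonal")
        with pytest.raises(ValueError):
            MalpositionSpec(magnitude=np.inf)


class TestApplyToInsertions:
    def test_identity_spec_leaves_points(self, frames):
        ligset = _ligset()
        out = apply_to_insertions(ligset, MalpositionSpec(magnitude=0.0), frames)
        assert np.array_equal(out.P_fem, ligset.P_fem)
        assert np.array_equal(out.P_tib, ligset.P_tib)

    def test_posterior_shift_moves_insertions_anteriorly(self, frames):
        ligset = _ligset()
        spec = MalpositionSpec("femoral", "translation", "AP", -3.0)
        out = apply_to_insertions(ligset, spec, frames)
        assert np.allclose(out.P_fem - ligset.P_fem, [[3.0, 0.0, 0.0]] * 2)
        assert np.array_equal(out.P_tib, ligset.P_tib)

    def test_twist_matches_explicit_inverse_rotation(self, frames):
        ligset = _ligset()
        spec = MalpositionSpec("tibial", "rotation", "long", 6.0)
        out = apply_to_insertions(ligset, spec, frames)
        R_inv = rot_y(np.deg2rad(-6.0))
        for before, after in zip(ligset.P_tib, out.P_tib):
            assert np.allclose(after, R_inv @ before, atol=1e-12)
        assert np.array_equal(out.P_fem, ligset.P_fem)

    def test_exact_group_inverse_on_every_point(self, frames, rng):
        ligset = _ligset()
        for spec in variation_matrix():
            if spec.is_identity:
                continue
            T = spec_to_transform(spec, frames)
            out = apply_to_insertions(ligset, spec, frames)
            moved = out.P_fem if spec.component == "femoral" else out.P_tib
            orig = ligset.P_fem if spec.component == "femoral" else ligset.P_tib
            assert np.allclose(T.apply(moved), orig, atol=1e-10)


class TestRecomputeReferenceStrains:
    def test_requires_initialised_l0(self):
        with pytest.raises(RuntimeError):
            recompute_reference_strains(_ligset(), JointPose())

    def test_identity_malposition_preserves_eps_ref(self, frames):
        ligset = _ligset()
        pose = JointPose(si_mm=25.0)
        l_ref = ligset.chord_lengths(pose)
        ligset = ligset.with_l0(l_ref / (1.0 + ligset.eps_ref))
        out = recompute_reference_strains(ligset, pose)
        assert np.allclose(out.eps_ref, ligset.eps_ref, atol=1e-12)

    def test_arithmetic_on_shortened_chord(self):
        # reference chord 53 -> 51 mm with l0 = 50 mm: eps_ref 0.06 -> 0.02
        b = LigamentBundle("F", (0.0, 53.0, 0.0), (0.0, 0.0, 0.0), 1000.0, 0.06, l0=50.0)
        out = recompute_reference_strains(LigamentSet([b]), JointPose())
        assert out.eps_ref[0] == pytest.approx(0.06, abs=1e-12)
        moved = out.with_insertions(P_fem=np.array([[0.0, 51.0, 0.0]]))
        out2 = recompute_reference_strains(moved, JointPose())
        assert out2.eps_ref[0] == pytest.approx(0.02, abs=1e-12)

    def test_never_alters_l0(self, frames):
        ligset = _ligset(l0=45.0)
        spec = MalpositionSpec("femoral", "translation", "AP", -3.0)
        shifted = apply_to_insertions(ligset, spec, frames)
        out = recompute_reference_strains(shifted, JointPose(si_mm=20.0))
        assert np.array_equal(out.l0, ligset.l0)

    def test_rigid_invariance(self):
        """A common rigid transform of both clusters and the reference pose
        leaves all reference strains unchanged."""
        ligset = _ligset(l0=40.0)
        pose = JointPose(flexion_deg=10.0, si_mm=24.0, ap_mm=1.0)
        base = recompute_reference_strains(ligset, pose).eps_ref
        W = RigidTransform.rotation([0, 1, 0], 25.0, pivot=[3.0, 1.0, -2.0])
        moved = ligset.with_insertions(P_tib=W.apply(ligset.P_tib))
        pose_T = W @ pose.transform()
        l = np.linalg.norm(pose_T.apply(moved.P_fem) - moved.P_tib, axis=1)
        eps = (l - ligset.l0) / ligset.l0
        assert np.allclose(eps, base, atol=1e-12)


class TestDirectGeometry:
    def test_identity_spec_keeps_geometry(self, frames):
        g = parametric_geometry()
        out = direct_geometry_malposition(g, MalpositionSpec(magnitude=0.0), frames)
        assert out.mount_t is None or out.mount_t.is_identity

    def test_si_translation_moves_dish_centers(self, frames):
        g = parametric_geometry()
        spec = MalpositionSpec("tibial", "translation", "SI", 2.0)
        out = direct_geometry_malposition(g, spec, frames)
        for side in ("medial", "lateral"):
            assert np.allclose(
                out.dish_center_effective(side) - g.dish_center_effective(side),
                [0.0, 2.0, 0.0],
            )

    def test_composition_of_opposite_shifts_cancels(self, frames):
        g = parametric_geometry()
        plus = MalpositionSpec("femoral", "translation", "AP", 3.0)
        minus = MalpositionSpec("femoral", "translation", "AP", -3.0)
        out = direct_geometry_malposition(
            direct_geometry_malposition(g, plus, frames), minus, frames
        )
        assert out.mount_f.is_identity


class TestVariationMatrix:
    def test_entry_count_and_reference(self):
        specs = variation_matrix()
        assert len(specs) == 15
        assert sum(s.is_identity for s in specs) == 1

    def test_family_magnitudes(self):
        specs = variation_matrix()

        def fam(component, mode, axis):
            return sorted(
                s.magnitude for s in specs
                if s.component == component and s.mode == mode
                and s.axis == axis and not s.is_identity
            )

        assert fam("femoral", "translation", "AP") == [-3.0, 3.0]
        assert fam("femoral", "translation", "ML") == [-6.0, -3.0, 3.0, 6.0]
        assert fam("tibial", "rotation", "long") == [-6.0, -3.0, 3.0, 6.0]
        assert fam("tibial", "translation", "SI") == [-2.0, -1.0, 1.0, 2.0]

    def test_labels_unique(self):
        labels = [s.label for s in variation_matrix()]
        assert len(set(labels)) == len(labels)
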