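"""The synthetic study generator: template, population, raters, voxel loop."""

import numpy as np
import pytest

from pelvimetry3d.landmarks import Landmark, LandmarkSet, canonical_instances
from pelvimetry3d.phantoms import (
    PhantomParams,
    make_icc_matrix,
    make_study_fixture,
    make_template_pelvis,
    sample_subject,
    simulate_operator,
    simulate_rater,
    voxelize,
    voxelize_model,
)
from pelvimetry3d.reliability import icc, leave_one_out_error
from pelvimetry3d.surface_modeling import dice_index


class TestTemplate:
    def test_three_watertight_bones_and_22_landmarks(self, template):
        model, truth = template
        for mesh in model.bones().values():
            assert mesh.is_watertight
            assert mesh.euler_characteristic == 2
        assert len(truth) == 22
        sides = [lm.side for lm in truth]
        assert sides.count("midline") == 2
        assert sides.count("left") == sides.count("right") == 10
        assert set(truth.keys()) == set(canonical_instances())

    def test_bilateral_landmarks_mirror_across_midsagittal(self, template_truth):
        for lm in template_truth:
            if lm.side == "left":
                right = template_truth.position(lm.name, "right")
                np.testing.assert_allclose(
                    lm.position * [-1, 1, 1], right, atol=1e-9
                )
            elif lm.side == "midline":
                assert lm.position[0] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self):
        a, la = make_template_pelvis()
        b, lb = make_template_pelvis()
        np.testing.assert_array_equal(a.all_vertices(), b.all_vertices())
        np.testing.assert_array_equal(la.positions(), lb.positions())


class TestSampleSubject:
    def test_zero_amplitude_is_identity(self, template):
        model, truth = template
        params = PhantomParams(deformation_amplitude=0.0)
        subj, lm, fields = sample_subject(model, truth, params, seed=1)
        np.testing.assert_allclose(subj.all_vertices(), model.all_vertices())
        np.testing.assert_allclose(lm.positions(truth.keys()), truth.positions())

    def test_max_displacement_equals_amplitude(self, template):
        model, truth = template
        params = PhantomParams(deformation_amplitude=5.0)
        _, _, fields = sample_subject(model, truth, params, seed=2)
        max_disp = max(
            np.linalg.norm(f.displacements, axis=1).max() for f in fields.values()
        )
        assert max_disp == pytest.approx(5.0, abs=1e-9)

    def test_reproducible_per_seed(self, template):
        model, truth = template
        params = PhantomParams()
        a = sample_subject(model, truth, params, seed=7)[0]
        b = sample_subject(model, truth, params, seed=7)[0]
        np.testing.assert_array_equal(a.all_vertices(), b.all_vertices())

    def test_meshes_stay_valid(self, template):
        model, truth = template
        subj, _, _ = sample_subject(model, truth, PhantomParams(), seed=3)
        for mesh in subj.bones().values():
            assert mesh.is_watertight


class TestSimulateRater:
    def _one_landmark_truth(self):
        ls = LandmarkSet(subject_id="s")
        ls.add(Landmark("promontory", "midline", [0.0, 0.0, 0.0], "truth"))
        return ls

    def test_zero_noise_identity(self, template_truth):
        out = simulate_rater(template_truth, 0.0, seed=0)
        np.testing.assert_array_equal(out.positions(template_truth.keys()), template_truth.positions())

    def test_mean_error_matches_chi3_expectation(self):
        """E||N3(0, s^2 I)|| = 2 s sqrt(2/pi) ~ 1.596 s; Monte-Carlo at s=2."""
        truth = self._one_landmark_truth()
        sd = 2.0
        errs = [
            np.linalg.norm(
                simulate_rater(truth, sd, seed=i).position("promontory") - 0.0
            )
            for i in range(10_000)
        ]
        expected = 2 * sd * np.sqrt(2 / np.pi)
        assert np.mean(errs) == pytest.approx(expected, rel=0.02)

    def test_reproducible(self, template_truth):
        a = simulate_rater(template_truth, 2.0, seed=5)
        b = simulate_rater(template_truth, 2.0, seed=5)
        np.testing.assert_array_equal(a.positions(), b.positions())

    def test_heterogeneous_map_applied(self, template_truth):
        noise = {name: 0.0 for name, _ in template_truth.keys()}
        noise["iliac_crest"] = 3.0
        out = simulate_rater(template_truth, noise, seed=2)
        for lm in out:
            delta = np.linalg.norm(lm.position - template_truth.position(lm.name, lm.side))
            if lm.name == "iliac_crest":
                assert delta > 0
            else:
                assert delta == 0


class TestVoxelize:
    def test_sphere_volume_1mm(self, sphere_mesh):
        seg = voxelize(sphere_mesh, 1.0)
        count = int((seg.array > 0).sum())
        analytic = 4 / 3 * np.pi * 10.0**3
        assert abs(count - analytic) / analytic < 0.03

    def test_sphere_volume_half_mm_tighter(self, sphere_mesh):
        seg = voxelize(sphere_mesh, 0.5)
        vol = float((seg.array > 0).sum()) * 0.125
        analytic = 4 / 3 * np.pi * 10.0**3
        assert abs(vol - analytic) / analytic < 0.015

    def test_open_mesh_rejected(self):
        from pelvimetry3d.meshes import SurfaceMesh

        tri = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]), np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="watertight"):
            voxelize(tri, 1.0)

    def test_mesh_outside_grid_warns_empty(self, sphere_mesh):
        with pytest.warns(UserWarning, match="outside"):
            seg = voxelize(
                sphere_mesh, 1.0, origin=np.array([100.0, 100.0, 100.0]), shape=(5, 5, 5)
            )
        assert (seg.array == 0).all()

    def test_model_rasterizes_three_labels(self, template_model):
        seg = voxelize_model(template_model, (2.0, 2.0, 2.0))
        assert sorted(np.unique(seg.array)) == [0, 1, 2, 3]
        assert set(seg.label_map.values()) == {1, 2, 3}


class TestSimulateOperator:
    def test_zero_jitter_identity(self, sphere_mesh):
        seg = voxelize(sphere_mesh, 1.0)
        out = simulate_operator(seg, 0.0, seed=0)
        np.testing.assert_array_equal(out.array, seg.array)
        assert dice_index(seg, out, "ball") == 1.0

    def test_dice_in_calibrated_band(self):
        """0.4 mm boundary jitter on a 30 mm phantom bone lands in the
        Dice band observed between repeated human segmentations."""
        import trimesh

        from pelvimetry3d.meshes import SurfaceMesh

        s = trimesh.creation.icosphere(3, 15.0)  # 30 mm diameter bone
        bone = SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces), "bone")
        seg = voxelize(bone, 1.0)
        dices = [
            dice_index(seg, simulate_operator(seg, 0.4, seed=s), "bone")
            for s in range(3)
        ]
        assert all(0.93 <= d <= 0.99 for d in dices)

    def test_reproducible(self, template_model):
        seg = voxelize(template_model.sacrum, 1.5)
        a = simulate_operator(seg, 0.4, seed=3)
        b = simulate_operator(seg, 0.4, seed=3)
        np.testing.assert_array_equal(a.array, b.array)


class TestStudyFixture:
    def test_full_design_counts(self):
        params = PhantomParams(voxel_spacing=None)
        fx = make_study_fixture(10, 3, 3, params, seed=0)
        assert fx.n_models == 30
        assert fx.n_labelings == 90

    def test_minimal_design(self):
        params = PhantomParams(voxel_spacing=None)
        fx = make_study_fixture(1, 1, 2, params, seed=0)
        assert fx.n_models == 1
        assert fx.n_labelings == 2

    def test_same_seed_identical(self):
        params = PhantomParams(voxel_spacing=None)
        a = make_study_fixture(2, 2, 2, params, seed=5)
        b = make_study_fixture(2, 2, 2, params, seed=5)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(
                sa.subject_model.all_vertices(), sb.subject_model.all_vertices()
            )
            for la, lb in zip(sa.rater_labelings["seg0"], sb.rater_labelings["seg0"]):
                np.testing.assert_array_equal(la.positions(), lb.positions())

    def test_voxel_pipeline_produces_distinct_segmentations(self):
        params = PhantomParams(voxel_spacing=(2.0, 2.0, 2.0), template_subdivisions=2)
        fx = make_study_fixture(1, 2, 2, params, seed=1)
        m0, m1 = fx.subjects[0].models
        assert m0.sacrum.is_watertight and m1.sacrum.is_watertight
        assert m0.sacrum.n_vertices != m1.sacrum.n_vertices or not np.array_equal(
            m0.sacrum.vertices, m1.sacrum.vertices
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            make_study_fixture(0, 3, 3)


class TestStatisticalRecovery:
    def test_loo_error_matches_gaussian_expectation(self):
        """With homogeneous sd s and k raters the expected leave-one-out
        error is E||N3(0, s^2 (1 + 1/(k-1)) I)||; Monte-Carlo at k=3, s=2."""
        rng = np.random.default_rng(0)
        sd, k, reps = 2.0, 3, 10_000
        errs = np.empty(reps)
        for i in range(reps):
            pos = rng.normal(scale=sd, size=(k, 3))
            errs[i] = leave_one_out_error(pos)[0]
        s_eff = sd * np.sqrt(1 + 1 / (k - 1))
        expected = 2 * s_eff * np.sqrt(2 / np.pi)
        assert errs.mean() == pytest.approx(expected, rel=0.03)

    def test_icc_recovery_from_known_variance_ratio(self):
        """Matrices with subject/noise variance ratio rho give ICC(3,1)
        near rho/(rho+1) at n=30 (average over repeated seeds)."""
        rho = 4.0  # subject_sd^2 / noise_sd^2
        truth = rho / (rho + 1)
        estimates = [
            icc(
                make_icc_matrix(30, 3, subject_sd=2.0, noise_sd=1.0, seed=s),
                "(3,1)",
            ).icc
            for s in range(20)
        ]
        assert np.mean(estimates) == pytest.approx(truth, abs=0.05)
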