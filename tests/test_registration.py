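import numpy as np
import pytest

from emseg.image_io import Volume
from emseg.phantom import PhantomSpec, make_session
from emseg.registration import (DeformableUnavailableError, SpatialTransform,
                                _center, _euler_matrix, _matrix_about_center,
                                _rigid_matrix, deformable_backend, fuse_repeats,
                                register_affine, register_rigid, resample,
                                resample_prior_stack)


@pytest.fixture(scope="module")
def asym_volume():
    """Anisotropic phantom with an off-center blob so rotations are
    observable (the default phantom is spherically symmetric)."""
    from emseg.image_io import phantom_tissue_config
    from emseg.priors import TissueConfig

    spec = PhantomSpec(
        shape=(36, 30, 26), pn=1.0, seed=5,
        blobs=[("Thal", (0.12, 0.08, 0.0), 0.09)],
        means={**{c: dict(v) for c, v in PhantomSpec().means.items()},
               "Thal": {"T1": 100.0, "T2": 70.0}})
    configs = phantom_tissue_config() + [
        TissueConfig(name="Thal", super_class="WM&GM",
                     quantiles={"T1": (0.7, 1.0), "T2": (0.6, 0.9)})]
    return make_session(spec, configs=configs).session.fused_volume("T1")


def _move(fixed, true_matrix):
    """Synthesize a moving image whose pull-back alignment is true_matrix."""
    inv = SpatialTransform(kind="affine", matrix=np.linalg.inv(true_matrix))
    return resample(fixed, inv)


class TestSpatialTransform:
    def test_identity(self):
        tr = SpatialTransform.identity()
        pts = np.random.default_rng(0).normal(size=(3, 4, 4, 4))
        np.testing.assert_array_equal(tr.apply_points(pts), pts)

    def test_rigid_requires_orthonormal(self):
        mat = np.eye(4)
        mat[0, 0] = 2.0
        with pytest.raises(ValueError, match="orthonormal"):
            SpatialTransform(kind="rigid", matrix=mat)

    def test_rigid_compose_stays_rigid(self):
        c = np.zeros(3)
        a = SpatialTransform(kind="rigid",
                             matrix=_matrix_about_center(_euler_matrix(0, 0, 10),
                                                         np.array([1.0, 0, 0]), c))
        b = SpatialTransform(kind="rigid",
                             matrix=_matrix_about_center(_euler_matrix(5, 0, 0),
                                                         np.array([0, 2.0, 0]), c))
        ab = a.compose(b)
        assert ab.kind == "rigid"
        R = ab.matrix[:3, :3]
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)

    def test_compose_associative(self):
        rng = np.random.default_rng(3)
        mats = []
        for _ in range(3):
            R = _euler_matrix(*rng.uniform(-20, 20, 3))
            mats.append(SpatialTransform(
                kind="rigid",
                matrix=_matrix_about_center(R, rng.normal(size=3), np.zeros(3))))
        lhs = mats[0].compose(mats[1]).compose(mats[2])
        rhs = mats[0].compose(mats[1].compose(mats[2]))
        np.testing.assert_allclose(lhs.matrix, rhs.matrix, atol=1e-12)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            SpatialTransform(kind="affine", matrix=np.zeros((4, 4)))


class TestResample:
    def test_identity_unchanged(self, asym_volume):
        out = resample(asym_volume, SpatialTransform.identity())
        np.testing.assert_allclose(out.data, asym_volume.data, atol=1e-10)

    def test_integer_translation_nearest_exact_shift(self, asym_volume):
        mat = np.eye(4)
        mat[0, 3] = 2.0  # sample from x+2 -> content shifts by -2
        tr = SpatialTransform(kind="rigid", matrix=mat)
        out = resample(asym_volume, tr, interpolation="nearest")
        np.testing.assert_array_equal(out.data[:-2], asym_volume.data[2:])

    def test_out_of_domain_zero(self, asym_volume):
        mat = np.eye(4)
        mat[0, 3] = 1000.0
        tr = SpatialTransform(kind="rigid", matrix=mat)
        out = resample(asym_volume, tr)
        assert (out.data == 0).all()

    def test_prior_stack_renormalized(self, rng):
        maps = rng.dirichlet(np.ones(3), size=(8, 8, 8)).transpose(3, 0, 1, 2)
        mat = np.eye(4)
        mat[0, 3] = 0.5
        tr = SpatialTransform(kind="rigid", matrix=mat)
        out = resample_prior_stack(maps, (1, 1, 1), (0, 0, 0), tr,
                                   (8, 8, 8), (1, 1, 1), (0, 0, 0))
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-10)
        assert (out >= 0).all()

    def test_displacement_field_translation(self, asym_volume):
        disp = np.zeros((3,) + asym_volume.shape)
        disp[0] = 3.0
        tr = SpatialTransform(kind="displacement", displacement=disp)
        out = resample(asym_volume, tr, interpolation="nearest")
        np.testing.assert_array_equal(out.data[:-3], asym_volume.data[3:])


class TestRegisterRigid:
    def test_identity_pair(self, asym_volume):
        tr = register_rigid(asym_volume, asym_volume)
        c = _center(asym_volume)
        # displacement of the center and corners stays tiny
        assert np.linalg.norm(tr.apply_points(c.reshape(3, 1, 1, 1)) -
                              c.reshape(3, 1, 1, 1)) < 0.05
        angles = np.rad2deg(np.arccos(np.clip(
            (np.trace(tr.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert angles < 0.05

    def test_translation_recovered(self, asym_volume):
        true = _rigid_matrix(np.array([3.0, 0, 0, 0, 0, 0]),
                             _center(asym_volume))
        moving = _move(asym_volume, true)
        tr = register_rigid(asym_volume, moving)
        assert np.linalg.norm(tr.matrix[:3, 3] - true[:3, 3]) < 0.5

    def test_rotation_recovered(self, asym_volume):
        c = _center(asym_volume)
        true = _matrix_about_center(_euler_matrix(0, 0, 5.0), np.zeros(3), c)
        moving = _move(asym_volume, true)
        tr = register_rigid(asym_volume, moving)
        rec = np.rad2deg(np.arctan2(tr.matrix[1, 0], tr.matrix[0, 0]))
        assert abs(rec - 5.0) < 1.0

    def test_deterministic(self, asym_volume):
        true = _rigid_matrix(np.array([2.0, -1.0, 0, 0, 0, 0]),
                             _center(asym_volume))
        moving = _move(asym_volume, true)
        t1 = register_rigid(asym_volume, moving)
        t2 = register_rigid(asym_volume, moving)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)


class TestRegisterAffine:
    def test_identity_pair(self, asym_volume):
        tr = register_affine(asym_volume, asym_volume,
                             init=SpatialTransform.identity())
        np.testing.assert_allclose(np.diag(tr.matrix[:3, :3]), 1.0, atol=0.02)

    def test_scale_recovered_within_2_percent(self, asym_volume):
        c = _center(asym_volume)
        true = _matrix_about_center(np.diag([1.1, 1.0, 0.9]), np.zeros(3), c)
        moving = _move(asym_volume, true)
        tr = register_affine(asym_volume, moving,
                             init=SpatialTransform.identity())
        rec = np.diag(tr.matrix[:3, :3])
        np.testing.assert_allclose(rec, [1.1, 1.0, 0.9], rtol=0.02)

    def test_residual_displacement_below_one_voxel(self, asym_volume):
        c = _center(asym_volume)
        true = _matrix_about_center(np.diag([1.05, 1.0, 0.95]),
                                    np.array([1.0, 0, 0]), c)
        moving = _move(asym_volume, true)
        tr = register_affine(asym_volume, moving,
                             init=SpatialTransform.identity())
        resid = SpatialTransform(kind="affine",
                                 matrix=np.linalg.inv(true) @ tr.matrix)
        mask = asym_volume.data > 10
        pts = np.indices(asym_volume.shape, dtype=float)
        moved = resid.apply_points(pts)
        disp = np.linalg.norm((moved - pts)[:, mask], axis=0)
        assert disp.mean() < 1.0


class TestDeformableBackend:
    def test_missing_plugin_raises(self, asym_volume):
        with pytest.raises(DeformableUnavailableError, match="no deformable"):
            deformable_backend(asym_volume, asym_volume, plugin=None)

    def test_zero_field_stub_is_identity(self, asym_volume):
        import nibabel as nib

        def stub(fixed_path, moving_path, out_path):
            field = np.zeros(asym_volume.shape + (3,), dtype=np.float32)
            nib.save(nib.Nifti1Image(field, np.eye(4)), out_path)

        tr = deformable_backend(asym_volume, asym_volume, plugin=stub)
        out = resample(asym_volume, tr)
        np.testing.assert_allclose(out.data, asym_volume.data, atol=1e-10)

    def test_translation_field_stub_matches_shift_oracle(self, asym_volume):
        import nibabel as nib

        def stub(fixed_path, moving_path, out_path):
            field = np.zeros(asym_volume.shape + (3,), dtype=np.float32)
            field[..., 0] = 2.0
            nib.save(nib.Nifti1Image(field, np.eye(4)), out_path)

        tr = deformable_backend(asym_volume, asym_volume, plugin=stub)
        out = resample(asym_volume, tr, interpolation="nearest")
        np.testing.assert_array_equal(out.data[:-2], asym_volume.data[2:])

    def test_bad_field_shape_rejected(self, asym_volume):
        import nibabel as nib

        def stub(fixed_path, moving_path, out_path):
            nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32),
                                     np.eye(4)), out_path)

        with pytest.raises(DeformableUnavailableError, match="displacement"):
            deformable_backend(asym_volume, asym_volume, plugin=stub)


class TestFuseRepeats:
    def test_single_repeat_identity(self, asym_volume):
        out = fuse_repeats([asym_volume])
        np.testing.assert_array_equal(out.data, asym_volume.data)

    def test_mean_of_identical_is_image(self, asym_volume):
        out = fuse_repeats([asym_volume] * 3)
        np.testing.assert_allclose(out.data, asym_volume.data, atol=1e-12)

    def test_noise_reduction_sqrt2(self):
        rng = np.random.default_rng(8)
        clean = np.full((48, 48, 48), 100.0)
        sigma = 5.0
        reps = [Volume(clean + rng.normal(0, sigma, clean.shape))
                for _ in range(2)]
        fused = fuse_repeats(reps)
        resid_sd = (fused.data - clean).std()
        assert resid_sd == pytest.approx(sigma / np.sqrt(2), rel=0.05)

    def test_grid_mismatch_rejected(self, asym_volume):
        other = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="grid"):
            fuse_repeats([asym_volume, other])
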