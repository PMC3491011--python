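"""Registration primitives: resampling semantics, field algebra, linear and
non-rigid recovery, kernel-width selection."""

import numpy as np
import pytest

from gwtbss import imgreg, phantom
from gwtbss.core import ScalarVolume
from gwtbss.imgreg import AffineTransform, DisplacementField


def interior_rmse(a, b, margin=4):
    sl = tuple(slice(margin, -margin) for _ in range(3))
    return float(np.sqrt(np.mean((a.data[sl] - b.data[sl]) ** 2)))


class TestResample:
    def test_identity_trilinear_exact(self, template):
        out = imgreg.resample(template.fa_volume, imgreg.identity_affine())
        assert np.allclose(out.data, template.fa_volume.data)

    def test_integer_translation_nearest_is_shift(self, template):
        M = np.eye(4)
        M[0, 3] = 4.0  # two voxels at 2 mm spacing
        out = imgreg.resample(template.fa_volume, AffineTransform(M),
                              interpolation="nearest")
        assert np.array_equal(out.data[:-2], template.fa_volume.data[2:])

    def test_nearest_introduces_no_new_labels(self, template):
        rng = np.random.default_rng(3)
        fld = phantom._random_smooth_field(template.tract_labels.shape,
                                           template.tract_labels.voxel_size,
                                           4.0, 8.0, rng)
        out = imgreg.resample(template.tract_labels, fld, interpolation="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(template.tract_labels.data))

    def test_trilinear_preserves_range(self, template):
        rng = np.random.default_rng(4)
        fld = phantom._random_smooth_field(template.fa_volume.shape,
                                           template.fa_volume.voxel_size,
                                           5.0, 6.0, rng)
        out = imgreg.resample(template.fa_volume, fld, boundary="extend")
        assert out.data.min() >= template.fa_volume.data.min() - 1e-12
        assert out.data.max() <= template.fa_volume.data.max() + 1e-12

    def test_unknown_interpolation_raises(self, template):
        with pytest.raises(ValueError, match="interpolation"):
            imgreg.resample(template.fa_volume, imgreg.identity_affine(),
                            interpolation="cubic")


class TestFieldAlgebra:
    def test_compose_identity_is_noop(self, template):
        rng = np.random.default_rng(5)
        T = phantom._random_smooth_field(template.fa_volume.shape, (2, 2, 2),
                                         3.0, 8.0, rng)
        comp = imgreg.compose(imgreg.identity_affine(), T)
        assert np.allclose(comp.vectors, T.vectors, atol=1e-9)

    def test_invert_zero_field_is_zero(self):
        z = DisplacementField(np.zeros((8, 8, 8, 3)), (2, 2, 2))
        assert np.all(imgreg.invert(z).vectors == 0)

    def test_invert_compose_residual_below_half_voxel(self, template):
        rng = np.random.default_rng(6)
        T = phantom._random_smooth_field(template.fa_volume.shape, (2, 2, 2),
                                         4.0, 8.0, rng)
        resid = imgreg.compose(imgreg.invert(T), T)
        mean_vox = imgreg.deformation_magnitude(resid) / 2.0
        assert mean_vox <= 0.5

    def test_compose_matches_sequential_resampling(self, template):
        rng = np.random.default_rng(8)
        a = phantom._random_smooth_field(template.fa_volume.shape, (2, 2, 2),
                                         2.0, 10.0, rng)
        b = phantom._random_smooth_field(template.fa_volume.shape, (2, 2, 2),
                                         2.0, 10.0, rng)
        one = imgreg.resample(template.fa_volume, imgreg.compose(a, b))
        two = imgreg.resample(imgreg.resample(template.fa_volume, b), a)
        assert interior_rmse(one, two) < 0.01  # equal up to one interpolation

    def test_deformation_magnitude(self):
        z = DisplacementField(np.zeros((6, 6, 6, 3)), (2, 2, 2))
        assert imgreg.deformation_magnitude(z) == 0.0
        u = np.zeros((6, 6, 6, 3))
        u[..., 0] = 2.0
        assert imgreg.deformation_magnitude(DisplacementField(u, (2, 2, 2))) == 2.0
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 6, 6, 3))
        got = imgreg.deformation_magnitude(DisplacementField(v, (2, 2, 2)))
        want = float(np.mean([np.linalg.norm(v[i, j, k])
                              for i in range(6) for j in range(6) for k in range(6)]))
        assert np.isclose(got, want)

    def test_rigid_validation(self):
        M = np.eye(4)
        M[0, 0] = 2.0
        with pytest.raises(ValueError, match="orthonormal"):
            AffineTransform(M, kind="rigid")


class TestRegisterLinear:
    def test_identical_images_give_identity(self, template):
        T = imgreg.register_linear(template.fa_volume, template.fa_volume, "rigid")
        # translation below 0.1 voxel (0.2 mm at 2 mm spacing)
        assert np.linalg.norm(T.matrix[:3, 3]) < 0.2

    @pytest.mark.parametrize("shift", [(3, 0, 0), (0, 3, 0), (2, 3, -2)])
    def test_planted_translation_recovered(self, template, shift):
        M = np.eye(4)
        M[:3, 3] = shift
        moved = imgreg.resample(template.fa_volume, AffineTransform(M),
                                boundary="extend")
        T = imgreg.register_linear(moved, template.fa_volume, "rigid")
        err = np.linalg.norm(T.matrix[:3, 3] + np.asarray(shift, float))
        assert err <= 0.5

    def test_ncc_never_decreases(self, template):
        rng = np.random.default_rng(9)
        noisy = template.fa_volume.like(
            np.clip(template.fa_volume.data + rng.normal(0, 0.03,
                                                         template.fa_volume.shape), 0, 1))
        M = np.eye(4)
        M[:3, 3] = (2, -1, 1)
        moved = imgreg.resample(noisy, AffineTransform(M), boundary="extend")
        before = imgreg.ncc(moved.data, template.fa_volume.data)
        T = imgreg.register_linear(moved, template.fa_volume, "affine")
        after = imgreg.ncc(imgreg.resample(moved, T, boundary="extend").data,
                           template.fa_volume.data)
        assert after >= before

    def test_deterministic(self, template):
        rng = np.random.default_rng(10)
        noisy = template.fa_volume.like(
            np.clip(template.fa_volume.data + rng.normal(0, 0.02,
                                                         template.fa_volume.shape), 0, 1))
        a = imgreg.register_linear(noisy, template.fa_volume, "affine")
        b = imgreg.register_linear(noisy, template.fa_volume, "affine")
        assert np.array_equal(a.matrix, b.matrix)


class TestRegisterNonrigid:
    def test_identical_images_near_zero_field(self, template):
        for alg in ("pipeline", "independent"):
            fld = imgreg.register_nonrigid(template.fa_volume, template.fa_volume, alg)
            assert imgreg.deformation_magnitude(fld) / 2.0 < 0.2  # voxels

    def test_planted_field_recovery(self, template, small_warped_pair):
        warped, fld = small_warped_pair
        pre = interior_rmse(warped, template.fa_volume)
        est = imgreg.register_nonrigid(warped, template.fa_volume, "independent")
        post = interior_rmse(imgreg.resample(warped, est, boundary="extend"),
                             template.fa_volume)
        assert post <= 0.5 * pre
        est2 = imgreg.register_nonrigid(warped, template.fa_volume, "pipeline")
        post2 = interior_rmse(imgreg.resample(warped, est2, boundary="extend"),
                              template.fa_volume)
        assert post2 < pre  # the parametric path must also reduce the misfit

    def test_algorithms_are_distinct(self, template, small_warped_pair):
        warped, _ = small_warped_pair
        a = imgreg.register_nonrigid(warped, template.fa_volume, "pipeline")
        b = imgreg.register_nonrigid(warped, template.fa_volume, "independent")
        assert not np.allclose(a.vectors, b.vectors)

    def test_shape_mismatch_raises(self, template):
        small = ScalarVolume(np.zeros((16, 16, 16)), (2, 2, 2))
        with pytest.raises(ValueError, match="mismatch"):
            imgreg.register_nonrigid(small, template.fa_volume)


class TestKernelSelection:
    def test_identity_warp_selects_smallest(self, template):
        originals = [template.fa_volume]
        assert imgreg.select_kernel_width(originals, originals,
                                          (0.5, 1.0, 1.5, 2.0)) == 0.5

    def test_single_candidate(self, template):
        assert imgreg.select_kernel_width([template.fa_volume], [template.fa_volume],
                                          (1.5,)) == 1.5

    def test_matches_brute_force_argmin(self, template):
        rng = np.random.default_rng(11)
        originals, back = [], []
        for k in range(3):
            fld = phantom._random_smooth_field(template.fa_volume.shape, (2, 2, 2),
                                               3.0, 8.0, rng)
            originals.append(template.fa_volume)
            w = imgreg.resample(template.fa_volume, fld, boundary="extend")
            back.append(imgreg.resample(w, imgreg.invert(fld), boundary="extend"))
        candidates = (0.5, 1.0, 1.5, 2.0)
        got = imgreg.select_kernel_width(originals, back, candidates)
        table = []
        for sig in candidates:
            errs = [imgreg.rmse(imgreg.gaussian_smooth(o, sig).data, b.data)
                    for o, b in zip(originals, back)]
            table.append(np.mean(errs))
        assert got == candidates[int(np.argmin(table))]

    def test_mismatched_lengths_raise(self, template):
        with pytest.raises(ValueError, match="length"):
            imgreg.select_kernel_width([template.fa_volume], [], (0.5,))
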