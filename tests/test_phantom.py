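"""Phantom generator: geometry, determinism, planted-effect arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gwtbss import imgreg, phantom
from gwtbss.core import ScalarVolume


class TestMakeTemplate:
    def test_counts_and_determinism(self):
        a = phantom.make_template((48, 48, 48), (2, 2, 2), n_tracts=3, seed=1)
        assert len(a.centrelines) == 3
        assert set(np.unique(a.tract_labels.data)) == {0.0, 1.0, 2.0, 3.0}
        b = phantom.make_template((48, 48, 48), (2, 2, 2), n_tracts=3, seed=1)
        assert np.array_equal(a.fa_volume.data, b.fa_volume.data)
        assert np.array_equal(a.tract_labels.data, b.tract_labels.data)

    def test_fa_range_and_tissue_levels(self, template):
        fa = template.fa_volume.data
        assert fa.min() >= 0 and fa.max() <= 1
        assert fa.max() >= 0.6                      # tract peak
        assert fa[template.ventricle_mask].max() <= 0.1   # CSF-like
        # labels only where FA exceeds the background level
        labelled = template.tract_labels.data > 0
        assert fa[labelled].min() > phantom.BACKGROUND_FA

    def test_centreline_is_cross_section_maximum(self, template):
        """Brute-force scan: no voxel in the perpendicular disc of any
        centreline voxel exceeds the centreline FA."""
        fa = template.fa_volume.data
        h = np.asarray(template.fa_volume.voxel_size)
        radius = phantom.TUBE_RADIUS_MM
        for cl in template.centrelines:
            for k in range(1, len(cl) - 1, 5):
                c = cl[k]
                tangent = (cl[k + 1] - cl[k - 1]) * h
                tangent = tangent / np.linalg.norm(tangent)
                # all integer voxels within the tube radius, near-perpendicular
                span = np.array(np.meshgrid(*[np.arange(-3, 4)] * 3,
                                            indexing="ij")).reshape(3, -1).T
                for off in span:
                    d_mm = off * h
                    r = np.linalg.norm(d_mm)
                    if r == 0 or r > radius:
                        continue
                    if abs(d_mm @ tangent) > 0.5 * min(h):  # keep the disc
                        continue
                    v = c + off
                    if np.any(v < 0) or np.any(v >= fa.shape):
                        continue
                    assert fa[tuple(v)] <= fa[tuple(c)] + 1e-9

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError, match="32"):
            phantom.make_template((24, 48, 48))
        with pytest.raises(ValueError, match="small|tracts"):
            phantom.make_template((32, 32, 32), (1, 1, 1), n_tracts=4)


class TestMakeSubject:
    def test_zero_warp_zero_noise_is_identity(self, template):
        spec = phantom.CohortSpec(n_subjects=2, seed=3, warp_amplitude=0, noise_sd=0)
        img, fld = phantom.make_subject(template, spec, 0)
        assert np.array_equal(img.data, template.fa_volume.data)
        assert np.all(fld.vectors == 0)

    def test_deterministic_and_in_range(self, template):
        spec = phantom.CohortSpec(n_subjects=2, seed=3)
        a, fa_ = phantom.make_subject(template, spec, 1)
        b, fb_ = phantom.make_subject(template, spec, 1)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(fa_.vectors, fb_.vectors)
        assert a.data.min() >= 0 and a.data.max() <= 1

    def test_field_round_trips_through_resampler(self, template):
        spec = phantom.CohortSpec(n_subjects=2, seed=5, warp_amplitude=4, noise_sd=0)
        img, fld = phantom.make_subject(template, spec, 0)
        redo = imgreg.resample(template.fa_volume, fld, boundary="extend")
        assert np.abs(redo.data - img.data).max() <= 0.02

    def test_no_noise_change_bounded_by_warp(self, template):
        spec = phantom.CohortSpec(n_subjects=2, seed=5, warp_amplitude=4, noise_sd=0)
        img, fld = phantom.make_subject(template, spec, 0)
        # the warp moves values around: the largest possible change is
        # bounded by the image range, and zero where the field vanishes
        assert np.abs(img.data - template.fa_volume.data).max() <= \
            template.fa_volume.data.max() - template.fa_volume.data.min() + 1e-12


class TestSimulateAtrophy:
    def test_zero_severity_identity(self, template):
        out, fld = phantom.simulate_atrophy(template.fa_volume, template.ventricle_mask,
                                            severity=0.0, seed=1, random_amplitude_mm=0.0)
        assert np.array_equal(out.data, template.fa_volume.data)
        assert np.all(fld.vectors == 0)

    def test_ventricle_grows(self, template):
        out, _ = phantom.simulate_atrophy(template.fa_volume, template.ventricle_mask,
                                          severity=5.0, seed=1)
        before = int((template.fa_volume.data <= 0.05).sum())
        after = int((out.data <= 0.05).sum())
        assert after > before

    def test_forward_field_divergence_positive_inside_ventricle(self, template):
        _, fld = phantom.simulate_atrophy(template.fa_volume, template.ventricle_mask,
                                          severity=5.0, seed=1, random_amplitude_mm=0.0)
        h = template.fa_volume.voxel_size
        div = sum(np.gradient(fld.vectors[..., k], h[k], axis=k) for k in range(3))
        assert div[template.ventricle_mask].mean() > 0

    def test_empty_mask_raises(self, template):
        with pytest.raises(ValueError, match="empty"):
            phantom.simulate_atrophy(template.fa_volume,
                                     np.zeros(template.fa_volume.shape, bool), 1.0)


class TestReduceFa:
    def test_arithmetic(self):
        vol = ScalarVolume(np.full((4, 4, 4), 0.5), (1, 1, 1))
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        out = phantom.reduce_fa(vol, mask, 0.4)
        assert np.allclose(out.data[mask], 0.3)
        assert np.array_equal(out.data[~mask], vol.data[~mask])
        assert np.array_equal(phantom.reduce_fa(vol, mask, 0.0).data, vol.data)

    def test_mean_reduction_matches_fraction(self, template):
        vol = template.fa_volume
        mask = template.tract_labels.data == 1
        frac = 0.3
        out = phantom.reduce_fa(vol, mask, frac)
        assert np.isclose(out.data[mask].mean(), (1 - frac) * vol.data[mask].mean())
        assert np.array_equal(out.data[~mask], vol.data[~mask])

    def test_invalid_fraction(self, template):
        with pytest.raises(ValueError):
            phantom.reduce_fa(template.fa_volume, template.ventricle_mask, 1.0)
        with pytest.raises(ValueError):
            phantom.reduce_fa(template.fa_volume, template.ventricle_mask, -0.1)

    @given(frac=hst.floats(0.05, 0.9), split=hst.integers(1, 46))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_mask_partition(self, frac, split):
        """Reducing two disjoint masks sequentially equals reducing their
        union."""
        rng = np.random.default_rng(0)
        vol = ScalarVolume(rng.uniform(0, 1, (12, 12, 12)), (2, 2, 2))
        union = rng.uniform(0, 1, vol.shape) > 0.5
        part = np.zeros(vol.shape, bool)
        part.flat[: split * 30] = True
        a, b = union & part, union & ~part
        seq = phantom.reduce_fa(phantom.reduce_fa(vol, a, frac), b, frac)
        direct = phantom.reduce_fa(vol, union, frac)
        assert np.allclose(seq.data, direct.data)
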