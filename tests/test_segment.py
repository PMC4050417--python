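import numpy as np
import pytest

import gatedpet as gp
from gatedpet.segment import EmptySegmentationWarning


def bare_sphere_spec(radius=10.0, suv=7.9, background=2.97, amplitude=0.0,
                     fwhm=0.0, shape=(48, 48, 48), spacing=2.0, n_phases=6,
                     snapshot=True):
    """Sphere in a uniform background, no compartments: exact-arithmetic phantom."""
    geo = gp.GridGeometry(shape, (spacing,) * 3)
    center = tuple(geo.spacing[a] * geo.shape[a] / 2 for a in range(3))
    return gp.PhantomSpec(
        geometry=geo,
        background_suv=background,
        spheres=(gp.SphereSpec(center, radius, suv),),
        motion_amplitude_mm=amplitude,
        n_phases=n_phases,
        psf_fwhm_mm=fwhm,
        time_supersample=1 if snapshot else 5,
    )


class TestThresholdSegment:
    def test_strict_inequality_at_threshold(self, geo2mm):
        img = gp.SUVImage(geo2mm, np.full(geo2mm.shape, 2.97))
        assert gp.threshold_segment(img, 2.97).n_voxels == 0

    def test_noiseless_sphere_segmented_exactly(self):
        res = gp.simulate_gated(bare_sphere_spec())
        mask = gp.threshold_segment(res.series[0], (7.9 + 2.97) / 2)
        truth = res.truth_masks[0][0]
        np.testing.assert_array_equal(mask.values, truth.values)

    def test_blurred_sphere_volume_matches_analytic_oracle(self):
        spec = bare_sphere_spec(radius=15.63, fwhm=6.0, shape=(64, 64, 64))
        res = gp.simulate_gated(spec)
        tau = 4.0
        mask = gp.threshold_segment(res.series[0], tau)
        expected = gp.analytic_blurred_sphere_volume(
            15.63, 7.9, 2.97, 6.0 / (2 * np.sqrt(2 * np.log(2))), tau
        )
        assert gp.volume_cc(mask) == pytest.approx(expected, rel=0.03)

    def test_monotone_in_threshold(self):
        res = gp.simulate_gated(bare_sphere_spec(fwhm=6.0))
        img = res.series[0]
        prev = gp.threshold_segment(img, 3.1)
        for tau in (3.5, 4.0, 5.0, 6.0):
            cur = gp.threshold_segment(img, tau)
            assert not (cur.values & ~prev.values).any()  # cur subset of prev
            prev = cur

    def test_nonpositive_threshold_rejected(self, geo2mm):
        img = gp.SUVImage(geo2mm, np.ones(geo2mm.shape))
        with pytest.raises(ValueError):
            gp.threshold_segment(img, 0.0)


class TestLabelLesions:
    def test_two_spheres_two_labels(self, geo2mm, sphere_mask_factory):
        a = sphere_mask_factory(geo2mm, (16, 16, 16), 8.0)
        b = sphere_mask_factory(geo2mm, (48, 48, 48), 6.0)
        lset = gp.label_lesions(a.union(b), min_volume_cc=0.1)
        assert lset.n_lesions == 2
        vols = sorted(l.volume_cc for l in lset)
        assert vols == pytest.approx(sorted([gp.volume_cc(a), gp.volume_cc(b)]))

    def test_single_voxel_speck_removed(self, geo2mm):
        vals = np.zeros(geo2mm.shape, bool)
        vals[5, 5, 5] = True  # 0.008 cc at 2 mm spacing
        lset = gp.label_lesions(gp.BinaryMask(geo2mm, vals), min_volume_cc=0.1)
        assert lset.n_lesions == 0

    def test_scattered_specks_filtered_big_sphere_survives(self, geo2mm, sphere_mask_factory):
        rng = np.random.default_rng(4)
        vals = sphere_mask_factory(geo2mm, (32, 32, 32), 10.0).values.copy()
        sphere_count = vals.sum()
        specks = rng.random(geo2mm.shape) < 0.002
        specks[10:22, 10:22, 10:22] = False  # keep specks away from the sphere
        vals |= specks
        lset = gp.label_lesions(gp.BinaryMask(geo2mm, vals), min_volume_cc=0.5)
        # brute force: only components with > 0.5/0.008 = 62 voxels survive
        from scipy import ndimage
        lab, n = ndimage.label(vals, structure=np.ones((3, 3, 3)))
        sizes = np.bincount(lab.ravel())[1:]
        assert lset.n_lesions == int((sizes * geo2mm.voxel_volume_cc > 0.5).sum()) == 1
        assert lset.lesions[0].volume_cc == pytest.approx(sphere_count * 0.008)

    def test_empty_mask_empty_set(self, geo2mm):
        lset = gp.label_lesions(gp.BinaryMask(geo2mm, np.zeros(geo2mm.shape, bool)))
        assert lset.n_lesions == 0


class TestMatchAndBitv:
    def _phase_sets(self, spec, tau):
        res = gp.simulate_gated(spec)
        return gp.segment_series(res.series, tau), res

    def test_identical_phases_identity_correspondence(self):
        sets, _ = self._phase_sets(bare_sphere_spec(), 5.0)
        corr = gp.match_lesions(sets)
        assert corr.lesion_ids == [0]
        assert corr.phases_present(0) == list(range(6))

    def test_translating_sphere_single_identity(self):
        spec = bare_sphere_spec(radius=10.0, amplitude=8.0, shape=(48, 48, 64))
        sets, _ = self._phase_sets(spec, 5.0)
        corr = gp.match_lesions(sets)
        assert corr.lesion_ids == [0]
        assert corr.phases_present(0) == list(range(6))

    def test_bitv_equals_brute_force_union(self):
        spec = bare_sphere_spec(radius=10.0, amplitude=7.5, shape=(48, 48, 64))
        sets, res = self._phase_sets(spec, (7.9 + 2.97) / 2)
        corr = gp.match_lesions(sets)
        bitv = gp.build_bitv(corr, sets, corr.lesion_ids[0])
        union = np.zeros(spec.geometry.shape, bool)
        for masks in res.truth_masks:
            union |= masks[0].values
        np.testing.assert_array_equal(bitv.values, union)

    def test_static_bitv_equals_single_phase_btv(self):
        sets, _ = self._phase_sets(bare_sphere_spec(), 5.0)
        corr = gp.match_lesions(sets)
        bitv = gp.build_bitv(corr, sets, 0)
        btv = sets[0].mask_for(corr.mapping[0][0])
        np.testing.assert_array_equal(bitv.values, btv.values)
        assert gp.volume_cc(bitv) == pytest.approx(gp.volume_cc(btv))

    def test_bitv_superset_of_each_phase(self):
        spec = bare_sphere_spec(radius=10.0, amplitude=10.0, shape=(48, 48, 72))
        sets, _ = self._phase_sets(spec, 5.0)
        corr = gp.match_lesions(sets)
        bitv = gp.build_bitv(corr, sets, 0)
        for p, lab in enumerate(corr.mapping[0]):
            if lab is not None:
                phase_mask = sets[p].mask_for(lab)
                assert not (phase_mask.values & ~bitv.values).any()
                assert gp.volume_cc(bitv) >= gp.volume_cc(phase_mask)

    def test_disjoint_positions_volumes_add(self, geo2mm, sphere_mask_factory):
        a = sphere_mask_factory(geo2mm, (32, 32, 16), 7.0)
        b = sphere_mask_factory(geo2mm, (32, 32, 48), 7.0)
        sets = [gp.label_lesions(m) for m in (a, b)]
        corr = gp.match_lesions(sets, capture_radius_mm=40.0)
        assert corr.lesion_ids == [0]  # centroid fallback links them
        bitv = gp.build_bitv(corr, sets, 0)
        assert gp.volume_cc(bitv) == pytest.approx(gp.volume_cc(a) + gp.volume_cc(b))

    def test_lesion_present_in_single_phase(self, geo2mm, sphere_mask_factory):
        empty = gp.BinaryMask(geo2mm, np.zeros(geo2mm.shape, bool))
        blob = sphere_mask_factory(geo2mm, (16, 16, 16), 6.0)
        sets = [gp.label_lesions(m) for m in [empty, empty, blob, empty, empty, empty]]
        corr = gp.match_lesions(sets)
        assert corr.phases_present(0) == [2]

    def test_unknown_lesion_id_rejected(self, geo2mm, sphere_mask_factory):
        sets = [gp.label_lesions(sphere_mask_factory(geo2mm, (16, 16, 16), 6.0))]
        corr = gp.match_lesions(sets)
        with pytest.raises(KeyError):
            gp.build_bitv(corr, sets, 99)


class TestNongatedBtv:
    def test_seed_inside_blob_returns_blob(self, geo2mm, sphere_mask_factory):
        blob = sphere_mask_factory(geo2mm, (32, 32, 32), 8.0)
        img = gp.SUVImage(geo2mm, np.where(blob.values, 6.0, 1.0))
        btv = gp.nongated_btv(img, 3.0, (32, 32, 32))
        np.testing.assert_array_equal(btv.values, blob.values)

    def test_seed_far_from_blobs_warns_empty(self, geo2mm, sphere_mask_factory):
        blob = sphere_mask_factory(geo2mm, (48, 48, 48), 6.0)
        img = gp.SUVImage(geo2mm, np.where(blob.values, 6.0, 1.0))
        with pytest.warns(EmptySegmentationWarning):
            btv = gp.nongated_btv(img, 3.0, (8, 8, 8))
        assert btv.n_voxels == 0

    def test_moving_lesion_lost_on_nongated_but_visible_gated(self):
        spec = gp.occult_lesion_preset()
        res = gp.simulate_gated(spec)
        ng = gp.simulate_nongated(res.series)
        tau = 4.3
        seed = spec.spheres[0].center_mm
        with pytest.warns(EmptySegmentationWarning):
            btv_ng = gp.nongated_btv(ng, tau, seed)
        assert btv_ng.n_voxels == 0
        gated_masks = [gp.threshold_segment(ph, tau) for ph in res.series]
        assert any(m.n_voxels > 0 for m in gated_masks)
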