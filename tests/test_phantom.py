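import numpy as np
import pytest

import gatedpet as gp
from gatedpet.phantom import FWHM_TO_SIGMA, blurred_sphere_profile


class TestSpecValidation:
    def test_sphere_leaving_grid_under_motion_rejected(self):
        geo = gp.GridGeometry((32, 32, 32), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="leaves the grid"):
            gp.PhantomSpec(
                geometry=geo,
                background_suv=1.0,
                spheres=(gp.SphereSpec((32, 32, 32), 10.0, 5.0),),
                motion_amplitude_mm=30.0,
            )

    def test_negative_parameters_rejected(self):
        geo = gp.GridGeometry((16, 16, 16), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            gp.PhantomSpec(geometry=geo, background_suv=1.0, psf_fwhm_mm=-1.0)
        with pytest.raises(ValueError):
            gp.PhantomSpec(geometry=geo, background_suv=1.0, n_phases=0)


class TestSimulateGated:
    def test_static_noiseless_sharp_phases_identical_and_exact(self):
        geo = gp.GridGeometry((40, 40, 40), (2.0, 2.0, 2.0))
        spec = gp.PhantomSpec(
            geometry=geo,
            background_suv=1.0,
            spheres=(gp.SphereSpec((40, 40, 40), 10.0, 5.0),),
            psf_fwhm_mm=0.0,
        )
        res = gp.simulate_gated(spec)
        for ph in res.series.phases[1:]:
            np.testing.assert_array_equal(ph.values, res.series[0].values)
        assert res.series[0].suv_max == pytest.approx(5.0)

    def test_blurred_profile_matches_analytic_within_1pct(self, torso16_static):
        res = torso16_static
        spec = res.spec
        sphere = spec.spheres[0]
        sigma = spec.psf_fwhm_mm * FWHM_TO_SIGMA
        geo = spec.geometry
        cx, cy, cz = geo.voxel_centers()
        i = int(round((sphere.center_mm[0] - geo.origin[0]) / geo.spacing[0]))
        j = int(round((sphere.center_mm[1] - geo.origin[1]) / geo.spacing[1]))
        vals = res.series[0].values[i, j, :]
        # craniocaudal profile through the sphere centre; at the centre the
        # agreement is sub-1%, along the blurred edge voxel box-integration
        # widens the effective sigma slightly (sqrt(sigma^2 + h^2/12))
        r = np.abs(cz - sphere.center_mm[2])
        k = int(round((sphere.center_mm[2] - geo.origin[2]) / geo.spacing[2]))
        centre_expected = blurred_sphere_profile(
            r[k], sphere.radius_mm, sphere.suv, 2.97, sigma
        )
        assert vals[k] == pytest.approx(centre_expected, rel=0.01)
        sel = r <= sphere.radius_mm + 1.5 * sigma
        expected = blurred_sphere_profile(r[sel], sphere.radius_mm, sphere.suv, 2.97, sigma)
        np.testing.assert_allclose(vals[sel], expected, rtol=0.025)

    def test_fixed_seed_bit_identical(self):
        def run():
            spec = gp.torso_preset(
                "torso8", noise="gaussian_sqrt", seed=42,
                geometry=gp.GridGeometry((48, 48, 48), (2, 2, 2)),
            )
            return gp.simulate_gated(spec)

        a, b = run(), run()
        for pa, pb in zip(a.series, b.series):
            np.testing.assert_array_equal(pa.values, pb.values)
        np.testing.assert_array_equal(
            a.healthy_liver_mask.values, b.healthy_liver_mask.values
        )

    def test_truth_mask_volume_matches_sphere(self, torso16_static):
        truth = torso16_static.truth_masks[0][0]
        assert gp.volume_cc(truth) == pytest.approx(16.0, rel=0.02)

    def test_healthy_liver_excludes_lesion_neighbourhood(self, torso16_static):
        res = torso16_static
        assert res.healthy_liver_mask.n_voxels < res.liver_mask.n_voxels
        # lesion centre voxel is not healthy liver
        geo = res.spec.geometry
        c = res.spec.spheres[0].center_mm
        idx = tuple(int(round((c[a] - geo.origin[a]) / geo.spacing[a])) for a in range(3))
        assert not res.healthy_liver_mask.values[idx]


class TestSimulateNongated:
    def test_static_equals_any_phase(self):
        spec = gp.torso_preset(
            "torso8", geometry=gp.GridGeometry((48, 48, 48), (2, 2, 2))
        )
        res = gp.simulate_gated(spec)
        ng = gp.simulate_nongated(res.series)
        np.testing.assert_allclose(ng.values, res.series[0].values, atol=1e-12)

    def test_two_phase_weighted_mean(self, geo2mm):
        a = gp.SUVImage(geo2mm, np.full(geo2mm.shape, 2.0))
        b = gp.SUVImage(geo2mm, np.full(geo2mm.shape, 6.0))
        series = gp.GatedSeries([a, b], phase_fractions=[0.25, 0.75])
        ng = gp.simulate_nongated(series)
        assert ng.values.flat[0] == pytest.approx(0.25 * 2 + 0.75 * 6)

    def test_moving_sphere_loses_peak_contrast(self):
        spec = gp.torso_preset(
            "torso8", motion_amplitude_mm=10.0,
            geometry=gp.GridGeometry((48, 48, 64), (2, 2, 2)),
        )
        res = gp.simulate_gated(spec)
        ng = gp.simulate_nongated(res.series)
        assert ng.suv_max < max(ph.suv_max for ph in res.series)


class TestPresets:
    def test_jaszczak_sphere_volume_converges(self):
        spec = gp.jaszczak_preset(16.0, 8.0)
        assert spec.background_suv == 0.0
        assert spec.compartments[0].suv == pytest.approx(1.23)
        # rasterized at 1 mm the sphere mask volume is within 2% of 16 cc
        from gatedpet.phantom import _sphere_occupancy
        geo = gp.GridGeometry((44, 44, 44), (1.0, 1.0, 1.0))
        s = spec.spheres[0]
        occ = _sphere_occupancy(geo, (22.0, 22.0, 22.0), s.radius_mm, 3)
        vol = (occ >= 0.5).sum() * geo.voxel_volume_cc
        assert vol == pytest.approx(16.0, rel=0.02)

    def test_jaszczak_contrast_bookkeeping(self):
        spec = gp.jaszczak_preset(4.0, 2.0)
        ratio = spec.spheres[0].suv / spec.compartments[0].suv
        assert ratio == pytest.approx(2.0 / 1.17, abs=0.005)
        assert ratio == pytest.approx(1.71, abs=0.005)

    def test_jaszczak_is_static(self):
        spec = gp.jaszczak_preset(8.0, 4.0)
        assert spec.motion_amplitude_mm == 0.0
        with pytest.raises(ValueError):
            gp.jaszczak_preset(10.0, 8.0)  # not a fillable sphere size

    def test_torso_configs(self):
        s16 = gp.torso_preset("torso16")
        s8 = gp.torso_preset("torso8")
        assert s16.spheres[0].volume_cc == pytest.approx(16.0, rel=1e-6)
        assert s16.spheres[0].suv == 7.9
        assert s8.spheres[0].volume_cc == pytest.approx(8.0, rel=1e-6)
        assert s8.spheres[0].suv == 5.6
        assert s16.liver.suv == 2.97
        with pytest.raises(ValueError):
            gp.torso_preset("torso4")


class TestAnalyticOracle:
    def test_sigma_zero_limit_recovers_true_sphere(self):
        for tau in (3.0, 5.0, 7.5):
            v = gp.analytic_blurred_sphere_volume(15.63, 7.9, 2.97, 0.0, tau)
            assert v == pytest.approx(4 / 3 * np.pi * 15.63**3 / 1000)

    def test_monotone_decreasing_in_tau(self):
        taus = np.linspace(3.2, 7.0, 12)
        vols = [gp.analytic_blurred_sphere_volume(15.63, 7.9, 2.97, 4.0, t) for t in taus]
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_threshold_at_background_overestimates(self):
        # tau just above background inflates the 16 cc sphere
        v = gp.analytic_blurred_sphere_volume(15.63, 7.9, 2.97, 4.0, 2.97 + 0.05)
        assert v > 16.0

    def test_tau_outside_profile_range_rejected(self):
        with pytest.raises(ValueError):
            gp.analytic_blurred_sphere_volume(15.63, 7.9, 2.97, 4.0, 2.97)
        with pytest.raises(ValueError):
            gp.analytic_blurred_sphere_volume(15.63, 7.9, 2.97, 4.0, 7.9)

    def test_profile_matches_numeric_radial_integration(self):
        from scipy import integrate

        R, A, b, sigma = 12.0, 6.0, 2.0, 3.0

        def numeric(r):
            def integrand(z):
                rad2 = R * R - z * z
                if rad2 <= 0:
                    return 0.0
                return (1 - np.exp(-rad2 / (2 * sigma**2))) * np.exp(
                    -((z - r) ** 2) / (2 * sigma**2)
                )

            val, _ = integrate.quad(integrand, -R, R)
            return b + (A - b) * val / (np.sqrt(2 * np.pi) * sigma)

        for r in (0.0, 4.0, 11.0, 14.0, 20.0):
            assert blurred_sphere_profile(r, R, A, b, sigma) == pytest.approx(
                numeric(r), rel=1e-9
            )


class TestEndToEndRecovery:
    def test_protocol_threshold_segmentation_matches_oracle(self, torso16_noisy_fwhm4):
        """Full chain on the default-noise phantom: measured background
        threshold -> segmentation -> volume agrees with the analytic
        blurred-sphere prediction at that threshold, with the positive
        partial-volume bias of threshold-near-background segmentation."""
        res = torso16_noisy_fwhm4
        est = gp.estimate_threshold(res.series[0], res.healthy_liver_mask, seed=0)
        lset = gp.label_lesions(
            gp.threshold_segment(res.series[0], est.threshold), 0.1
        )
        vol = max(l.volume_cc for l in lset)
        sigma = 4.0 * FWHM_TO_SIGMA
        expected = gp.analytic_blurred_sphere_volume(
            gp.sphere_radius_mm(16.0), 7.9, 2.97, sigma, est.threshold
        )
        assert vol == pytest.approx(expected, rel=0.05)
        assert vol > 16.0  # bias is positive
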