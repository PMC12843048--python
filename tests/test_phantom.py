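"""Synthetic phantom construction and acquisition simulation."""

import numpy as np
import pytest

import uteqsm as u
from uteqsm.phantom import TE_KNEE_S, TE_PHANTOM_S, FatRegion


class TestSpec:
    def test_default_concentration_design(self):
        spec = u.PhantomSpec()
        assert spec.dia_concentrations == (522.0, 347.0, 174.0)
        assert spec.para_concentrations == (12.0, 8.0, 4.0)
        assert spec.dia_slope < 0 < spec.para_slope

    def test_echo_presets(self):
        np.testing.assert_allclose(
            np.asarray(TE_PHANTOM_S) * 1e3,
            [0.05, 0.2, 0.4, 0.8, 2.2, 3.3, 4.4, 5.5],
        )
        np.testing.assert_allclose(
            np.asarray(TE_KNEE_S) * 1e3, [0.032, 0.2, 0.6, 2.7, 3.7, 4.7]
        )

    def test_sign_conventions_enforced(self):
        with pytest.raises(ValueError, match="dia_slope"):
            u.PhantomSpec(dia_slope=0.001)
        with pytest.raises(ValueError, match="para_slope"):
            u.PhantomSpec(para_slope=-0.001)


class TestMakeTubePhantom:
    def test_signed_maps_and_disjoint_rois(self, small_phantom):
        spec, gt = small_phantom
        assert (gt.chi_para_gt >= 0).all()
        assert (gt.chi_dia_gt <= 0).all()
        labels = np.unique(gt.tube_rois)
        assert set(labels) == {0, 1, 2, 3}
        # ROI interiors carry exactly the concentration * slope plateau
        for i in (1, 2, 3):
            sel = gt.tube_rois == i
            np.testing.assert_allclose(
                gt.chi_para_gt[sel],
                spec.para_concentrations[i - 1] * spec.para_slope,
            )

    def test_r2star_composition(self, small_phantom):
        spec, gt = small_phantom
        sel = gt.tube_rois == 1
        expected = (
            spec.background_r2
            + spec.r2_slope_para * spec.para_concentrations[0]
            + spec.r2_slope_dia * spec.dia_concentrations[0]
        )
        np.testing.assert_allclose(gt.r2star_gt[sel], expected)

    def test_zero_concentrations_zero_chi(self):
        geom = u.phantom_geometry(32)
        spec = u.PhantomSpec(
            dia_concentrations=(0, 0, 0), para_concentrations=(0, 0, 0),
            container_radius_mm=28.0, container_length_mm=48.0, tube_length_mm=32.0,
        )
        gt = u.make_tube_phantom(spec, geom)
        np.testing.assert_array_equal(gt.chi_para_gt, 0.0)
        np.testing.assert_array_equal(gt.chi_dia_gt, 0.0)
        np.testing.assert_allclose(
            gt.r2star_gt[gt.mask_gt], spec.background_r2, rtol=1e-9
        )

    def test_doubling_concentrations_doubles_chi(self):
        geom = u.phantom_geometry(32)
        base = dict(container_radius_mm=28.0, container_length_mm=48.0,
                    tube_length_mm=32.0)
        s1 = u.PhantomSpec(**base)
        s2 = u.PhantomSpec(
            dia_concentrations=tuple(2 * c for c in s1.dia_concentrations),
            para_concentrations=tuple(2 * c for c in s1.para_concentrations),
            **base,
        )
        g1 = u.make_tube_phantom(s1, geom)
        g2 = u.make_tube_phantom(s2, geom)
        np.testing.assert_allclose(g2.chi_para_gt, 2 * g1.chi_para_gt, atol=1e-15)
        np.testing.assert_allclose(g2.chi_dia_gt, 2 * g1.chi_dia_gt, atol=1e-15)

    def test_overlapping_tubes_rejected(self):
        geom = u.phantom_geometry(48)
        with pytest.raises(ValueError, match="overlap"):
            u.make_tube_phantom(
                u.PhantomSpec(
                    tube_centers_mm=((0, 0, 0), (5, 0, 0), (20, 20, 0)),
                    container_length_mm=80.0, tube_length_mm=56.0,
                ),
                geom,
            )

    def test_tube_outside_container_rejected(self):
        geom = u.phantom_geometry(48)
        with pytest.raises(ValueError, match="container"):
            u.make_tube_phantom(
                u.PhantomSpec(
                    tube_centers_mm=((38, 0, 0), (-20, 0, 0), (0, 20, 0)),
                    container_length_mm=80.0, tube_length_mm=56.0,
                ),
                geom,
            )


class TestSimulateAcquisition:
    def test_noise_free_flat_field_pure_decay(self):
        """With zero chi everywhere the magnitude decays mono-exponentially."""
        geom = u.phantom_geometry(32)
        spec = u.PhantomSpec(
            dia_concentrations=(0, 0, 0), para_concentrations=(0, 0, 0),
            container_radius_mm=28.0, container_length_mm=48.0, tube_length_mm=32.0,
        )
        gt = u.make_tube_phantom(spec, geom)
        ser = u.simulate_acquisition(gt, TE_PHANTOM_S, snr=np.inf)
        sel = gt.tube_rois == 1
        te = np.asarray(TE_PHANTOM_S)
        mags = np.abs(ser.data[:, sel])
        expected = np.exp(-np.outer(te, np.full(sel.sum(), spec.background_r2)))
        np.testing.assert_allclose(mags, expected, rtol=1e-12)

    def test_same_seed_bit_identical(self, small_phantom):
        spec, gt = small_phantom
        a = u.simulate_acquisition(gt, TE_KNEE_S, snr=30.0, seed=11)
        b = u.simulate_acquisition(gt, TE_KNEE_S, snr=30.0, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_scale_matches_snr(self, small_phantom):
        spec, gt = small_phantom
        clean = u.simulate_acquisition(gt, TE_KNEE_S, snr=np.inf)
        noisy = u.simulate_acquisition(gt, TE_KNEE_S, snr=50.0, seed=5)
        resid = (noisy.data - clean.data).real.ravel()
        mean_mag = np.abs(clean.data[0][gt.mask_gt]).mean()
        assert np.std(resid) == pytest.approx(mean_mag / 50.0, rel=0.02)

    def test_seed_required_with_noise(self, small_phantom):
        spec, gt = small_phantom
        with pytest.raises(ValueError, match="seed"):
            u.simulate_acquisition(gt, TE_KNEE_S, snr=40.0)

    def test_empty_echo_list_rejected(self, small_phantom):
        spec, gt = small_phantom
        with pytest.raises(ValueError, match="echo"):
            u.simulate_acquisition(gt, [], snr=np.inf)

    def test_fat_region_produces_fat_signal(self):
        geom = u.phantom_geometry(32)
        spec = u.PhantomSpec(
            dia_concentrations=(0, 0, 0), para_concentrations=(0, 0, 0),
            container_radius_mm=28.0, container_length_mm=48.0, tube_length_mm=32.0,
            fat_regions=(FatRegion((0, 0, 0), 8.0, 0.5),),
        )
        gt = u.make_tube_phantom(spec, geom)
        assert gt.fat_fraction_gt.max() == pytest.approx(0.5)


class TestRoundTrips:
    def test_fitted_field_matches_simulated_field(self, small_phantom, spectrum3t):
        """IDEAL round trip: fitted B0 equals the simulated field (noise-free)."""
        spec, gt = small_phantom
        ext = [u.ExternalSphere()]
        ser = u.simulate_acquisition(gt, TE_PHANTOM_S, snr=np.inf, external_sources=ext)
        f_true = u.simulated_field_hz(gt, ext).values
        fit = u.fit_ideal_volume(ser, spectrum3t, gt.mask_gt)
        m = gt.mask_gt & fit.converged
        assert np.abs(fit.f_b0_hz - f_true)[m].max() <= 0.1
        r2fit = 1.0 / fit.t2star_s[m]
        r2rel = np.abs(r2fit - gt.r2star_gt[m]) / gt.r2star_gt[m]
        assert r2rel.max() <= 0.01
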