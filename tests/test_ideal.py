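"""Multi-echo water/fat/B0/T2* model and its variable-projection fitter."""

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings, strategies as st

import uteqsm as u
from uteqsm.phantom import TE_PHANTOM_S

TE = np.array(TE_PHANTOM_S)


def brute_force_fit(signal, te, spectrum, f_range=500.0, f_step=10.0):
    """Independent dense-grid oracle: scan (f_B0, R2*, phi0) and solve
    the nonnegative amplitudes by NNLS on the stacked real system."""
    fat = spectrum.phasor(te, 3.0)
    best = (np.inf, None)
    yr = np.concatenate([signal.real, signal.imag])
    for f in np.arange(-f_range, f_range + f_step / 2, f_step):
        ph = np.exp(2j * np.pi * f * te)
        for r2s in np.linspace(0.0, 400.0, 21):
            a = np.exp(-r2s * te) * ph
            b = fat * ph
            for phi in np.linspace(-np.pi, np.pi, 36, endpoint=False):
                A = np.stack([a * np.exp(1j * phi), b * np.exp(1j * phi)], axis=1)
                Ar = np.vstack([A.real, A.imag])
                x, rnorm = scipy.optimize.nnls(Ar, yr)
                if rnorm < best[0]:
                    best = (rnorm, (f, r2s, phi, x))
    return best[1]


class TestFatSpectrum:
    def test_packaged_six_peak_table(self, spectrum3t):
        assert spectrum3t.n_peaks == 6
        assert sum(spectrum3t.amplitudes) == pytest.approx(1.0, abs=1e-9)
        mean_shift = float(
            np.dot(spectrum3t.amplitudes, spectrum3t.shifts_hz)
        )
        # dominant-methylene convention: about -440 Hz at 3 T
        assert abs(mean_shift - (-440.0)) <= 15.0

    def test_shifts_scale_linearly_with_field(self, spectrum3t):
        half = u.default_fat_spectrum(1.5)
        np.testing.assert_allclose(
            np.asarray(half.shifts_hz), 0.5 * np.asarray(spectrum3t.shifts_hz)
        )
        np.testing.assert_allclose(
            spectrum3t.shifts_at(1.5), 0.5 * np.asarray(spectrum3t.shifts_hz)
        )

    def test_invalid_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            u.FatSpectrum(amplitudes=(0.5, 0.6), shifts_hz=(-440.0, -300.0))


class TestSignalModel:
    def test_zero_te_value(self, spectrum3t):
        p = u.SignalParams(s_w=0.7, s_f=0.3, phi0=0.9, f_b0_hz=123.0, t2star_s=0.01)
        s0 = u.eval_signal_model(p, spectrum3t, 0.0)
        assert s0 == pytest.approx((0.7 + 0.3) * np.exp(1j * 0.9))

    def test_pure_water_real_decay(self, spectrum3t):
        p = u.SignalParams(s_w=2.0, s_f=0.0, phi0=0.0, f_b0_hz=0.0, t2star_s=0.02)
        s = u.eval_signal_model(p, spectrum3t, TE)
        np.testing.assert_allclose(s, 2.0 * np.exp(-TE / 0.02))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(f=st.floats(-500, 500), phi=st.floats(-3.1, 3.1))
    def test_magnitude_invariant_to_phase_terms_without_fat(self, spectrum3t, f, phi):
        p = u.SignalParams(s_w=1.0, s_f=0.0, phi0=phi, f_b0_hz=f, t2star_s=0.015)
        ref = u.SignalParams(s_w=1.0, s_f=0.0, phi0=0.0, f_b0_hz=0.0, t2star_s=0.015)
        np.testing.assert_allclose(
            np.abs(u.eval_signal_model(p, spectrum3t, TE)),
            np.abs(u.eval_signal_model(ref, spectrum3t, TE)),
            atol=1e-12,
        )

    def test_nonpositive_t2star_rejected(self, spectrum3t):
        p = u.SignalParams(s_w=1, s_f=0, phi0=0, f_b0_hz=0, t2star_s=0.0)
        with pytest.raises(ValueError, match="T2"):
            u.eval_signal_model(p, spectrum3t, TE)


class TestVoxelFit:
    def test_water_only_recovery_matches_brute_force_basin(self, spectrum3t):
        truth = u.SignalParams(s_w=1.0, s_f=0.0, phi0=0.3, f_b0_hz=25.0, t2star_s=0.020)
        sig = u.eval_signal_model(truth, spectrum3t, TE)
        fit = u.fit_ideal_voxel(sig, TE, spectrum3t)
        assert fit.s_w == pytest.approx(truth.s_w, rel=1e-6)
        assert fit.phi0 == pytest.approx(truth.phi0, rel=1e-6)
        assert fit.f_b0_hz == pytest.approx(truth.f_b0_hz, rel=1e-6)
        assert fit.t2star_s == pytest.approx(truth.t2star_s, rel=1e-6)
        assert fit.s_f == pytest.approx(0.0, abs=1e-6)
        # independent oracle: the global basin sits at the truth's grid node
        f_o, r_o, phi_o, amps_o = brute_force_fit(np.asarray(sig), TE, spectrum3t)
        assert abs(f_o - truth.f_b0_hz) <= 10.0
        assert abs(r_o - 1.0 / truth.t2star_s) <= 20.0
        assert amps_o[0] > 10 * amps_o[1]

    def test_fat_fraction_recovery(self, spectrum3t):
        truth = u.SignalParams(s_w=0.6, s_f=0.4, phi0=-0.7, f_b0_hz=-60.0, t2star_s=0.010)
        sig = u.eval_signal_model(truth, spectrum3t, TE)
        fit = u.fit_ideal_voxel(sig, TE, spectrum3t)
        ff = fit.s_f / (fit.s_w + fit.s_f)
        assert ff == pytest.approx(0.4, abs=1e-4)
        f_o, r_o, _, amps_o = brute_force_fit(np.asarray(sig), TE, spectrum3t)
        assert abs(f_o - truth.f_b0_hz) <= 10.0
        ff_o = amps_o[1] / amps_o.sum()
        assert abs(ff_o - 0.4) < 0.1

    def test_refit_idempotence(self, spectrum3t):
        """Refitting a converged fit's model prediction reproduces it."""
        truth = u.SignalParams(s_w=0.8, s_f=0.2, phi0=1.1, f_b0_hz=40.0, t2star_s=0.008)
        sig = u.eval_signal_model(truth, spectrum3t, TE)
        fit1 = u.fit_ideal_voxel(sig, TE, spectrum3t)
        sig2 = u.eval_signal_model(fit1, spectrum3t, TE)
        fit2 = u.fit_ideal_voxel(sig2, TE, spectrum3t)
        for attr in ("s_w", "s_f", "phi0", "f_b0_hz", "t2star_s"):
            assert getattr(fit2, attr) == pytest.approx(
                getattr(fit1, attr), rel=1e-6, abs=1e-8
            )

    def test_degenerate_signal_raises(self, spectrum3t):
        with pytest.raises(ValueError, match="degenerate"):
            u.fit_ideal_voxel(np.zeros(8, complex), TE, spectrum3t)
        with pytest.raises(ValueError, match="4 echoes"):
            u.fit_ideal_voxel(np.ones(3, complex), TE[:3], spectrum3t)


def _synthetic_volume(spectrum, f_map, ff_map, t2s_map, phi0=0.3):
    """Vectorized forward model over a parameter-map volume (noise-free)."""
    shape = f_map.shape
    geometry = u.AcquisitionGeometry(shape=shape, voxel_size_mm=(2.0, 2.0, 2.0))
    fat_ph = spectrum.phasor(TE, geometry.field_strength_T)
    data = np.empty((TE.size, *shape), complex)
    for e, t in enumerate(TE):
        core = (1 - ff_map) * np.exp(-t / t2s_map) + ff_map * fat_ph[e]
        data[e] = core * np.exp(1j * (phi0 + 2 * np.pi * f_map * t))
    return u.MultiEchoSeries(data=data, echo_times_s=tuple(TE), geometry=geometry)


@pytest.fixture(scope="module")
def param_grid_fit(spectrum3t):
    f = np.linspace(-100, 100, 9)[:, None, None]
    ff = np.array([0.0, 0.15, 0.35, 0.6, 0.85, 1.0, 0.05, 0.5])[None, :, None]
    t2s = np.array(
        [3e-3, 5e-3, 8e-3, 15e-3, 30e-3, 60e-3, 20e-3, 10e-3]
    )[None, None, :]
    f, ff, t2s = np.broadcast_arrays(f + 0 * ff + 0 * t2s, ff + 0 * f, t2s + 0 * f)
    series = _synthetic_volume(spectrum3t, f, ff, t2s)
    mask = np.ones(f.shape, bool)
    fit = u.fit_ideal_volume(series, spectrum3t, mask,
                             u.FitOptions(search_range_hz=700.0))
    return f, ff, t2s, fit


class TestVolumeFit:

    def test_noise_free_field_map_recovery(self, param_grid_fit):
        f, ff, t2s, fit = param_grid_fit
        assert np.abs(fit.f_b0_hz - f).max() <= 0.1

    def test_noise_free_t2star_and_fat_fraction(self, param_grid_fit):
        f, ff, t2s, fit = param_grid_fit
        # T2* of the water pool is undefined where there is no water signal
        has_water = ff < 0.999
        rel = np.abs(fit.t2star_s - t2s)[has_water] / t2s[has_water]
        assert rel.max() <= 0.01
        maps = u.derive_maps(fit)
        assert np.abs(maps["fat_fraction"] - ff).max() <= 1e-3

    def test_no_fat_water_swaps_within_100hz(self, param_grid_fit):
        f, ff, t2s, fit = param_grid_fit
        maps = u.derive_maps(fit)
        swaps = np.abs(maps["fat_fraction"] - ff) > 0.5
        assert swaps.sum() == 0

    def test_r2star_is_reciprocal_t2star(self, param_grid_fit):
        *_, fit = param_grid_fit
        maps = u.derive_maps(fit)
        np.testing.assert_allclose(
            maps["r2star"] * fit.t2star_s, 1.0, rtol=1e-9
        )

    def test_global_phase_offset_shifts_phi0_only(self, spectrum3t, param_grid_fit):
        f, ff, t2s, fit = param_grid_fit
        sl = (slice(0, 3), slice(0, 3), slice(0, 3))
        shape = (8, 8, 8)
        rng = np.random.default_rng(3)
        fmap = rng.uniform(-50, 50, shape)
        series = _synthetic_volume(
            spectrum3t, fmap, np.zeros(shape), np.full(shape, 0.02), phi0=0.2
        )
        dphi = 0.8
        shifted = u.MultiEchoSeries(
            data=series.data * np.exp(1j * dphi),
            echo_times_s=series.echo_times_s,
            geometry=series.geometry,
        )
        mask = np.ones(shape, bool)
        opts = u.FitOptions(search_range_hz=300.0)
        fit_a = u.fit_ideal_volume(series, spectrum3t, mask, opts)
        fit_b = u.fit_ideal_volume(shifted, spectrum3t, mask, opts)
        np.testing.assert_allclose(fit_b.f_b0_hz, fit_a.f_b0_hz, atol=1e-5)
        np.testing.assert_allclose(fit_b.t2star_s, fit_a.t2star_s, rtol=1e-5)
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (fit_b.phi0 - fit_a.phi0 - dphi))), 0.0, atol=1e-5
        )

    def test_zero_voxels_flagged_not_converged(self, spectrum3t):
        shape = (8, 8, 8)
        series = _synthetic_volume(
            spectrum3t, np.zeros(shape), np.zeros(shape), np.full(shape, 0.02)
        )
        series.data[:, 0, 0, 0] = 0.0
        fit = u.fit_ideal_volume(
            series, spectrum3t, np.ones(shape, bool), u.FitOptions(search_range_hz=100.0)
        )
        assert not fit.converged[0, 0, 0]
        assert fit.f_b0_hz[0, 0, 0] == 0.0
        assert fit.converged[1:].all()

    def test_empty_mask_rejected(self, spectrum3t):
        shape = (8, 8, 8)
        series = _synthetic_volume(
            spectrum3t, np.zeros(shape), np.zeros(shape), np.full(shape, 0.02)
        )
        with pytest.raises(ValueError, match="mask"):
            u.fit_ideal_volume(series, spectrum3t, np.zeros(shape, bool))
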