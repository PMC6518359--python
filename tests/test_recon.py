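import numpy as np
import pytest

from invpetdose import phantom, projection, recon


def make_noisy_annulus(seed=5):
    """Hot annulus with a cold core: a stress case for ramp filtering."""
    grid = phantom.GridSpec(nx=64, ny=64, nz=1, dx=1.0, dy=1.0, dz=1.0)
    x = grid.axis_coords("x")[:, None]
    y = grid.axis_coords("y")[None, :]
    r2 = x**2 + y**2
    ann = (((r2 <= 20.0**2) & (r2 >= 10.0**2)).astype(float) * 5.0)[:, :, None]
    amap = phantom.ActivityMap(ann, grid)
    geom = projection.ScanGeometry.for_grid(grid, 96)
    sino = projection.forward_project(amap, geom)
    noisy = projection.sample_counts(sino, 2e5, seed=seed)
    return grid, geom, r2, noisy


class TestApodizationWindows:
    def test_ramp_component_zero_at_dc(self):
        for name in recon.FBP_WINDOWS:
            w = apod = recon.apodization_window(name, 0.5, np.array([0.0]))
            assert apod[0] == 0.0

    def test_hanning_vanishes_at_cutoff(self):
        fc = 0.5 * 0.5
        w = recon.apodization_window("hanning", 0.5, np.array([fc]))
        assert w[0] == pytest.approx(0.0, abs=1e-12)

    def test_hamming_residual_at_cutoff(self):
        fc = 0.5 * 0.5
        w = recon.apodization_window("hamming", 0.5, np.array([fc]))
        assert w[0] == pytest.approx(0.08 * fc, rel=1e-9)

    def test_zero_beyond_cutoff_and_bounded(self):
        f = np.linspace(0, 0.5, 257)
        for name in recon.FBP_WINDOWS:
            w = recon.apodization_window(name, 0.5, f)
            assert np.all(w[f > 0.25] == 0.0)
            assert np.all((w >= 0) & (w <= np.abs(f) + 1e-12))

    def test_unknown_window_rejected(self):
        with pytest.raises(ValueError):
            recon.apodization_window("welch", 0.5, 64)


class TestFBP:
    def test_uniform_disc_mean_recovered(self, disc_setup):
        grid, amap, geom, sino = disc_setup
        img = recon.fbp2d(sino, grid, "ramp")[0]
        x = grid.axis_coords("x")[:, None]
        y = grid.axis_coords("y")[None, :]
        core = (x**2 + y**2) <= 10.0**2
        assert img[core].mean() == pytest.approx(5.0, rel=0.05)

    def test_zero_sinogram_gives_zero_image(self, disc_setup):
        grid, _, geom, sino = disc_setup
        zero = sino.copy_with(np.zeros_like(sino.data))
        assert np.all(recon.fbp2d(zero, grid) == 0)

    def test_linearity(self, disc_setup):
        grid, _, _, sino = disc_setup
        a = recon.fbp2d(sino, grid, "hanning")
        b = recon.fbp2d(sino.copy_with(3.0 * sino.data), grid, "hanning")
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-9, atol=1e-12)

    def test_cold_region_can_go_negative(self):
        grid, geom, r2, noisy = make_noisy_annulus()
        img = recon.fbp2d(noisy, grid, "ramp")[0]
        assert img[r2 <= 8.0**2].min() < 0


class TestOSEM:
    def test_output_nonnegative(self):
        grid, geom, _, noisy = make_noisy_annulus()
        img = recon.osem2d(noisy, grid, n_subsets=16, n_iterations=5)
        assert np.all(img >= 0)

    def test_mlem_fixed_point_on_noiseless_disc(self, disc_setup):
        grid, _, geom, sino = disc_setup
        rec = recon.osem2d(sino, grid, n_subsets=1, n_iterations=200)[0]
        proj = projection.get_projector(grid, geom)
        resid = proj.forward(rec) - sino.data[0]
        rms = np.sqrt((resid**2).mean())
        assert rms <= 0.01 * sino.data[sino.data > 0].mean()

    def test_total_activity_consistent_by_iteration_50(self, disc_setup):
        grid, amap, geom, sino = disc_setup
        rec = recon.osem2d(sino, grid, n_subsets=16, n_iterations=50)[0]
        assert rec.sum() == pytest.approx(amap.values.sum(), rel=0.01)

    def test_subsets_must_divide_angles(self, disc_setup):
        grid, _, _, sino = disc_setup
        with pytest.raises(ValueError):
            recon.osem2d(sino, grid, n_subsets=7, n_iterations=1)

    def test_attenuation_in_model_restores_quantification(self, disc_setup):
        grid, amap, geom, sino = disc_setup
        mu = phantom.MuMap((amap.values > 0) * 0.0096, grid)
        atten = projection.apply_attenuation(sino, mu)
        acf = recon.attenuation_correction_factors(mu, geom)
        biased = recon.osem2d(atten, grid, 16, 10)[0]
        corrected = recon.osem2d(atten, grid, 16, 10, acf=acf)[0]
        x = grid.axis_coords("x")[:, None]
        y = grid.axis_coords("y")[None, :]
        core = (x**2 + y**2) <= 10.0**2
        assert biased[core].mean() < 0.85 * 5.0
        assert corrected[core].mean() == pytest.approx(5.0, rel=0.05)


class TestMAPEM:
    def test_beta_zero_is_mlem(self, disc_setup):
        grid, _, _, sino = disc_setup
        mlem = recon.osem2d(sino, grid, n_subsets=1, n_iterations=10)
        mapem = recon.mapem2d(sino, grid, beta=0.0, n_iterations=10)
        np.testing.assert_allclose(mapem, mlem, atol=1e-10)

    @staticmethod
    def _roughness(img):
        return np.mean(
            (np.diff(img, axis=0) ** 2).sum() + (np.diff(img, axis=1) ** 2).sum()
        )

    def test_roughness_decreases_with_beta(self):
        grid, geom, _, noisy = make_noisy_annulus()
        low = recon.mapem2d(noisy, grid, beta=0.1, n_iterations=18)[0]
        high = recon.mapem2d(noisy, grid, beta=1.5, n_iterations=18)[0]
        assert self._roughness(high) <= self._roughness(low)

    def test_peak_value_nonincreasing_in_beta(self):
        grid, geom, r2, noisy = make_noisy_annulus()
        peaks = [
            recon.mapem2d(noisy, grid, beta=b, n_iterations=18)[0].max()
            for b in (0.1, 1.0, 1.5)
        ]
        assert peaks[0] >= peaks[1] >= peaks[2]


class TestGaussianPostfilter:
    def test_zero_fwhm_is_identity(self, disc_setup):
        grid, amap, _, _ = disc_setup
        out = recon.gaussian_postfilter(amap.values[:, :, 0], 0.0, 1.0)
        np.testing.assert_array_equal(out, amap.values[:, :, 0])

    def test_total_preserved(self, disc_setup):
        grid, amap, _, _ = disc_setup
        img = amap.values[:, :, 0]
        out = recon.gaussian_postfilter(img, 4.5, 1.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_impulse_response_fwhm(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        fwhm = 6.0
        out = recon.gaussian_postfilter(img, fwhm, 1.0)
        profile = out[32]
        half = profile.max() / 2.0
        above = np.where(profile >= half)[0]
        # linear interpolation of the half-max crossings
        lo = above[0] - (profile[above[0]] - half) / (
            profile[above[0]] - profile[above[0] - 1]
        )
        hi = above[-1] + (profile[above[-1]] - half) / (
            profile[above[-1]] - profile[above[-1] + 1]
        )
        assert hi - lo == pytest.approx(fwhm, abs=0.5)


class TestCorrections:
    def test_acf_identity_for_zero_mu(self, disc_setup):
        grid, _, geom, _ = disc_setup
        mu = phantom.MuMap(np.zeros(grid.shape), grid)
        acf = recon.attenuation_correction_factors(mu, geom)
        np.testing.assert_array_equal(acf.data, 1.0)

    def test_acf_round_trip_and_bound(self, disc_setup):
        grid, amap, geom, sino = disc_setup
        mu = phantom.MuMap((amap.values > 0) * 0.0096, grid)
        atten = projection.apply_attenuation(sino, mu)
        acf = recon.attenuation_correction_factors(mu, geom)
        np.testing.assert_allclose(atten.data * acf.data, sino.data, rtol=1e-10)
        assert np.all(acf.data >= 1.0)

    def test_scatter_correct_recovers_trues(self, disc_setup):
        _, _, _, sino = disc_setup
        mixed, est = projection.add_scatter(sino, 0.25)
        out = recon.scatter_correct(mixed, est)
        np.testing.assert_allclose(out.data, sino.data, atol=1e-9)

    def test_scatter_correct_zero_estimate_identity_and_clamp(self, disc_setup):
        _, _, _, sino = disc_setup
        out = recon.scatter_correct(sino, np.zeros_like(sino.data))
        np.testing.assert_array_equal(out.data, sino.data)
        over = recon.scatter_correct(sino, sino.data + 1.0, clamp=True)
        assert np.all(over.data >= 0)
        with pytest.raises(ValueError):
            recon.scatter_correct(sino, np.zeros((2, 2)))

    def test_calibration_scaling(self, disc_setup):
        _, amap, _, _ = disc_setup
        img = amap.values
        np.testing.assert_array_equal(recon.calibrate_to_concentration(img, 1.0), img)
        np.testing.assert_allclose(
            recon.calibrate_to_concentration(
                recon.calibrate_to_concentration(img, 2.5), 1 / 2.5
            ),
            img,
        )
        with pytest.raises(ValueError):
            recon.calibrate_to_concentration(img, 0.0)
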