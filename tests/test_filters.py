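"""Parametric filter families, synthesis, thresholding, oscillator."""

import numpy as np
import pytest
from scipy.integrate import quad

from vegpattern import Grid, ScalarField
from vegpattern import filters, spectra
from vegpattern.filters import (
    BandPassParams,
    LowPassParams,
    OscillatorParams,
    bandpass_density,
    bandpass_params_for,
    bandpass_regularity,
    cover_fraction,
    lowpass_density,
    oscillator_density,
    oscillator_generate,
    oscillator_params_for,
    oscillator_regularity,
    synthesize,
    threshold,
)


class TestLowPass:
    def test_corner_is_the_half_power_point(self):
        p = LowPassParams(k0=0.4, p=3.0)
        assert lowpass_density(0.4, p) == pytest.approx(0.5 * lowpass_density(0.0, p))

    def test_high_order_limit_is_an_ideal_filter(self):
        p = LowPassParams(k0=0.4, p=400.0)
        assert lowpass_density(0.38, p) > 0.99
        assert lowpass_density(0.42, p) < 0.01

    def test_non_integrable_order_rejected(self):
        with pytest.raises(ValueError):
            LowPassParams(k0=0.4, p=0.5)


class TestBandPass:
    def test_vanishes_at_the_origin(self):
        p = BandPassParams(kc=0.2, alpha=2.0)
        assert bandpass_density(0.0, p) == 0.0

    def test_argmax_at_kc_by_construction(self):
        p = BandPassParams(kc=0.2, alpha=3.0)
        k = np.linspace(1e-4, 1.0, 20001)
        assert k[np.argmax(bandpass_density(k, p))] == pytest.approx(0.2, abs=1e-3)

    def test_calibration_roundtrip_within_1_percent(self):
        for lam, reg in [(44.0, 0.5), (24.0, 1.5), (100.0, 5.0)]:
            p = bandpass_params_for(lam, reg)
            assert 2 * np.pi / p.kc == pytest.approx(lam, rel=1e-10)
            assert bandpass_regularity(p.alpha) == pytest.approx(reg, rel=0.01)

    def test_closed_form_regularity_matches_quadrature(self):
        # independent oracle: numerical normalization + peak value
        alpha, kc = 2.5, 0.2
        p = BandPassParams(kc=kc, alpha=alpha)
        total, _ = quad(lambda k: bandpass_density(k, p), 0, np.inf, limit=200)
        src = bandpass_density(kc, p) / total
        reg_num = 2 * np.pi * src / (2 * np.pi / kc)
        assert bandpass_regularity(alpha) == pytest.approx(reg_num, rel=1e-8)

    def test_unattainable_regularity_reports_range(self):
        with pytest.raises(ValueError, match="attainable"):
            bandpass_params_for(44.0, 0.05)


class TestOscillatorDensity:
    def test_matches_fourier_transform_of_damped_cosine(self):
        # closed-form oracle: S(k) = FT of cos(kc x) exp(-g|x|) via quadrature
        kc, g = 0.25, 0.03
        p = OscillatorParams(kc=kc, gamma_x=g)
        for k in (0.0, 0.1, 0.25, 0.4):
            num, _ = quad(lambda x: 2 * np.cos(k * x) * np.cos(kc * x)
                          * np.exp(-g * x), 0, np.inf, limit=500)
            assert oscillator_density(k, p, "x") == pytest.approx(num, rel=1e-8)

    def test_positive_at_origin(self):
        p = OscillatorParams(kc=0.25, gamma_x=0.05)
        assert oscillator_density(0.0, p, "x") > 0

    def test_parallel_axis_peaks_at_origin(self):
        p = OscillatorParams(gamma_y=0.1)
        k = np.linspace(0, 1, 100)
        s = oscillator_density(k, p, "y")
        assert np.argmax(s) == 0

    def test_regularity_calibration_roundtrip(self):
        p = oscillator_params_for(40.0, 1.5, 3.0)
        rx, ry = oscillator_regularity(p)
        assert rx == pytest.approx(1.5, rel=1e-9)
        assert ry == pytest.approx(3.0, rel=1e-9)


class TestSynthesize:
    def test_identity_transfer_returns_the_input(self):
        grid = Grid(64, 64, 1.0)
        rng = np.random.default_rng(0)
        noise = ScalarField(grid, rng.standard_normal(grid.shape))
        t = spectra.TransferFunction2D(grid, np.ones(grid.shape, complex))
        out = synthesize(t, noise=noise)
        centred = noise.values - noise.values.mean()
        np.testing.assert_allclose(out.values, centred, atol=1e-12)

    def test_seed_determinism(self):
        grid = Grid(64, 64, 1.0)
        p = bandpass_params_for(16.0, 1.0)
        f1 = synthesize(lambda k: bandpass_density(k, p), grid=grid, seed=3)
        f2 = synthesize(lambda k: bandpass_density(k, p), grid=grid, seed=3)
        assert np.array_equal(f1.values, f2.values)

    def test_output_density_matches_request_at_scale(self):
        # synthesis-density identity: radial L1 error < 10% at 1024^2
        # (the cell-wise 2D error is dominated by the chi-squared scatter
        # of the finite tile count; the angular average removes it)
        grid = Grid(1024, 1024, 1.0)
        params = bandpass_params_for(44.0, 0.5)
        pat = synthesize(lambda k: bandpass_density(k, params), grid=grid,
                         seed=4)
        rd = spectra.radial_density(spectra.estimate_density(pat, tile_count=4))
        truth = bandpass_density(rd.kr, params)
        truth[0] = 0.0
        truth = truth / (truth.sum() * rd.dk)
        l1 = np.abs(rd.values - truth).sum() / truth.sum()
        assert l1 < 0.10

    def test_fit_and_resynthesis_closes_the_loop(self):
        # fitted parameters on a synthesized pattern recover the generator
        grid = Grid(1024, 1024, 1.0)
        true = bandpass_params_for(44.0, 1.5)
        pat = synthesize(lambda k: bandpass_density(k, true), grid=grid, seed=5)
        rd = spectra.radial_density(spectra.periodogram(pat))
        fitted, _ = spectra.hellinger_fit(rd, "bandpass")
        assert fitted.kc == pytest.approx(true.kc, rel=0.05)
        assert bandpass_regularity(fitted.alpha) == pytest.approx(
            bandpass_regularity(true.alpha), rel=0.05)


class TestThreshold:
    def test_full_cover_gives_constant_mean(self):
        grid = Grid(16, 16, 1.0)
        rng = np.random.default_rng(1)
        pat = ScalarField(grid, rng.standard_normal(grid.shape))
        out = threshold(pat, 1.0, mean_biomass=3.5)
        np.testing.assert_allclose(out.values, 3.5)

    @pytest.mark.parametrize("cover", [0.2, 0.5, 0.8])
    def test_cover_and_mean_exact(self, cover):
        grid = Grid(64, 64, 1.0)
        rng = np.random.default_rng(2)
        pat = ScalarField(grid, rng.standard_normal(grid.shape))
        out = threshold(pat, cover, mean_biomass=2.0)
        frac = (out.values > 0).mean()
        assert abs(frac - cover) <= 1.0 / grid.n_cells
        assert out.values.mean() == pytest.approx(2.0, rel=1e-12)

    def test_double_threshold_gives_rings(self):
        # excluding the very top of the distribution empties patch cores
        grid = Grid(256, 256, 1.0)
        pat = synthesize(lambda k: bandpass_density(
            k, bandpass_params_for(32.0, 2.0)), grid=grid, seed=6)
        ring = threshold(pat, 0.3, exclude_top=0.1)
        solid = threshold(pat, 0.3)
        core = pat.values >= np.quantile(pat.values, 0.95)
        assert (ring.values[core] == 0).all()
        assert (solid.values[core] > 0).all()
        assert (ring.values > 0).mean() == pytest.approx(0.3, abs=1e-3)

    def test_zero_cover_rejected(self):
        with pytest.raises(ValueError):
            threshold(np.zeros((4, 4)), 0.0)


class TestOscillatorGenerate:
    def test_vanishing_phase_noise_gives_periodic_stripes(self):
        grid = Grid(256, 64, 1.0)
        p = OscillatorParams(kc=2 * np.pi / 32, gamma_x=1e-15, gamma_y=1e-15)
        pat = oscillator_generate(p, grid, seed=1, cover=0.5)
        assert np.allclose(pat.values, pat.values[0])  # stripes along y
        assert set(np.unique(pat.values)) == {0.0, pat.values.max()}

    def test_measured_densities_match_the_oscillator_shape(self):
        grid = Grid(512, 512, 1.0)
        p = oscillator_params_for(40.0, 1.5, 3.0)
        pat = oscillator_generate(p, grid, seed=2, cover=0.5)
        spec = spectra.periodogram(pat)
        sx = spectra.directional_density(spec, "x")
        sy = spectra.directional_density(spec, "y")
        m = spectra.pattern_metrics((sx, sy))
        assert m.wavelength == pytest.approx(40.0, rel=0.06)
        assert sx.values[0] > 0  # heavy tails: positive density at the origin
        assert np.argmax(sy.values) <= 1

    def test_anisotropy_controls_stripe_spacing_regularity(self):
        # larger perpendicular regularity -> more regular spacing
        grid = Grid(512, 512, 1.0)
        ragged = oscillator_generate(oscillator_params_for(40.0, 3.0, 0.6),
                                     grid, seed=3)
        smooth = oscillator_generate(oscillator_params_for(40.0, 0.6, 3.0),
                                     grid, seed=3)
        def reg_x(pat):
            spec = spectra.periodogram(pat)
            m = spectra.pattern_metrics(
                (spectra.directional_density(spec, "x"),
                 spectra.directional_density(spec, "y")))
            return m.regularity[0]
        assert reg_x(ragged) > reg_x(smooth)

    def test_phase_surface_increments_are_calibrated(self):
        from vegpattern.filters import _brownian_phase_spectrum

        grid = Grid(512, 512, 1.0)
        gx, gy = 0.05, 0.1
        spec = _brownian_phase_spectrum(grid, gx, gy)
        rng = np.random.default_rng(4)
        phi = np.fft.ifft2(np.sqrt(spec) * np.fft.fft2(
            rng.standard_normal(grid.shape))).real
        dx4 = ((phi - np.roll(phi, 4, axis=1)) ** 2).mean() / 4
        dy4 = ((phi - np.roll(phi, 4, axis=0)) ** 2).mean() / 4
        assert dx4 == pytest.approx(2 * gx, rel=0.25)
        assert dy4 == pytest.approx(2 * gy, rel=0.25)


class TestCoverFraction:
    def test_thresholded_pattern_cover_recovered_exactly(self):
        grid = Grid(128, 128, 1.0)
        pat = synthesize(lambda k: bandpass_density(
            k, bandpass_params_for(24.0, 1.5)), grid=grid, seed=7)
        th = threshold(pat, 0.3)
        assert cover_fraction(th) == pytest.approx(0.3, abs=1e-3)

    def test_stable_under_small_additive_noise(self):
        grid = Grid(128, 128, 1.0)
        pat = synthesize(lambda k: bandpass_density(
            k, bandpass_params_for(24.0, 1.5)), grid=grid, seed=8)
        th = threshold(pat, 0.4, mean_biomass=10.0)
        rng = np.random.default_rng(9)
        noisy = ScalarField(grid, th.values + rng.normal(0, 0.5, grid.shape))
        assert cover_fraction(noisy) == pytest.approx(0.4, abs=0.02)

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError):
            cover_fraction(np.ones((8, 8)))
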