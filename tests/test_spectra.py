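"""Spectral estimation, pattern metrics, coherence, periodicity, phase."""

import numpy as np
import pytest

from vegpattern import Grid, ScalarField
from vegpattern import filters, spectra
from vegpattern.spectra import (
    RadialDensity,
    autocorrelation,
    coherence,
    cross_density,
    directional_density,
    estimate_density,
    hellinger_fit,
    local_phase,
    pattern_metrics,
    periodicity_test,
    periodogram,
    radial_density,
    transfer_estimate,
)


def _cosine_field(grid, wavelength, axis="x"):
    x = grid.x()[None, :] if axis == "x" else grid.y()[:, None]
    return ScalarField(grid, np.broadcast_to(
        np.cos(2 * np.pi * x / wavelength), grid.shape).copy())


def _bandpass_pattern(grid, wavelength=24.0, regularity=1.5, seed=0):
    params = filters.bandpass_params_for(wavelength, regularity)
    return filters.synthesize(
        lambda k: filters.bandpass_density(k, params), grid=grid, seed=seed)


class TestPeriodogram:
    def test_cosine_gives_symmetric_peak_pair(self):
        grid = Grid(64, 64, 1.0)
        p = periodogram(_cosine_field(grid, 16.0)).values
        peaks = np.argwhere(p > 0.5 * p.max())
        assert len(peaks) == 2
        ks = sorted(grid.kx()[c] for _, c in peaks)
        assert ks[1] == pytest.approx(2 * np.pi / 16.0)
        assert ks[0] == pytest.approx(-2 * np.pi / 16.0)

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((64, 48))
        p = periodogram(f)
        assert abs(p.values.sum() - f.var()) < 1e-10

    def test_white_noise_is_flat_on_average(self):
        rng = np.random.default_rng(1)
        acc = None
        for _ in range(50):
            p = periodogram(rng.standard_normal((64, 64)))
            v = radial_density(p).values
            acc = v if acc is None else acc + v
        acc /= 50
        interior = acc[2:30]
        assert interior.std() / interior.mean() < 0.1


class TestDensityEstimation:
    def test_single_tile_reduces_to_periodogram(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((64, 64))
        d1 = estimate_density(f, tile_count=1).values
        p = periodogram(f)
        pn = p.normalize().values
        np.testing.assert_allclose(d1, pn, rtol=1e-12)

    def test_matches_generating_filter_density(self):
        grid = Grid(512, 512, 1.0)
        params = filters.bandpass_params_for(24.0, 1.5)
        pat = _bandpass_pattern(grid, 24.0, 1.5, seed=3)
        est = estimate_density(pat, tile_count=4)
        truth = filters.bandpass_density(est.grid.k_radial(), params)
        truth[0, 0] = 0.0
        dkx, dky = est.dk
        truth = truth / (truth.sum() * dkx * dky)
        l1 = np.abs(est.values - truth).sum() / truth.sum()
        assert l1 < 0.25  # tile estimate with 16 tiles, sampling error

    def test_quadrupling_tiles_quarters_estimator_variance(self):
        # estimator variance scales inversely with the tile count;
        # compare density values at the same physical wavenumber
        grid = Grid(128, 128, 1.0)
        per_tiles = {2: [], 4: []}
        for seed in range(40):
            pat = filters.synthesize(
                lambda k: filters.lowpass_density(k, filters.LowPassParams(0.5)),
                grid=grid, seed=seed)
            per_tiles[2].append(estimate_density(pat, 2).values[2, 2])
            per_tiles[4].append(estimate_density(pat, 4).values[1, 1])
        ratio = np.var(per_tiles[2]) / np.var(per_tiles[4])
        assert 2.0 < ratio < 8.0  # 4x the tiles -> ~1/4 the variance

    def test_too_small_tiles_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.zeros((32, 32)), tile_count=8)


class TestReductions:
    def test_isotropic_ring_gives_single_lobe(self):
        grid = Grid(128, 128, 1.0)
        kr = grid.k_radial()
        ring = np.exp(-0.5 * ((kr - 0.5) / 0.05) ** 2)
        rd = radial_density(spectra.Spectrum2D(grid, ring))
        peak_k = rd.kr[np.argmax(rd.values)]
        assert peak_k == pytest.approx(0.5, abs=rd.dk)

    def test_rotation_leaves_radial_density_unchanged(self):
        grid = Grid(128, 128, 1.0)
        pat = _bandpass_pattern(grid, seed=4)
        r1 = radial_density(periodogram(pat))
        rot = ScalarField(grid, np.rot90(pat.values).copy())
        r2 = radial_density(periodogram(rot))
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-8, atol=1e-12)

    def test_stripes_put_lobes_on_the_perpendicular_axis(self):
        grid = Grid(128, 128, 1.0)
        spec = periodogram(_cosine_field(grid, 16.0, axis="x"))
        sx = directional_density(spec, "x")
        sy = directional_density(spec, "y")
        assert sx.k[np.argmax(sx.values)] == pytest.approx(2 * np.pi / 16.0)
        assert np.argmax(sy.values) == 0

    def test_reduction_conserves_band_limited_volume(self):
        grid = Grid(128, 128, 1.0)
        pat = _bandpass_pattern(grid, seed=5)
        spec = periodogram(pat).normalize()
        rd = radial_density(spec)
        assert rd.volume == pytest.approx(1.0, rel=0.01)


class TestPatternMetrics:
    def test_white_noise_has_no_finite_wavelength(self):
        rng = np.random.default_rng(3)
        m = pattern_metrics(radial_density(periodogram(
            rng.standard_normal((256, 256)))))
        assert m.regularity < 0.3

    def test_periodic_pattern_reaches_the_domain_bound(self):
        # regularity of a pure cosine approaches the maximum L / lambda
        grid = Grid(512, 512, 1.0)
        m = pattern_metrics(radial_density(periodogram(
            _cosine_field(grid, 32.0))), smooth=1)
        assert m.wavelength == pytest.approx(32.0, rel=1e-6)
        assert m.regularity == pytest.approx(512 / 32.0, rel=0.05)

    def test_bandpass_parameters_recovered_within_5_percent(self):
        grid = Grid(512, 512, 1.0)
        lams, regs = [], []
        for seed in range(5):
            pat = _bandpass_pattern(grid, 44.0, 1.5, seed=seed)
            m = pattern_metrics(radial_density(periodogram(pat)))
            lams.append(m.wavelength)
            regs.append(m.regularity)
        assert np.mean(lams) == pytest.approx(44.0, rel=0.05)
        assert np.mean(regs) == pytest.approx(1.5, rel=0.05)

    def test_regularity_is_scale_invariant(self):
        grid1 = Grid(256, 256, 1.0)
        pat = _bandpass_pattern(grid1, seed=6)
        m1 = pattern_metrics(radial_density(periodogram(pat)))
        grid2 = Grid(256, 256, 3.7)
        pat2 = ScalarField(grid2, pat.values)
        m2 = pattern_metrics(radial_density(periodogram(pat2)))
        assert m2.regularity == pytest.approx(m1.regularity, rel=1e-9)
        assert m2.wavelength == pytest.approx(3.7 * m1.wavelength, rel=1e-9)

    def test_low_pass_density_gets_cutoff_not_wavelength(self):
        grid = Grid(256, 256, 1.0)
        lp = filters.LowPassParams(k0=0.3, p=2.0)
        pat = filters.synthesize(lambda k: filters.lowpass_density(k, lp),
                                 grid=grid, seed=7)
        m = pattern_metrics(radial_density(periodogram(pat)))
        assert m.regularity == 0.0
        # half-power point of the family is k0
        assert m.cutoff == pytest.approx(2 * np.pi / 0.3, rel=0.25)


class TestAutocorrelation:
    def test_white_noise_decorrelates_immediately(self):
        rng = np.random.default_rng(4)
        r = autocorrelation(rng.standard_normal((128, 128)))
        assert r[0, 0] == pytest.approx(1.0)
        assert np.abs(r[0, 1:]).max() < 0.1

    def test_bandpass_first_maximum_near_wavelength(self):
        grid = Grid(512, 512, 1.0)
        pat = _bandpass_pattern(grid, 24.0, 2.0, seed=8)
        r = autocorrelation(pat)
        profile = r[0, :48]
        # first local maximum after the first minimum of the damped wave
        imin = int(np.argmin(profile))
        lag = imin + int(np.argmax(profile[imin:]))
        assert lag == pytest.approx(24.0, abs=5.0)

    def test_wiener_khinchin_roundtrip(self):
        rng = np.random.default_rng(5)
        p = periodogram(rng.standard_normal((64, 64))).values
        r = np.fft.ifft2(p).real
        back = np.fft.fft2(r).real
        np.testing.assert_allclose(back, p, atol=1e-10)


class TestTransferAndCoherence:
    def test_known_filter_transfer_recovered(self):
        grid = Grid(256, 256, 1.0)
        rng = np.random.default_rng(6)
        noise = ScalarField(grid, rng.standard_normal(grid.shape))
        params = filters.bandpass_params_for(20.0, 1.0)
        pat = filters.synthesize(
            lambda k: filters.bandpass_density(k, params), noise=noise)
        tf = transfer_estimate(noise, pat, tile_count=4)
        truth = np.sqrt(filters.bandpass_density(tf.grid.k_radial(), params))
        est = np.abs(tf.values)
        scale = (est * truth).sum() / (truth * truth).sum()
        strong = truth > 0.1 * truth.max()
        rel = np.abs(est - scale * truth)[strong].mean() / (scale * truth.max())
        assert rel < 0.1

    def test_independent_fields_give_vanishing_transfer(self):
        grid = Grid(256, 256, 1.0)
        rng = np.random.default_rng(7)
        e = ScalarField(grid, rng.standard_normal(grid.shape))
        b = ScalarField(grid, rng.standard_normal(grid.shape))
        tf = transfer_estimate(e, b, tile_count=8)
        assert np.abs(tf.values).mean() < 0.3  # ~1/sqrt(64 tiles) noise floor

    def test_coherence_bounded_and_one_for_linear_pairs(self):
        grid = Grid(256, 256, 1.0)
        rng = np.random.default_rng(8)
        noise = ScalarField(grid, rng.standard_normal(grid.shape))
        pat = filters.synthesize(
            lambda k: filters.lowpass_density(k, filters.LowPassParams(0.5)),
            noise=noise)
        c = coherence(noise, pat, tile_count=4)
        assert c.values.min() >= 0.0 and c.values.max() <= 1.0
        assert c.weighted_mean > 0.95
        assert np.median(c.values[c.values > 0]) > 0.9

    def test_independent_fields_are_incoherent(self):
        grid = Grid(256, 256, 1.0)
        rng = np.random.default_rng(9)
        e = ScalarField(grid, rng.standard_normal(grid.shape))
        b = ScalarField(grid, rng.standard_normal(grid.shape))
        assert coherence(e, b, tile_count=4).weighted_mean < 0.2

    def test_thresholding_reduces_coherence(self):
        grid = Grid(256, 256, 1.0)
        rng = np.random.default_rng(10)
        noise = ScalarField(grid, rng.standard_normal(grid.shape))
        pat = _bandpass_pattern(grid, 24.0, 1.5, seed=11)
        pat = filters.synthesize(
            lambda k: filters.bandpass_density(
                k, filters.bandpass_params_for(24.0, 1.5)), noise=noise)
        thr = filters.threshold(pat, 0.3)
        c_lin = coherence(noise, pat, tile_count=4).weighted_mean
        c_thr = coherence(noise, thr, tile_count=4).weighted_mean
        assert c_thr < c_lin

    def test_too_few_tiles_rejected(self):
        with pytest.raises(ValueError):
            coherence(np.zeros((64, 64)), np.zeros((64, 64)), tile_count=(1, 2))


class TestPeriodicityTest:
    def test_pure_cosine_is_maximally_significant(self):
        grid = Grid(128, 128, 1.0)
        f = _cosine_field(grid, 16.0)
        assert periodicity_test(f, 99, seed=1) == pytest.approx(0.01)

    def test_type_one_error_at_nominal_level(self):
        # parametric-bootstrap calibration on the test's own null
        grid = Grid(64, 64, 1.0)
        params = filters.bandpass_params_for(12.0, 1.0)
        pvals = []
        for seed in range(200):
            pat = filters.synthesize(
                lambda k: filters.bandpass_density(k, params),
                grid=grid, seed=1000 + seed)
            pvals.append(periodicity_test(pat, 99, seed=2000 + seed))
        rate = np.mean(np.asarray(pvals) <= 0.05)
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= 3 * se

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            periodicity_test(np.zeros((16, 16)), n_surrogates=10)


class TestLocalPhase:
    def test_pure_cosine_profile(self):
        x = np.arange(512) + 0.5
        k = 2 * np.pi / 32.0
        prof = local_phase(np.cos(k * x), dx=1.0)
        inner = slice(50, -50)
        assert prof.amplitude[inner].std() < 0.01
        np.testing.assert_allclose(prof.wavelength[inner], 32.0, rtol=0.01)
        assert np.abs(prof.dphi[inner] - prof.dphi[256]).max() < 0.05

    def test_phase_step_is_detected_and_persists(self):
        x = np.arange(1024) + 0.5
        k = 2 * np.pi / 32.0
        step = 0.5 * (x > 512)
        prof = local_phase(np.cos(k * x + step), dx=1.0, kc=k)
        before = prof.dphi[200:400].mean()
        after = prof.dphi[650:850].mean()
        assert after - before == pytest.approx(0.5, abs=0.05)


class TestHellingerFit:
    @pytest.mark.parametrize("family,params", [
        ("lowpass", (0.3, 2.0)),
        ("bandpass", (0.25, 3.0)),
        ("oscillator-x", (0.2, 0.04)),
    ])
    def test_self_consistency_within_2_percent(self, family, params):
        k = np.arange(0, 128) * (np.pi / 128)
        model = filters.density_family(family)
        s = model(k, *params)
        s = s / (s.sum() * (k[1] - k[0]))
        fitted, r2 = hellinger_fit(RadialDensity(k, s, k[1] - k[0]), family)
        vals = [getattr(fitted, f) for f in
                {"lowpass": ("k0", "p"), "bandpass": ("kc", "alpha"),
                 "oscillator-x": ("kc", "gamma_x")}[family]]
        np.testing.assert_allclose(vals, params, rtol=0.02)
        assert r2 > 0.99

    def test_sampled_bandpass_recovery(self):
        grid = Grid(512, 512, 1.0)
        true = filters.bandpass_params_for(44.0, 1.5)
        pat = _bandpass_pattern(grid, 44.0, 1.5, seed=12)
        fitted, r2 = hellinger_fit(radial_density(periodogram(pat)), "bandpass")
        assert fitted.kc == pytest.approx(true.kc, rel=0.05)
        assert fitted.alpha == pytest.approx(true.alpha, rel=0.15)
        assert r2 > 0.98
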