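import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmfseg.io_formats import VolumeImage
from cmfseg.phase_denoise import (
    SQRT_2LN2, RAYLEIGH_MEAN, RAYLEIGH_STD,
    build_log_gabor_bank, wavelet_responses, estimate_noise_model,
    shrink_responses, reconstruct, reconstruct_frame_normalized,
    denoise_volume, RayleighNoiseModel,
)
from cmfseg.phantom import rician_noise
from cmfseg.metrics import psnr


@pytest.fixture(scope="module")
def bank128():
    return build_log_gabor_bank((128, 128))


class TestBankConstruction:
    def test_zero_dc_gain(self, bank128):
        assert np.all(bank128.filters[:, :, 0, 0] == 0)

    def test_cardinality_2x15(self):
        bank = build_log_gabor_bank((64, 64), n_scales=2, n_orientations=15)
        assert bank.filters.shape[:2] == (2, 15)

    def test_unit_peak_transfer(self):
        # all scales resolvable on this grid
        bank = build_log_gabor_bank((128, 128), n_scales=4)
        np.testing.assert_allclose(bank.filters.max(axis=(2, 3)), 1.0)

    def test_rejects_oversized_min_wavelength(self):
        with pytest.raises(ValueError):
            build_log_gabor_bank((16, 16), min_wavelength=32)

    def test_rejects_tiny_shape(self):
        with pytest.raises(ValueError):
            build_log_gabor_bank((4, 4))


class TestWaveletResponses:
    def test_constant_slice_zero_response(self, bank128):
        resp = wavelet_responses(np.full((128, 128), 200.0), bank128)
        assert resp.amplitude().max() <= 1e-9 * 255

    def test_matched_cosine_dominates(self, bank128):
        # cosine at scale-1 center frequency, orientation 0 (x-axis waves)
        wavelength = bank128.min_wavelength * bank128.scale_multiplier
        xx = np.arange(128)[None, :] * np.ones((128, 1))
        img = np.cos(2 * np.pi * xx / wavelength)
        resp = wavelet_responses(img, bank128)
        totals = resp.amplitude().sum(axis=(2, 3))
        assert totals[1, 0] == totals.max()
        assert totals[1, 0] > 2 * np.delete(totals.ravel(),
                                            1 * bank128.n_orientations).max()

    def test_polar_identity(self, bank128, band_limited_slice):
        resp = wavelet_responses(band_limited_slice, bank128)
        a, phi = resp.amplitude(), resp.phase()
        np.testing.assert_allclose(a * np.cos(phi), resp.responses.real,
                                   atol=1e-10)
        np.testing.assert_allclose(a * np.sin(phi), resp.responses.imag,
                                   atol=1e-10)

    def test_shape_mismatch(self, bank128):
        with pytest.raises(ValueError):
            wavelet_responses(np.zeros((64, 64)), bank128)


class TestNoiseModel:
    def test_closed_form_moments(self):
        m = RayleighNoiseModel(sigma=np.array([[1.0]]), c=1.0,
                               tau=np.array([[0.0]]))
        assert m.mu_R[0, 0] == pytest.approx(np.sqrt(np.pi / 2), abs=1e-12)
        assert m.var_R[0, 0] == pytest.approx((4 - np.pi) / 2, abs=1e-12)
        assert m.median_M[0, 0] == pytest.approx(np.sqrt(2 * np.log(2)),
                                                 abs=1e-12)

    def test_median_inversion(self):
        # observed median amplitude 1.1774 -> sigma 1.0000
        assert 1.1774 / SQRT_2LN2 == pytest.approx(1.0, abs=1e-4)

    def test_threshold_formula(self):
        # sigma=1, c=1: tau = sqrt(pi/2) + sqrt((4-pi)/2) ~= 1.9084
        tau = RAYLEIGH_MEAN + RAYLEIGH_STD
        assert tau == pytest.approx(1.2533 + 0.6551, abs=1e-4)

    def test_monte_carlo_sigma_recovery(self):
        gen = np.random.default_rng(2024)
        samples = gen.rayleigh(2.0, 10 ** 6)
        sigma_hat = np.median(samples) / SQRT_2LN2
        assert 1.99 <= sigma_hat <= 2.01

    def test_estimator_consistency_improves_with_n(self):
        gen = np.random.default_rng(7)
        errs = []
        for n in (10 ** 4, 10 ** 6):
            s = gen.rayleigh(1.0, n)
            errs.append(abs(np.median(s) / SQRT_2LN2 - 1.0))
        assert errs[1] < errs[0]

    def test_estimate_from_responses_scales_with_noise(self, bank128):
        gen = np.random.default_rng(3)
        img = gen.normal(0, 5.0, (128, 128))
        model = estimate_noise_model(wavelet_responses(img, bank128))
        np.testing.assert_allclose(model.tau,
                                   model.sigma * (RAYLEIGH_MEAN + RAYLEIGH_STD))
        assert not model.degenerate
        # doubling the noise doubles every band sigma
        model2 = estimate_noise_model(wavelet_responses(2 * img, bank128))
        np.testing.assert_allclose(model2.sigma, 2 * model.sigma, rtol=1e-10)

    def test_all_zero_amplitudes_flagged(self, bank128):
        model = estimate_noise_model(wavelet_responses(np.zeros((128, 128)),
                                                       bank128))
        assert model.degenerate
        np.testing.assert_allclose(model.tau, 0.0, atol=1e-12)


class TestShrinkage:
    def test_soft_shrink_values_and_phase(self, bank128, band_limited_slice):
        resp = wavelet_responses(band_limited_slice, bank128)
        tau = np.full((bank128.n_scales, bank128.n_orientations), 2.0)
        model = RayleighNoiseModel(sigma=tau / (RAYLEIGH_MEAN + RAYLEIGH_STD),
                                   c=1.0, tau=tau)
        out = shrink_responses(resp, model)
        a, a2 = resp.amplitude(), out.amplitude()
        np.testing.assert_allclose(a2, np.maximum(a - 2.0, 0.0), atol=1e-12)
        kept = a2 > 0
        np.testing.assert_allclose(out.phase()[kept], resp.phase()[kept],
                                   atol=1e-12)

    def test_zero_threshold_identity(self, bank128, band_limited_slice):
        resp = wavelet_responses(band_limited_slice, bank128)
        model = RayleighNoiseModel(
            sigma=np.zeros((bank128.n_scales, bank128.n_orientations)),
            c=1.0, tau=np.zeros((bank128.n_scales, bank128.n_orientations)))
        out = shrink_responses(resp, model)
        np.testing.assert_allclose(out.responses, resp.responses, atol=1e-12)

    def test_negative_threshold_rejected(self, bank128, band_limited_slice):
        resp = wavelet_responses(band_limited_slice, bank128)
        model = RayleighNoiseModel(
            sigma=np.zeros((bank128.n_scales, bank128.n_orientations)), c=1.0,
            tau=np.full((bank128.n_scales, bank128.n_orientations), -1.0))
        with pytest.raises(ValueError):
            shrink_responses(resp, model)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(tau=st.floats(0.0, 50.0))
    def test_contraction_property(self, bank128, tau):
        """A' <= A everywhere for every tau >= 0 (hypothesis-driven)."""
        gen = np.random.default_rng(11)
        resp = wavelet_responses(gen.normal(0, 10, (128, 128)), bank128)
        taus = np.full((bank128.n_scales, bank128.n_orientations), tau)
        model = RayleighNoiseModel(sigma=taus, c=1.0, tau=taus)
        out = shrink_responses(resp, model)
        assert np.all(out.amplitude() <= resp.amplitude() + 1e-12)


class TestReconstruction:
    def test_zero_responses_zero_image(self, bank128):
        resp = wavelet_responses(np.zeros((128, 128)), bank128)
        assert np.allclose(reconstruct(resp), 0.0)

    def test_linearity(self, bank128, band_limited_slice):
        resp = wavelet_responses(band_limited_slice, bank128)
        r1 = reconstruct(resp)
        resp.responses *= 3.0
        np.testing.assert_allclose(reconstruct(resp), 3.0 * r1,
                                   atol=1e-12 * np.abs(r1).max())

    def test_band_limited_roundtrip(self, bank128, band_limited_slice):
        """tau=0 decompose/reconstruct keeps a covered-band image to <=5% RMS."""
        resp = wavelet_responses(band_limited_slice, bank128)
        rec = reconstruct(resp)
        rel = (np.sqrt(np.mean((rec - band_limited_slice) ** 2)) /
               np.sqrt(np.mean(band_limited_slice ** 2)))
        assert rel <= 0.05

    def test_frame_normalized_is_tighter(self, bank128, band_limited_slice):
        resp = wavelet_responses(band_limited_slice, bank128)
        rec = reconstruct_frame_normalized(resp, bank128)
        rel = (np.sqrt(np.mean((rec - band_limited_slice) ** 2)) /
               np.sqrt(np.mean(band_limited_slice ** 2)))
        assert rel <= 0.01


class TestDenoiseVolume:
    def test_deterministic(self, default_case):
        _, pre, _, _ = default_case
        a = denoise_volume(pre).data
        b = denoise_volume(pre).data
        np.testing.assert_array_equal(a, b)

    def test_smooth_volume_stability(self, smooth_slice):
        vol = VolumeImage(smooth_slice[None])
        out = denoise_volume(vol, bias_correction=False).data[0]
        rel = (np.sqrt(np.mean((out - smooth_slice) ** 2)) /
               np.sqrt(np.mean(smooth_slice ** 2)))
        assert rel <= 0.10

    def test_improves_psnr_on_rician_phantom(self, clean_case):
        _, clean, _, _ = clean_case
        noisy = rician_noise(clean, 8.0, seed=5)
        den = denoise_volume(noisy)
        assert psnr(clean, den) > psnr(clean, noisy)

    def test_larger_c_never_increases_energy(self, default_case):
        """Monotonicity: a larger threshold multiplier removes more amplitude."""
        _, pre, _, _ = default_case
        vol = VolumeImage(pre.data[:2])
        energies = []
        for c in (0.5, 1.0, 2.0):
            out = denoise_volume(vol, c=c, bias_correction=False).data
            energies.append(float(np.sum((out - out.mean()) ** 2)))
        assert energies[0] >= energies[1] >= energies[2] - 1e-6
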