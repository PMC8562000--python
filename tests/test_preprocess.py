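"""Enhancement chain: per-stage contracts and whole-chain properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage as ndi

from octamacula.preprocess import (
    HomomorphicConfig,
    PreprocessConfig,
    StageError,
    bilateral_denoise,
    central_disc_mask,
    grayscale_and_crop,
    homomorphic_filter,
    jerman_vesselness,
    normalize,
    run_preprocess,
    subtract_faz_background,
    tophat_bottomhat_enhance,
)
from octamacula.synthgen import PhantomParams, generate_phantom
from octamacula.vesselmetrics import binarize_otsu


class TestGrayscaleAndCrop:
    def test_crops_365_to_364(self, rng):
        img = rng.integers(0, 256, (365, 365), dtype=np.uint8)
        out = grayscale_and_crop(img)
        assert out.pixels.shape == (364, 364)
        assert np.array_equal(out.pixels, img[1:, 1:])

    def test_rgb_collapsed_by_luminance(self, rng):
        img = rng.integers(0, 256, (365, 365, 3), dtype=np.uint8)
        out = grayscale_and_crop(img)
        assert out.pixels.ndim == 2

    def test_constant_input_stays_constant(self):
        out = grayscale_and_crop(np.full((365, 365), 77, np.uint8))
        assert (out.pixels == 77).all()

    def test_wrong_size_raises_with_dimensions(self):
        with pytest.raises(ValueError, match="364x364"):
            grayscale_and_crop(np.zeros((364, 364), np.uint8))


class TestHomomorphic:
    def test_constant_image_scaled_by_low_gain_in_log_domain(self):
        c = 0.5
        out = homomorphic_filter(np.full((64, 64), c), HomomorphicConfig(low_gain=0.5))
        expected = np.expm1(0.5 * np.log1p(c))
        assert out == pytest.approx(np.full((64, 64), expected), rel=1e-9)

    def test_flattens_illumination_ramp(self):
        # horizontal ridge stripes under a 2:1 left-right illumination ramp
        n = 128
        y = np.arange(n)
        ridges = (0.5 + 0.4 * np.cos(2 * np.pi * y / 8))[:, None].repeat(n, 1)
        illum = np.linspace(1.0, 0.5, n)[None, :].repeat(n, 0)
        img = ridges * illum

        def contrast_ratio(im):
            # per-column stripe amplitude, averaged per half
            amp = im.max(axis=0) - im.min(axis=0)
            return amp[: n // 2].mean() / amp[n // 2:].mean()

        before = contrast_ratio(img)
        # illumination-correction setting: suppress low frequencies only
        after = contrast_ratio(
            homomorphic_filter(img, HomomorphicConfig(low_gain=0.5, high_gain=1.0))
        )
        assert abs(after - 1) < abs(before - 1)

    def test_double_application_equals_squared_gains(self):
        rng = np.random.default_rng(1)
        img = 0.5 + 0.3 * ndi.gaussian_filter(rng.normal(0, 1, (96, 96)), 2)
        cfg = HomomorphicConfig(low_gain=0.7, high_gain=1.2)
        cfg_sq = HomomorphicConfig(low_gain=0.49, high_gain=1.44)
        twice = homomorphic_filter(homomorphic_filter(img, cfg), cfg)
        once = homomorphic_filter(img, cfg_sq)
        assert np.allclose(twice, once, atol=1e-10)


class TestNormalize:
    def test_linear_rescale(self):
        assert np.allclose(normalize(np.array([[5.0, 10.0, 15.0]])), [[0, 0.5, 1]])

    def test_unit_range_unchanged(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        img[0, 0], img[0, 1] = 0.0, 1.0
        assert np.allclose(normalize(img), img)

    def test_constant_maps_to_zero(self):
        assert (normalize(np.full((8, 8), 3.0)) == 0).all()


class TestSubtractFazBackground:
    def test_zero_mean_region_is_identity(self, rng):
        img = rng.uniform(0.2, 1, (64, 64))
        region = np.zeros((64, 64), bool)
        region[30:34, 30:34] = True
        img[region] = 0.0
        assert np.allclose(subtract_faz_background(img, region), img)

    def test_constant_image_goes_to_zero(self):
        region = central_disc_mask(64, 5)
        out = subtract_faz_background(np.full((64, 64), 0.4), region)
        assert np.allclose(out, 0.0, atol=1e-12)

    @given(
        hnp.arrays(np.float64, (16, 16), elements=st.floats(0, 1)),
    )
    def test_elementwise_oracle_and_bounds(self, img):
        region = np.zeros((16, 16), bool)
        region[6:10, 6:10] = True
        out = subtract_faz_background(img, region)
        expected = np.maximum(img - img[region].mean(), 0.0)
        assert np.allclose(out, expected)
        assert (out <= img + 1e-12).all() and (out >= 0).all()

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            subtract_faz_background(np.ones((8, 8)), np.zeros((8, 8), bool))


class TestTophatBottomhat:
    def test_constant_unchanged(self):
        img = np.full((32, 32), 0.5)
        assert np.allclose(tophat_bottomhat_enhance(img), img)

    def test_bright_dot_contrast_increases(self):
        img = np.full((31, 31), 0.2)
        img[15, 15] = 0.6
        out = tophat_bottomhat_enhance(img, radius_px=4)
        assert out[15, 15] - out[0, 0] > img[15, 15] - img[0, 0]

    def test_thin_bar_enhanced(self):
        img = np.full((40, 40), 0.1)
        img[18:21, :] = 0.5  # 3-px bar, thinner than the 4-px-radius disc
        out = tophat_bottomhat_enhance(img, radius_px=4)
        assert out[18:21, :].mean() > img[18:21, :].mean()


class TestBilateral:
    def test_noise_free_constant_unchanged(self):
        img = np.full((32, 32), 0.5)
        assert np.allclose(bilateral_denoise(img), img, atol=1e-6)

    def test_reduces_noise_in_flat_region(self, rng):
        img = np.clip(0.5 + rng.normal(0, 0.05, (64, 64)), 0, 1)
        out = bilateral_denoise(img, 3, 0.1)
        assert out[16:48, 16:48].std() < img[16:48, 16:48].std()

    def test_preserves_step_edge(self):
        img = np.zeros((32, 64))
        img[:, 32:] = 1.0
        out = bilateral_denoise(img, 3, 0.1)
        height = out[:, 40:].mean() - out[:, :24].mean()
        assert height >= 0.9


class TestJermanVesselness:
    def test_constant_image_all_zero(self):
        assert (jerman_vesselness(np.full((32, 32), 0.3)) == 0).all()

    def test_bounded_unit_interval(self, rng):
        img = ndi.gaussian_filter(rng.uniform(0, 1, (64, 64)), 1)
        v = jerman_vesselness(img)
        assert v.min() >= 0 and v.max() <= 1

    def test_ridge_centerline_is_response_maximum(self):
        # Gaussian ridge (sigma 2 px) along the column direction
        n = 65
        y = np.arange(n) - n // 2
        img = np.exp(-(y**2) / (2 * 2.0**2))[:, None].repeat(n, 1)
        v = jerman_vesselness(img, scales_px=(1, 2, 3))
        for col in range(10, n - 10):
            # the centerline attains the column's maximum response
            assert v[n // 2, col] == v[:, col].max() > 0
            # and the response decays to zero away from the ridge
            assert v[2, col] == 0 and v[-3, col] == 0

    def test_ridge_beats_blob(self):
        # equal peak intensity: the elongated structure must respond more
        # strongly at its axis than the isotropic blob at its center
        n = 81
        y = np.arange(n) - n // 2
        ridge = np.exp(-(y**2) / (2 * 2.0**2))[:, None].repeat(n, 1)
        yy, xx = np.mgrid[0:n, 0:n] - n // 2
        blob = np.exp(-(yy**2 + xx**2) / (2 * 2.0**2))
        v_ridge = jerman_vesselness(ridge, scales_px=(1, 2, 3))
        v_blob = jerman_vesselness(blob, scales_px=(1, 2, 3))
        c = n // 2
        assert v_ridge[c, c] > v_blob[c, c]
        assert v_blob[c, c] < 0.1  # isotropic center suppressed

    def test_rotation_equivariance_90deg(self, rng):
        img = ndi.gaussian_filter(rng.uniform(0, 1, (48, 48)), 1)
        assert np.allclose(
            jerman_vesselness(np.rot90(img)), np.rot90(jerman_vesselness(img)),
            atol=1e-10,
        )

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            jerman_vesselness(np.zeros((8, 8)), scales_px=())
        with pytest.raises(ValueError):
            jerman_vesselness(np.zeros((8, 8)), tau=0.0)


class TestRunPreprocess:
    def test_deterministic(self, phantom_default):
        _, angio, _ = phantom_default
        v1 = run_preprocess(angio.pixels)
        v2 = run_preprocess(angio.pixels)
        assert np.array_equal(v1, v2)

    def test_all_black_input_gives_zero_map(self):
        v = run_preprocess(np.zeros((365, 365), np.uint8))
        assert (v == 0).all()

    def test_clean_phantom_segmentation_dice(self, phantom_clean, vesselness_clean):
        _, _, truth = phantom_clean
        mask = binarize_otsu(vesselness_clean).pixels
        t = truth.cropped().vessel_mask
        dice = 2 * (mask & t).sum() / (mask.sum() + t.sum())
        assert dice >= 0.75

    def test_stage_error_names_stage(self):
        cfg = PreprocessConfig()
        cfg.faz_sample_mask = np.zeros((364, 364), bool)  # empty sample region
        with pytest.raises(StageError, match="subtract_faz_background"):
            run_preprocess(np.random.default_rng(0).integers(0, 255, (365, 365), dtype=np.uint8), cfg)

    def test_enhancement_helps_on_attenuated_noisy_eyes(self):
        """On dim, attenuated, noisy vasculature (the irradiated-eye regime)
        Otsu on the enhanced map beats Otsu on the raw image on average."""
        d_enh, d_raw = [], []
        for seed in range(51, 59):
            params = PhantomParams(
                rng_seed=seed, target_vad=0.25 + 0.02 * (seed - 51),
                noise_sigma=0.1, faz_noise_level=0.1, burnout_attenuation=0.5,
            )
            angio, truth = generate_phantom(params)
            t = truth.cropped().vessel_mask
            m_enh = binarize_otsu(run_preprocess(angio.pixels)).pixels
            m_raw = binarize_otsu(angio.pixels[1:, 1:] / 255.0).pixels
            d_enh.append(2 * (m_enh & t).sum() / (m_enh.sum() + t.sum()))
            d_raw.append(2 * (m_raw & t).sum() / (m_raw.sum() + t.sum()))
        assert np.mean(d_enh) >= np.mean(d_raw)
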