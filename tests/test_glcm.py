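import numpy as np
import pytest
from scipy.signal import convolve2d

from breastasym.errors import ContractError, DegenerateInputError
from breastasym.glcm import (
    HARALICK_NAMES,
    GLCMConfig,
    compute_glcm,
    dog_denoise,
    glcm_feature_vector,
    haralick_features,
)
from breastasym.synthetic import TexturePatchParams, generate_texture_patch

from _oracles import glcm_by_pair_enumeration, haralick_by_literal_formulas


def _random_glcm(rng, g=8):
    m = rng.uniform(0, 1, size=(g, g))
    m = m + m.T
    return m / m.sum()


class TestDogDenoise:
    def test_constant_image_degenerates_to_midpoint(self):
        out = dog_denoise(np.full((16, 16), 7.0))
        assert np.allclose(out, 7.0)

    def test_impulse_has_center_peak_and_negative_surround(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = dog_denoise(img, 1.0, 3.0)
        assert out[10, 10] == out.max()
        assert out[10, 16] < out[10, 10]  # surround suppressed relative to center

    def test_matches_explicit_kernel_convolution(self):
        # oracle: explicit sampled Gaussian kernels + 2D convolution with
        # symmetric boundary, then the same min-max rescale
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, size=(24, 24))
        s1, s2 = 1.0, 2.0

        def gauss_kernel(sigma):
            radius = int(4.0 * sigma + 0.5)
            x = np.arange(-radius, radius + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            k /= k.sum()
            return np.outer(k, k)

        band = convolve2d(img, gauss_kernel(s1), mode="same", boundary="symm") - convolve2d(
            img, gauss_kernel(s2), mode="same", boundary="symm"
        )
        expected = img.min() + (band - band.min()) * (img.max() - img.min()) / (
            band.max() - band.min()
        )
        assert np.allclose(dog_denoise(img, s1, s2), expected, atol=1e-6)

    def test_output_spans_input_range(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 50, size=(32, 32))
        out = dog_denoise(img)
        assert out.min() == pytest.approx(img.min())
        assert out.max() == pytest.approx(img.max())

    def test_bad_sigmas_rejected(self):
        with pytest.raises(ContractError):
            dog_denoise(np.zeros((8, 8)), 2.0, 1.0)


class TestComputeGLCM:
    def test_alternating_row_example(self):
        img = np.array([[0.0, 1.0, 0.0, 1.0]])
        glcm = compute_glcm(img, distance=1, theta=0, gray_levels=2, symmetric=True)
        assert np.allclose(glcm, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_single_diagonal_cell(self):
        img = np.full((6, 6), 4.0)
        for theta in (0, 45, 90, 135):
            glcm = compute_glcm(img, theta=theta, gray_levels=8)
            assert glcm[0, 0] == 1.0
            assert glcm.sum() == 1.0

    def test_normalization_and_symmetry(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 100, size=(12, 12))
        glcm = compute_glcm(img, theta=45, gray_levels=16)
        assert glcm.sum() == pytest.approx(1.0)
        assert np.allclose(glcm, glcm.T)

    def test_matches_pair_enumeration_oracle(self):
        # 50 random small images with random masks, all four orientations
        rng = np.random.default_rng(3)
        for trial in range(50):
            h, w = rng.integers(4, 17, size=2)
            img = rng.uniform(0, 50, size=(h, w))
            mask = rng.random((h, w)) < 0.8
            mask.flat[rng.integers(0, h * w)] = True  # never empty
            theta = [0, 45, 90, 135][trial % 4]
            symmetric = bool(trial % 2)
            try:
                ours = compute_glcm(
                    img, mask, distance=1, theta=theta, gray_levels=8, symmetric=symmetric
                )
            except DegenerateInputError:
                continue  # no valid pair under this mask draw
            oracle = glcm_by_pair_enumeration(img, mask, 1, theta, 8, symmetric)
            assert np.allclose(ours, oracle, atol=1e-12)

    def test_agrees_with_skimage_on_integer_images(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(4)
        img = rng.integers(0, 8, size=(20, 20))
        ours = compute_glcm(img.astype(float), theta=0, gray_levels=8, symmetric=True)
        ref = graycomatrix(img.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True)
        assert np.allclose(ours, ref[:, :, 0, 0], atol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_glcm(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))


class TestHaralick:
    def test_constant_image_features(self):
        glcm = compute_glcm(np.full((8, 8), 3.0), gray_levels=8)
        feats = haralick_features(glcm)
        assert feats["asm"] == 1.0
        assert feats["contrast"] == 0.0
        assert feats["entropy"] == 0.0

    def test_checkerboard_contrast(self):
        # all co-occurring pairs differ by exactly one level
        glcm = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert haralick_features(glcm)["contrast"] == 1.0

    def test_matches_literal_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            glcm = _random_glcm(rng)
            ours = haralick_features(glcm)
            oracle = haralick_by_literal_formulas(glcm)
            for name in HARALICK_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-9), name

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ContractError):
            haralick_features(np.ones((4, 4)))

    def test_asm_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            feats = haralick_features(_random_glcm(rng))
            assert 0.0 < feats["asm"] <= 1.0
            assert feats["contrast"] >= 0.0
            assert feats["entropy"] >= 0.0


class TestFeatureVector:
    def test_identical_orientations_average_to_themselves(self):
        img = np.full((8, 8), 1.0)
        img[::2] = 0.0  # horizontal stripes: all four orientations defined
        config = GLCMConfig(gray_levels=4)
        averaged = glcm_feature_vector(img, config=config)
        per = [
            haralick_features(compute_glcm(img, None, 1, t, 4, True)) for t in (0, 45, 90, 135)
        ]
        for name in HARALICK_NAMES:
            assert averaged[f"h_{name}"] == pytest.approx(
                np.mean([p[name] for p in per]), abs=1e-12
            )

    def test_concatenated_mode_has_52_features(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 10, size=(16, 16))
        config = GLCMConfig(average_over_orientations=False)
        assert len(glcm_feature_vector(img, config=config)) == 52

    def test_isotropic_texture_has_isotropic_contrast(self):
        # orientations sharing a displacement length agree within 20%
        patch = generate_texture_patch(
            TexturePatchParams(size=96, gray_levels=16, correlation_length=4.0, seed=9)
        )
        config = GLCMConfig(gray_levels=16, average_over_orientations=False)
        feats = glcm_feature_vector(patch.values, config=config)
        c0, c90 = feats["h_contrast_o0"], feats["h_contrast_o90"]
        c45, c135 = feats["h_contrast_o45"], feats["h_contrast_o135"]
        assert abs(c0 - c90) <= 0.2 * max(c0, c90)
        assert abs(c45 - c135) <= 0.2 * max(c45, c135)
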