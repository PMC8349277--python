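import math

import numpy as np
import pytest

from breastasym.errors import ContractError
from breastasym.gabor import (
    GaborBankConfig,
    asymmetry_signature,
    build_filter_bank,
    compute_sigmas,
    extract_feature_vector,
    feature_names,
    filter_response,
)
from breastasym.pipelines import thermo_signature

from _oracles import gabor_energy_by_double_loop


def grating(shape, f, theta_deg, amplitude=1.0):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = math.radians(theta_deg)
    return amplitude * np.cos(2 * np.pi * f * (cols * math.cos(th) + rows * math.sin(th)))


class TestSigmas:
    def test_closed_form_value(self):
        # independent arithmetic: sqrt(ln2)*(2+1)/(sqrt(2)*pi*0.25*(2-1))
        expected = math.sqrt(math.log(2)) * 3 / (math.sqrt(2) * math.pi * 0.25)
        sx, sy = compute_sigmas(0.25, 1.0, 45.0, circular=True)
        assert sx == pytest.approx(expected, rel=1e-12)
        assert sx == pytest.approx(2.2487, abs=5e-5)
        assert sy == sx

    def test_noncircular_sigma_y(self):
        _, sy = compute_sigmas(0.25, 1.0, 45.0, circular=False)
        expected = math.sqrt(math.log(2)) / (
            math.sqrt(2) * math.pi * 0.25 * math.tan(math.radians(22.5))
        )
        assert sy == pytest.approx(expected, rel=1e-12)

    def test_inverse_frequency_scaling(self):
        sx1, _ = compute_sigmas(0.1)
        sx2, _ = compute_sigmas(0.2)
        assert sx1 / sx2 == pytest.approx(2.0, rel=1e-12)

    def test_wide_bandwidth_limit(self):
        f = 0.2
        sx, _ = compute_sigmas(f, frequency_bandwidth=40.0)
        assert sx == pytest.approx(math.sqrt(math.log(2)) / (math.sqrt(2) * math.pi * f), rel=1e-6)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ContractError):
            compute_sigmas(0.0)


class TestBank:
    def test_default_bank_structure(self):
        bank = build_filter_bank()
        assert len(bank) == 20
        assert sorted({f.f for f in bank}, reverse=True) == [0.25, 0.176, 0.125, 0.088]
        assert sorted({f.theta for f in bank}) == [0.0, 36.0, 72.0, 108.0, 144.0]

    def test_kernels_are_zero_mean(self):
        for filt in build_filter_bank():
            assert abs(filt.kernel.sum()) <= 1e-9 * np.abs(filt.kernel).sum()

    def test_kernel_side_follows_truncation(self):
        config = GaborBankConfig(kernel_truncation=2.5)
        for filt in build_filter_bank(config):
            half = math.ceil(2.5 * max(filt.sigma_x, filt.sigma_y))
            assert filt.kernel.shape == (2 * half + 1, 2 * half + 1)

    def test_bank_size_scales_with_config(self):
        config = GaborBankConfig(frequencies=(0.25, 0.125), n_orientations=3)
        assert len(build_filter_bank(config)) == 6

    def test_octave_spacing_flag(self):
        config = GaborBankConfig(frequency_spacing="octave", fmax=0.25, n_frequencies=3)
        assert config.frequency_set() == (0.25, 0.125, 0.0625)
        half = GaborBankConfig(frequency_spacing="half-octave", fmax=0.25, n_frequencies=4)
        assert half.frequency_set() == pytest.approx((0.25, 0.17678, 0.125, 0.08839), abs=5e-5)

    def test_feature_names_convention(self):
        names = feature_names()
        assert len(names) == 20
        assert names[0] == "g_f0.25_o0"
        assert names[-1] == "g_f0.088_o144"


class TestFilterResponse:
    def test_zero_image_zero_response(self):
        filt = build_filter_bank()[0]
        assert not filter_response(np.zeros((32, 32)), None, filt).any()

    def test_constant_image_near_zero_response(self):
        filt = build_filter_bank()[0]
        resp = filter_response(np.full((32, 32), 9.0), None, filt)
        assert np.abs(resp).max() < 1e-9

    def test_matched_orientation_dominates(self):
        config = GaborBankConfig(frequencies=(0.25,), n_orientations=2)  # 0 and 90 deg
        bank = build_filter_bank(config)
        img = grating((48, 48), f=0.25, theta_deg=0.0)
        e_matched = np.abs(filter_response(img, None, bank[0])).mean()
        e_orthogonal = np.abs(filter_response(img, None, bank[1])).mean()
        assert e_matched >= 5 * e_orthogonal

    def test_kernel_larger_than_roi_rejected(self):
        filt = build_filter_bank()[-1]  # f=0.088 -> largest kernel
        with pytest.raises(ContractError):
            filter_response(np.zeros((8, 8)), None, filt)


class TestEnergies:
    def test_zero_image_zero_energies(self):
        bank = build_filter_bank()
        fv = extract_feature_vector(np.zeros((48, 48)), None, bank)
        assert not fv.energies.any()

    def test_intensity_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        roi = rng.normal(size=(48, 48))
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25, 0.125)))
        e1 = extract_feature_vector(roi, None, bank).energies
        e3 = extract_feature_vector(3.0 * roi, None, bank).energies
        assert np.allclose(e3, 3.0 * e1, rtol=1e-9)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(6)
        roi = rng.normal(size=(48, 48))
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25,)))
        e0 = extract_feature_vector(roi, None, bank).energies
        e1 = extract_feature_vector(roi + 11.0, None, bank).energies
        assert np.allclose(e0, e1, atol=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        roi = rng.normal(size=(32, 32))
        mask = np.ones((32, 32), dtype=bool)
        mask[:4] = False
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25,), n_orientations=2))
        fv = extract_feature_vector(roi, mask, bank)
        for k, filt in enumerate(bank):
            oracle = gabor_energy_by_double_loop(roi, mask, filt.kernel)
            assert fv.energies[k] == pytest.approx(oracle, rel=1e-6)

    def test_mean_abs_comparable_across_roi_sizes(self):
        # the same grating, full field vs cropped to half size: matched-filter
        # mean-abs energies agree within 10%
        img = grating((64, 64), f=0.25, theta_deg=0.0)
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25,), n_orientations=1))
        full = extract_feature_vector(img, None, bank).energies[0]
        half = extract_feature_vector(img[:32, :32], None, bank).energies[0]
        assert half == pytest.approx(full, rel=0.10)

    def test_rotating_grating_permutes_orientation_energies(self):
        # a grating rotated by one orientation step moves the matched-filter
        # response to the next orientation channel (15% tolerance)
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25,)))
        mask = np.zeros((64, 64), dtype=bool)
        mask[8:-8, 8:-8] = True  # interior: keep padding artifacts out
        e36 = extract_feature_vector(grating((64, 64), 0.25, 36.0), mask, bank).energies
        e72 = extract_feature_vector(grating((64, 64), 0.25, 72.0), mask, bank).energies
        assert np.argmax(e36) == 1 and np.argmax(e72) == 2
        # matched channel and both side lobes follow the rotation
        for src, dst in ((1, 2), (0, 1), (2, 3)):
            assert e72[dst] == pytest.approx(e36[src], rel=0.15, abs=1e-4)

    def test_empty_mask_rejected(self):
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25,)))
        with pytest.raises(ContractError):
            extract_feature_vector(np.zeros((32, 32)), np.zeros((32, 32), bool), bank)


class TestAsymmetrySignature:
    def test_identical_vectors_give_zero(self):
        bank = build_filter_bank(GaborBankConfig(frequencies=(0.25,)))
        rng = np.random.default_rng(8)
        roi = rng.normal(size=(40, 40))
        fv = extract_feature_vector(roi, None, bank)
        sig = asymmetry_signature(fv, fv)
        assert not sig.values.any()

    def test_length_mismatch_rejected(self):
        from breastasym.gabor import FeatureVector

        with pytest.raises(ContractError):
            asymmetry_signature(FeatureVector(np.zeros(3)), FeatureVector(np.zeros(4)))

    def test_signed_mode_antisymmetric(self):
        from breastasym.gabor import FeatureVector

        a = FeatureVector(np.array([1.0, 2.0]))
        b = FeatureVector(np.array([0.5, 3.0]))
        sig = asymmetry_signature(a, b, mode="signed")
        assert sig.values.tolist() == [0.5, -1.0]
        sig_abs = asymmetry_signature(b, a, mode="absolute")
        assert sig_abs.values.tolist() == [0.5, 1.0]

    def test_symmetric_scene_signature_is_null(self, symmetric_scene):
        sig = thermo_signature(symmetric_scene.grid)
        energies_scale = max(abs(v) for v in sig.values())
        assert energies_scale <= 1e-9

    def test_signature_norm_monotone_in_lesion_amplitude(self, symmetric_scene, lesion_scenes):
        norms = [np.linalg.norm(list(thermo_signature(symmetric_scene.grid).values()))]
        for amp in (0.5, 1.0, 2.0):
            sig = thermo_signature(lesion_scenes[amp].grid)
            norms.append(np.linalg.norm(list(sig.values())))
        assert all(a < b for a, b in zip(norms, norms[1:]))
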