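import numpy as np
import pytest

import oracles
from xgifuse.errors import ValidationError
from xgifuse.image_io import TriContrastSet
from xgifuse.metrics import (
    crop_roi, edge_strength, entropy, feature_mutual_information, fsim,
    fusion_factor, mutual_information, overall_fsim, overall_ssim,
    periodogram, psd_curve, report, spatial_frequency, ssim,
    standard_deviation,
)


class TestSpatialFrequency:
    def test_constant_is_zero(self):
        assert spatial_frequency(np.full((16, 16), 0.5)) == 0.0

    def test_matches_double_loop(self, rng):
        Z = rng.random((16, 16))
        assert spatial_frequency(Z) == pytest.approx(oracles.sf_scalar(Z), abs=1e-12)

    def test_vertical_stripes_have_row_frequency_only(self):
        Z = np.tile(np.arange(16) % 2, (16, 1)).astype(float)  # columns alternate
        # along columns (vertical direction) nothing changes
        cf2 = np.sum((Z[1:, :] - Z[:-1, :]) ** 2)
        assert cf2 == 0.0
        assert spatial_frequency(Z) > 0


class TestEntropySD:
    def test_constant_image(self):
        img = np.full((16, 16), 0.5)
        assert standard_deviation(img) == 0.0
        assert entropy(img) == 0.0

    def test_two_level_equal_area_is_one_bit(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        assert entropy(img) == pytest.approx(1.0, abs=1e-12)

    def test_matches_histogram_oracle(self, rng):
        Z = rng.random((32, 32))
        assert entropy(Z) == pytest.approx(oracles.entropy_scalar(Z), abs=1e-12)
        assert standard_deviation(Z) == pytest.approx(oracles.sd_scalar(Z), abs=1e-12)

    def test_uniform_noise_entropy_approaches_eight_bits(self, rng):
        Z = rng.random((256, 256))
        h = entropy(Z)
        assert 7.9 < h < 8.0


class TestMutualInformation:
    def test_self_information_identity(self, rng):
        A = rng.random((32, 32))
        assert mutual_information(A, A) == pytest.approx(entropy(A), abs=1e-12)

    def test_independent_images_bounded_by_sampling_bias(self):
        """MI of independent noise is pure finite-sample bias: about
        (K-1)^2 / (2 N ln 2) bits for a K x K joint histogram on N
        pixels (chi-square approximation), i.e. ~0.72 bits here —
        orders of magnitude below the ~8 bits of self-information."""
        n = 256 * 256
        bias = 255 * 255 / (2 * n * np.log(2))
        mis = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            A, B = r.random((256, 256)), r.random((256, 256))
            mis.append(mutual_information(A, B))
        assert max(mis) < 2 * bias
        assert max(mis) < 0.15 * entropy(A)

    def test_matches_joint_histogram_oracle(self, rng):
        A, B = rng.random((16, 16)), rng.random((16, 16))
        assert mutual_information(A, B) == pytest.approx(
            oracles.mi_scalar(A, B), abs=1e-12)

    def test_fusion_factor_identity_triple(self, rng):
        A = rng.random((32, 32))
        tri = TriContrastSet(A, A, A)
        assert fusion_factor(tri, A) == pytest.approx(3 * entropy(A), abs=1e-12)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        A = rng.random((32, 32))
        assert ssim(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self, rng):
        A, B = rng.random((32, 32)), rng.random((32, 32))
        assert ssim(A, B) == pytest.approx(ssim(B, A), abs=1e-12)

    def test_matches_window_oracle(self, rng):
        A, B = rng.random((20, 20)), rng.random((20, 20))
        assert ssim(A, B) == pytest.approx(oracles.ssim_scalar(A, B), abs=1e-9)

    def test_inverted_two_level_image_below_one(self):
        A = np.zeros((32, 32))
        A[:, 16:] = 1.0
        assert ssim(A, 1.0 - A) < 1.0


class TestFSIM:
    def test_self_similarity_is_one(self, rng):
        A = rng.random((32, 32))
        assert fsim(A, A) == pytest.approx(1.0, abs=1e-9)

    def test_pooling_matches_pointwise_formula(self, rng):
        """Given the package's own phase-congruency and gradient maps, the
        pooled index must equal the double-loop evaluation of the
        similarity law."""
        from xgifuse.metrics import _scharr_magnitude, phase_congruency
        A, B = rng.random((24, 24)), rng.random((24, 24))
        pc_a, pc_b = phase_congruency(A), phase_congruency(B)
        gm_a, gm_b = _scharr_magnitude(A * 255), _scharr_magnitude(B * 255)
        num = den = 0.0
        for i in range(24):
            for j in range(24):
                s_pc = (2 * pc_a[i, j] * pc_b[i, j] + 0.85) / (
                    pc_a[i, j] ** 2 + pc_b[i, j] ** 2 + 0.85)
                s_gm = (2 * gm_a[i, j] * gm_b[i, j] + 160.0) / (
                    gm_a[i, j] ** 2 + gm_b[i, j] ** 2 + 160.0)
                w = max(pc_a[i, j], pc_b[i, j])
                num += s_pc * s_gm * w
                den += w
        assert fsim(A, B) == pytest.approx(num / den, abs=1e-9)

    def test_degraded_image_scores_below_identity(self, phantom_small):
        A = phantom_small.clean.ac
        blurred = np.clip(A + 0.2 * np.random.default_rng(0).random(A.shape), 0, 1)
        assert fsim(A, blurred) < fsim(A, A)


class TestEdgeStrength:
    def _tri(self, rng, n=16):
        return TriContrastSet(*[rng.random((n, n)) for _ in range(3)])

    def test_identity_fusion_reaches_measure_maximum(self, rng):
        A = rng.random((16, 16))
        tri = TriContrastSet(A, A, A)
        es = edge_strength(tri, A)
        q_max = (0.9994 / (1 + np.exp(-15 * (1 - 0.5)))) * \
                (0.9879 / (1 + np.exp(-22 * (1 - 0.8))))
        assert es == pytest.approx(q_max, abs=1e-9)

    def test_constant_fused_scores_near_zero(self, rng):
        tri = self._tri(rng)
        es = edge_strength(tri, np.full((16, 16), 0.5))
        assert es < 0.01

    def test_matches_double_loop_oracle(self, rng):
        tri = self._tri(rng, 12)
        F = rng.random((12, 12))
        expected = oracles.edge_strength_scalar(list(tri.channels()), F)
        assert edge_strength(tri, F) == pytest.approx(expected, abs=1e-9)


class TestPSD:
    def test_constant_image_dc_only(self):
        c = 0.3
        curve = psd_curve(np.full((16, 16), c))
        assert curve[0, 1] == pytest.approx(c ** 2 * 256, rel=1e-9)
        assert np.abs(curve[1:, 1]).max() < 1e-20

    def test_pure_sinusoid_peaks_at_its_radius(self):
        N = 32
        j = np.arange(N)
        img = 0.5 + 0.4 * np.cos(2 * np.pi * 4 * j / N)
        Z = np.tile(img, (N, 1))
        curve = psd_curve(Z)
        nondc = curve[1:, 1]
        assert int(curve[1 + np.argmax(nondc), 0]) == 4

    def test_parseval(self, rng):
        Z = rng.random((16, 16))
        P = periodogram(Z)
        assert P.sum() == pytest.approx(np.sum(Z ** 2), rel=1e-10)

    def test_matches_double_loop_dft_oracle(self, rng):
        Z = rng.random((8, 8))
        expected = oracles.psd_scalar(Z)
        got = psd_curve(Z)
        assert np.allclose(got, expected, atol=1e-9)


class TestReportAndROI:
    def test_identity_triple_composite(self, rng):
        A = rng.random((32, 32))
        tri = TriContrastSet(A, A, A)
        rep = report(tri, A)
        assert rep.ssim == pytest.approx(1.0, abs=1e-9)
        assert rep.fsim == pytest.approx(1.0, abs=1e-9)
        assert rep.ff == pytest.approx(3 * entropy(A), abs=1e-9)
        from xgifuse.metrics import _gradient_feature
        assert rep.fmi == pytest.approx(3 * entropy(_gradient_feature(A)), abs=1e-9)
        assert rep.fmi == feature_mutual_information(tri, A)

    def test_full_frame_roi_equals_absent(self, rng):
        tri = TriContrastSet(*[rng.random((32, 32)) for _ in range(3)])
        F = rng.random((32, 32))
        r_none = report(tri, F)
        r_full = report(tri, F, roi=(0, 0, 32, 32))
        for name in ("es", "sf", "sd", "entropy", "fmi", "fsim", "ff", "ssim"):
            assert getattr(r_none, name) == getattr(r_full, name)

    def test_roi_crop_before_equals_slice_after(self, rng):
        tri = TriContrastSet(*[rng.random((48, 48)) for _ in range(3)])
        F = rng.random((48, 48))
        roi = (8, 8, 40, 40)
        r_roi = report(tri, F, roi=roi)
        tri_c = tri.map(lambda im: crop_roi(im, roi))
        r_pre = report(tri_c, crop_roi(F, roi))
        for name in ("es", "sf", "sd", "entropy", "fmi", "fsim", "ff", "ssim"):
            assert getattr(r_roi, name) == getattr(r_pre, name)

    def test_empty_roi_rejected(self, rng):
        tri = TriContrastSet(*[rng.random((32, 32)) for _ in range(3)])
        with pytest.raises(ValidationError, match="ROI"):
            report(tri, rng.random((32, 32)), roi=(5, 5, 5, 20))

    def test_metric_ranges(self, rng):
        tri = TriContrastSet(*[rng.random((32, 32)) for _ in range(3)])
        rep = report(tri, rng.random((32, 32)))
        assert 0 <= rep.ssim <= 1 and 0 <= rep.fsim <= 1
        assert 0 <= rep.entropy <= 8
        assert min(rep.es, rep.sf, rep.sd, rep.fmi, rep.ff) >= 0
        assert all(p >= 0 for _, p in rep.psd)
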