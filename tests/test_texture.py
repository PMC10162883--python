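import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ct2bmd.errors import DegenerateROIError, ParameterError
from ct2bmd.imaging import quantize
from ct2bmd.texture import (
    CooccurrenceMatrix,
    average_glcms,
    compute_glcm,
    contrast,
    correlation,
    correlation_with_flag,
    energy,
    entropy,
    features_from_glcm,
    features_from_roi,
    homogeneity,
)


def random_probability_matrix(rng, ng):
    P = rng.uniform(0, 1, (ng, ng))
    return P / P.sum()


class TestComputeGLCM:
    def test_two_horizontal_pairs(self):
        q = quantize(np.array([[0.0, 1.0], [0.0, 1.0]]), 2)
        m = compute_glcm(q, d=1, theta=0)
        np.testing.assert_allclose(m.P, [[0, 1], [0, 0]])
        assert m.pair_count == 2

    def test_two_vertical_pairs(self):
        q = quantize(np.array([[0.0, 1.0], [0.0, 1.0]]), 2)
        m = compute_glcm(q, d=1, theta=90)
        np.testing.assert_allclose(m.P, [[0.5, 0], [0, 0.5]])

    def test_constant_image_single_entry(self):
        q = quantize(np.full((5, 5), 3.0), 4)
        m = compute_glcm(q, d=1, theta=45)
        assert m.P[0, 0] == 1.0
        assert m.P.sum() == 1.0

    def test_unsupported_theta(self):
        q = quantize(np.zeros((3, 3)), 2)
        with pytest.raises(ParameterError):
            compute_glcm(q, d=1, theta=30)

    def test_roi_too_small_for_offset(self):
        q = quantize(np.array([[0.0, 1.0]]), 2)
        with pytest.raises(DegenerateROIError):
            compute_glcm(q, d=1, theta=90)  # single row, vertical offset

    def test_masked_column_blocks_horizontal_pairs(self):
        grid = np.array([[0.0, 5.0, 0.0], [0.0, 5.0, 0.0]])
        q = quantize(grid, 2)
        q.mask[:, 1] = False
        # every d=1 horizontal pair crosses the masked column
        with pytest.raises(DegenerateROIError):
            compute_glcm(q, d=1, theta=0)
        # vertical pairs in the unmasked columns remain countable
        m = compute_glcm(q, d=1, theta=90)
        assert m.pair_count == 2
        assert m.P[0, 0] == 1.0

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_matches_brute_force_loops(self, rng, theta):
        from ct2bmd.texture import OFFSETS

        grid = rng.integers(0, 6, (9, 11)).astype(float)
        q = quantize(grid, 6)
        m = compute_glcm(q, d=1, theta=theta)
        expected = oracles.brute_glcm(q.levels, 6, OFFSETS[theta])
        np.testing.assert_allclose(m.P, expected, atol=1e-12)

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_reverse_offset_is_transpose(self, rng, theta):
        from ct2bmd.texture import OFFSETS

        grid = rng.integers(0, 4, (8, 8)).astype(float)
        q = quantize(grid, 4)
        m = compute_glcm(q, d=1, theta=theta)
        dr, dc = OFFSETS[theta]
        reverse = oracles.brute_glcm(q.levels, 4, (-dr, -dc))
        np.testing.assert_allclose(m.P.T, reverse, atol=1e-12)

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_symmetric_is_average_of_both_directions(self, rng, theta):
        from ct2bmd.texture import OFFSETS

        grid = rng.integers(0, 4, (8, 8)).astype(float)
        q = quantize(grid, 4)
        asym = compute_glcm(q, d=1, theta=theta)
        sym = compute_glcm(q, d=1, theta=theta, symmetric=True)
        np.testing.assert_allclose(sym.P, (asym.P + asym.P.T) / 2, atol=1e-12)

    def test_entries_sum_to_one(self, rng):
        grid = rng.normal(0, 100, (16, 16))
        q = quantize(grid, 8)
        for theta in (0, 45, 90, 135):
            m = compute_glcm(q, d=1, theta=theta)
            assert m.P.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(m.P >= 0)


class TestAverageGLCMs:
    def _mat(self, P):
        P = np.asarray(P, dtype=float)
        return CooccurrenceMatrix(P=P, ng=P.shape[0], d=1, theta=0, symmetric=False, pair_count=1)

    def test_single_matrix_identity(self):
        m = self._mat([[0.25, 0.25], [0.25, 0.25]])
        np.testing.assert_allclose(average_glcms([m]).P, m.P)

    def test_element_wise_mean(self):
        a = self._mat([[1.0, 0.0], [0.0, 0.0]])
        b = self._mat([[0.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(average_glcms([a, b]).P, [[0.5, 0], [0, 0.5]])

    def test_replicates_idempotent(self):
        m = self._mat([[0.1, 0.2], [0.3, 0.4]])
        for k in (2, 3, 5):
            np.testing.assert_allclose(average_glcms([m] * k).P, m.P, atol=1e-12)

    def test_mixed_ng_rejected(self):
        a = self._mat(np.eye(2) / 2)
        b = self._mat(np.eye(3) / 3)
        with pytest.raises(ParameterError):
            average_glcms([a, b])

    def test_theta_marked_averaged(self):
        assert average_glcms([self._mat(np.eye(2) / 2)]).theta == "averaged"


class TestFeatureScalars:
    def test_energy_concentrated(self):
        P = np.zeros((3, 3))
        P[1, 2] = 1.0
        assert energy(P) == 1.0

    def test_energy_uniform(self):
        assert energy(np.full((2, 2), 0.25)) == pytest.approx(0.25)

    def test_entropy_concentrated(self):
        P = np.zeros((3, 3))
        P[0, 0] = 1.0
        assert entropy(P) == 0.0

    def test_entropy_uniform_2x2_is_2_bits(self):
        assert entropy(np.full((2, 2), 0.25)) == pytest.approx(2.0)

    @pytest.mark.parametrize("ng", [2, 3, 5, 8])
    def test_entropy_uniform_closed_form(self, ng):
        P = np.full((ng, ng), 1.0 / ng**2)
        assert entropy(P) == pytest.approx(2 * np.log2(ng))

    def test_entropy_natural_log_base(self):
        P = np.full((2, 2), 0.25)
        assert entropy(P, base=np.e) == pytest.approx(2 * np.log(2))

    def test_contrast_diagonal_zero(self):
        assert contrast(np.diag([0.2, 0.3, 0.5])) == 0.0

    def test_contrast_single_offdiagonal(self):
        assert contrast(np.array([[0.0, 1.0], [0.0, 0.0]])) == 1.0

    def test_contrast_distance_two(self):
        P = np.zeros((3, 3))
        P[0, 2] = 1.0
        assert contrast(P) == 4.0

    def test_homogeneity_diagonal_one(self):
        assert homogeneity(np.diag([0.5, 0.5])) == 1.0

    def test_homogeneity_offdiagonal_half(self):
        assert homogeneity(np.array([[0.0, 1.0], [0.0, 0.0]])) == 0.5

    def test_homogeneity_in_unit_interval(self, rng):
        for _ in range(20):
            P = random_probability_matrix(rng, 5)
            assert 0 < homogeneity(P) <= 1

    def test_correlation_perfect_positive(self):
        assert correlation(np.diag([0.5, 0.5])) == pytest.approx(1.0)

    def test_correlation_perfect_negative(self):
        assert correlation(np.array([[0.0, 0.5], [0.5, 0.0]])) == pytest.approx(-1.0)

    def test_correlation_degenerate_flagged(self):
        P = np.zeros((2, 2))
        P[0, 0] = 1.0
        value, degenerate = correlation_with_flag(P)
        assert value == 1.0 and degenerate

    @pytest.mark.parametrize(
        "func,oracle",
        [
            (energy, oracles.brute_energy),
            (entropy, oracles.brute_entropy),
            (contrast, oracles.brute_contrast),
            (homogeneity, oracles.brute_homogeneity),
            (correlation, oracles.brute_correlation),
        ],
    )
    def test_matches_brute_force(self, rng, func, oracle):
        for ng in (2, 4, 8):
            P = random_probability_matrix(rng, ng)
            assert func(P) == pytest.approx(oracle(P), abs=1e-12)

    @given(ng=st.integers(2, 8), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_energy_entropy_duality(self, ng, seed):
        P = random_probability_matrix(np.random.default_rng(seed), ng)
        e = energy(P)
        assert e <= 1.0 + 1e-12
        # entropy zero iff all mass on one entry iff energy == 1
        assert (entropy(P) < 1e-9) == (e > 1 - 1e-9)


class TestFeaturesFromROI:
    def test_constant_roi_limits(self):
        q = quantize(np.full((6, 6), 500.0), 8)
        fv = features_from_roi(q)
        assert fv.energy == pytest.approx(1.0)
        assert fv.entropy == pytest.approx(0.0)
        assert fv.contrast == pytest.approx(0.0)
        assert fv.homogeneity == pytest.approx(1.0)
        assert fv.correlation == 1.0 and fv.correlation_degenerate

    def test_checkerboard_hand_enumerated(self, checkerboard_qroi):
        # 4x4 checkerboard: every horizontal (12) and vertical (12) pair
        # alternates, every 45-degree pair (9) matches.
        fv = features_from_roi(checkerboard_qroi, d=1, thetas=(0, 45, 90))
        P0 = np.array([[0, 0.5], [0.5, 0]])  # 12 pairs, all discordant
        P45 = np.array([[4 / 9, 0], [0, 5 / 9]])  # 9 pairs, all concordant
        P90 = np.array([[0, 0.5], [0.5, 0]])
        avg = (P0 + P45 + P90) / 3
        assert fv.energy == pytest.approx(oracles.brute_energy(avg), abs=1e-12)
        assert fv.entropy == pytest.approx(oracles.brute_entropy(avg), abs=1e-12)
        assert fv.contrast == pytest.approx(oracles.brute_contrast(avg), abs=1e-12)
        assert fv.homogeneity == pytest.approx(oracles.brute_homogeneity(avg), abs=1e-12)
        assert fv.correlation == pytest.approx(oracles.brute_correlation(avg), abs=1e-12)

    def test_cross_implementation_oracle(self, rng):
        from skimage.feature import graycomatrix

        grid = rng.normal(0, 150, (16, 16))
        q = quantize(grid, 8)
        fv = features_from_roi(q, d=1, thetas=(0, 45, 90))
        mats = [
            graycomatrix(
                q.levels.astype(np.uint8),
                [1],
                [oracles.SKIMAGE_ANGLES[t]],
                levels=8,
                symmetric=False,
                normed=True,
            )[:, :, 0, 0]
            for t in (0, 45, 90)
        ]
        avg = np.mean(mats, axis=0)
        assert fv.energy == pytest.approx(oracles.brute_energy(avg), abs=1e-9)
        assert fv.entropy == pytest.approx(oracles.brute_entropy(avg), abs=1e-9)
        assert fv.contrast == pytest.approx(oracles.brute_contrast(avg), abs=1e-9)
        assert fv.homogeneity == pytest.approx(oracles.brute_homogeneity(avg), abs=1e-9)
        assert fv.correlation == pytest.approx(oracles.brute_correlation(avg), abs=1e-9)

    def test_per_orientation_average_variant(self, rng):
        grid = rng.normal(0, 150, (12, 12))
        q = quantize(grid, 4)
        fv = features_from_roi(q, per_orientation_average=True)
        per = [features_from_glcm(compute_glcm(q, 1, t)) for t in (0, 45, 90)]
        assert fv.contrast == pytest.approx(np.mean([f.contrast for f in per]))

    def test_noise_trend_contrast_up_homogeneity_down(self):
        # additive HU noise must not decrease mean contrast nor increase
        # mean homogeneity (Monte-Carlo trend over replicates)
        base = np.where(np.indices((32, 32)).sum(axis=0) % 4 < 2, 700.0, -50.0)
        results = {}
        for sd in (0.0, 40.0, 120.0):
            co, ho = [], []
            for k in range(50):
                noisy = base + np.random.default_rng(k).normal(0, sd, base.shape)
                fv = features_from_roi(quantize(noisy, 8, bounds=(-500, 1150)))
                co.append(fv.contrast)
                ho.append(fv.homogeneity)
            results[sd] = (np.mean(co), np.mean(ho))
        assert results[0.0][0] <= results[40.0][0] <= results[120.0][0]
        assert results[0.0][1] >= results[40.0][1] >= results[120.0][1]
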