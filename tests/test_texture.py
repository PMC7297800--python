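"""GLCM/GLRLM matrices and texture statistics versus brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oracles import (
    oracle_glcm,
    oracle_glcm_features,
    oracle_glrlm,
    oracle_glrlm_features,
    oracle_voxel_features,
)
from periprog.radiomics import (
    directions_13,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    quantize,
)
from periprog.radiomics.registry import GLCM_NAMES, GLRLM_NAMES
from periprog.radiomics.table import extract_modality_features

qpatches = arrays(np.int64, (4, 4, 3), elements=st.integers(1, 5))


class TestGlcmMatrix:
    def test_constant_patch_single_diagonal_entry(self):
        P = glcm_matrix(np.ones((3, 3, 3), dtype=int))
        assert P.shape == (1, 1) and P[0, 0] == 1.0

    def test_single_offset_pair_enumeration(self):
        rng = np.random.default_rng(3)
        q = rng.integers(1, 3, size=(4, 4, 1))
        offsets = np.array([[1, 0, 0]])
        P = glcm_matrix(q, offsets)
        expected = oracle_glcm(q, offsets=[(1, 0, 0)])
        np.testing.assert_allclose(P, expected, rtol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(q=qpatches)
    def test_normalized_and_symmetric(self, q):
        P = glcm_matrix(q)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T, atol=0)

    def test_single_voxel_patch_gives_zero_matrix(self):
        P = glcm_matrix(np.ones((1, 1, 1), dtype=int))
        assert P.sum() == 0.0

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm_matrix(np.ones((2, 2, 2), int), np.array([[0, 0, 0]]))


class TestGlcmFeatures:
    def test_uniform_diagonal_support(self):
        n = 4
        P = np.eye(n) / n
        f = glcm_features(P)
        assert f["contrast"] == 0 and f["dissimilarity"] == 0
        assert f["homogeneity_m"] == pytest.approx(1.0)
        assert f["homogeneity_p"] == pytest.approx(1.0)
        assert f["maximum_probability"] == pytest.approx(1 / n)

    def test_independent_marginals_zero_information_correlation(self):
        px = np.array([0.5, 0.3, 0.2])
        P = np.outer(px, px)
        f = glcm_features(P)
        assert f["imc1"] == pytest.approx(0.0, abs=1e-12)
        assert f["imc2"] == pytest.approx(0.0, abs=1e-6)

    def test_toy_matrix_formula_by_formula(self):
        P = np.array([[0.2, 0.1, 0.0], [0.1, 0.3, 0.05], [0.0, 0.05, 0.2]])
        got = glcm_features(P)
        exp = oracle_glcm_features(P)
        for k in GLCM_NAMES:
            assert got[k] == pytest.approx(exp[k], rel=1e-12, abs=1e-12), k


class TestGlrlm:
    def test_row_of_identical_voxels_single_run(self):
        q = np.ones((1, 1, 4), dtype=int)
        R = glrlm_matrix(q, directions=np.array([[0, 0, 1]]))
        assert R[0, 3] == 1.0 and R.sum() == 1.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(q=qpatches)
    def test_voxel_conservation_per_direction(self, q):
        for d in directions_13():
            R = glrlm_matrix(q, directions=d[None, :])
            lengths = np.arange(1, R.shape[1] + 1)
            assert (R * lengths).sum() == q.size

    def test_toy_patch_exhaustive_run_enumeration(self):
        rng = np.random.default_rng(4)
        q = rng.integers(1, 4, size=(4, 4, 1))
        R = glrlm_matrix(q)
        expected = oracle_glrlm(q)
        np.testing.assert_allclose(R, expected)

    def test_all_runs_length_one(self):
        # checkerboard along the scan direction: every run has length 1
        q = np.array([[[1, 2, 1, 2]]], dtype=int)
        R = glrlm_matrix(q, directions=np.array([[0, 0, 1]]))
        f = glrlm_features(R)
        assert f["short_run_emphasis"] == 1.0
        assert f["long_run_emphasis"] == 1.0
        assert f["run_percentage"] == 1.0

    @pytest.mark.parametrize("L", [2, 3, 5])
    def test_single_run_closed_forms(self, L):
        R = np.zeros((2, L))
        R[1, L - 1] = 1.0
        f = glrlm_features(R)
        assert f["short_run_emphasis"] == pytest.approx(1 / L**2)
        assert f["long_run_emphasis"] == pytest.approx(L**2)
        assert f["run_percentage"] == pytest.approx(1 / L)

    def test_two_level_toy_matrix_direct_summation(self):
        R = np.array([[2.0, 1.0, 0.0], [3.0, 0.0, 1.0]])
        got = glrlm_features(R)
        exp = oracle_glrlm_features(R)
        for k in GLRLM_NAMES:
            assert got[k] == pytest.approx(exp[k], rel=1e-12), k

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            glrlm_features(np.zeros((3, 3)))


def test_fused_kernel_agrees_with_oracle_on_sampled_patches(random_volume_8):
    """Spot check of the fused 42-feature kernel against the pure-Python
    oracle on interior and border voxels (the full-volume sweep runs in the
    acceptance suite)."""
    rng = np.random.default_rng(5)
    coords = rng.integers(0, 8, size=(25, 3))
    coords = np.vstack([coords, [[0, 0, 0], [7, 7, 7], [0, 4, 7]]])
    got = extract_modality_features(random_volume_8, coords)
    for row, c in zip(got, coords):
        exp = oracle_voxel_features(random_volume_8, c)
        np.testing.assert_allclose(row, exp, rtol=1e-9, atol=1e-12)


def test_texture_features_invariant_to_intensity_shift(random_volume_8):
    coords = np.array([[4, 4, 4], [2, 5, 6]])
    a = extract_modality_features(random_volume_8, coords)
    b = extract_modality_features(random_volume_8 + 500.0, coords)
    # columns 9.. are quantization-based within first order block:
    # entropy(9), uniformity(10), mean_gray_level(12); all texture columns
    for col in [9, 10, 12] + list(range(13, 42)):
        np.testing.assert_allclose(a[:, col], b[:, col], rtol=1e-9, atol=1e-12)
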