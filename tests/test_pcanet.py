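"""PCA filter learning and feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcanlm import (
    ActivationSpec,
    PatchConfig,
    PCANetModel,
    apply_activation,
    extract_features,
    extract_patches,
    learn_pca_filters,
    load_model,
    save_model,
    train_pcanet,
)


def brute_force_eig(patches: np.ndarray, L: int):
    """Independent oracle: dense eigendecomposition of the patch scatter."""
    scatter = patches @ patches.T
    evals, evecs = np.linalg.eig(scatter)
    order = np.argsort(evals.real)[::-1][:L]
    return evals.real[order], evecs.real[:, order]


class TestExtractPatches:
    def test_constant_image_gives_zero_columns(self):
        cols = extract_patches(np.full((10, 10), 7.0), PatchConfig(3, 3))
        assert cols.shape == (9, 100)
        np.testing.assert_allclose(cols, 0.0, atol=1e-12)

    def test_single_placement_without_padding(self):
        img = np.arange(49, dtype=float).reshape(7, 7)
        cols = extract_patches(img, PatchConfig(7, 7), padding=None)
        assert cols.shape == (49, 1)

    def test_ramp_image_column_count_and_zero_means(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        cols = extract_patches(img, PatchConfig(3, 3))
        assert cols.shape == (9, 25)
        np.testing.assert_allclose(cols.sum(axis=0), 0.0, atol=1e-10)

    def test_image_smaller_than_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.ones((3, 3)), PatchConfig(5, 5))

    def test_even_patch_side_rejected(self):
        with pytest.raises(ValueError):
            PatchConfig(4, 3)


class TestLearnPcaFilters:
    def test_rank_one_construction_recovers_direction(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(9)
        d /= np.linalg.norm(d)
        c = rng.standard_normal(200)
        patches = np.outer(d, c)
        bank = learn_pca_filters(patches, L=3)
        k0 = bank.kernels[0].ravel()
        assert min(np.linalg.norm(k0 - d), np.linalg.norm(k0 + d)) < 1e-6
        np.testing.assert_allclose(bank.eigenvalues[0], (c**2).sum(), rtol=1e-10)
        np.testing.assert_allclose(bank.eigenvalues[1:], 0.0, atol=1e-8)

    def test_kernels_always_orthonormal(self):
        rng = np.random.default_rng(1)
        patches = rng.standard_normal((25, 300))
        patches -= patches.mean(axis=0)
        bank = learn_pca_filters(patches, L=8)
        V = bank.kernels.reshape(8, -1)
        np.testing.assert_allclose(V @ V.T, np.eye(8), atol=1e-8)
        assert np.all(np.diff(bank.eigenvalues) <= 1e-9)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        patches = rng.standard_normal((9, 50))
        patches -= patches.mean(axis=0)
        bank = learn_pca_filters(patches, L=4)
        evals, evecs = brute_force_eig(patches, 4)
        np.testing.assert_allclose(bank.eigenvalues, evals, rtol=1e-8)
        for j in range(4):
            k = bank.kernels[j].ravel()
            assert min(np.linalg.norm(k - evecs[:, j]), np.linalg.norm(k + evecs[:, j])) < 1e-6

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        k=st.sampled_from([3, 5]),
        n=st.integers(10, 60),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_oracle_agreement_property(self, k, n, seed):
        rng = np.random.default_rng(seed)
        patches = rng.standard_normal((k * k, n))
        patches -= patches.mean(axis=0)
        L = min(4, k * k)
        bank = learn_pca_filters(patches, L=L)
        evals, evecs = brute_force_eig(patches, L)
        np.testing.assert_allclose(bank.eigenvalues, evals, rtol=1e-6, atol=1e-6)
        for j in range(L):
            # compare only well-separated eigenvectors; near-degenerate pairs
            # span the same subspace but are individually unstable
            gap = min(
                abs(evals[j] - evals[j - 1]) if j > 0 else np.inf,
                abs(evals[j] - evals[j + 1]) if j + 1 < len(evals) else np.inf,
            )
            if gap < 1e-3 * max(evals[0], 1.0):
                continue
            k_vec = bank.kernels[j].ravel()
            assert min(
                np.linalg.norm(k_vec - evecs[:, j]), np.linalg.norm(k_vec + evecs[:, j])
            ) < 1e-6

    def test_reconstruction_beats_random_orthonormal_banks(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((9, 120))
        A -= A.mean(axis=0)
        bank = learn_pca_filters(A, L=3)
        V = bank.kernels.reshape(3, -1).T
        err_pca = np.linalg.norm(A - V @ (V.T @ A)) ** 2
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.standard_normal((9, 3)))
            err_rand = np.linalg.norm(A - Q @ (Q.T @ A)) ** 2
            assert err_pca <= err_rand + 1e-9

    def test_L_exceeding_patch_dim_rejected(self):
        with pytest.raises(ValueError):
            learn_pca_filters(np.random.default_rng(0).standard_normal((9, 10)), L=10)

    def test_all_zero_patches_rejected(self):
        with pytest.raises(ValueError):
            learn_pca_filters(np.zeros((9, 10)), L=2)


class TestTrainPcanet:
    def test_constant_corpus_is_degenerate(self):
        with pytest.raises(ValueError):
            train_pcanet([np.full((16, 16), 5.0)], PatchConfig(3, 3), L1=2, L2=2)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_pcanet([], PatchConfig(3, 3), L1=2, L2=2)

    def test_bit_reproducible_and_orthonormal(self):
        rng = np.random.default_rng(4)
        corpus = [rng.standard_normal((20, 20)) * 10 + 100 for _ in range(2)]
        m1 = train_pcanet(corpus, PatchConfig(3, 3), L1=2, L2=2)
        m2 = train_pcanet(corpus, PatchConfig(3, 3), L1=2, L2=2)
        np.testing.assert_array_equal(m1.stage1.kernels, m2.stage1.kernels)
        np.testing.assert_array_equal(m1.stage2.kernels, m2.stage2.kernels)
        for bank in (m1.stage1, m1.stage2):
            V = bank.kernels.reshape(len(bank), -1)
            np.testing.assert_allclose(V @ V.T, np.eye(len(bank)), atol=1e-8)

    def test_stage1_spectrum_conserves_total_variance(self, small_model):
        """Sum of ALL patch-scatter eigenvalues equals its trace."""
        from pcanlm.phantoms import make_training_corpus

        corpus = make_training_corpus(n=4, size=(64, 64), sigma=3.0, seed=2)
        patch = PatchConfig(7, 7)
        scatter = np.zeros((49, 49))
        for img in corpus:
            P = extract_patches(img, patch)
            scatter += P @ P.T
        full = learn_pca_filters(
            np.hstack([extract_patches(img, patch) for img in corpus]), L=49
        )
        np.testing.assert_allclose(
            full.eigenvalues.sum(), np.trace(scatter), rtol=1e-6
        )
        assert np.all(np.diff(small_model.stage1.eigenvalues) <= 1e-9)


class TestActivation:
    def test_prelu_branches(self):
        spec = ActivationSpec("prelu", a=0.25)
        assert apply_activation(np.array(2.0), spec) == 2.0
        assert apply_activation(np.array(-1.0), spec) == -0.25

    def test_relu_is_prelu_with_zero_slope(self):
        x = np.random.default_rng(5).standard_normal((40, 40)) * 10
        np.testing.assert_array_equal(
            apply_activation(x, ActivationSpec("relu")),
            apply_activation(x, ActivationSpec("prelu", a=0.0)),
        )
        assert apply_activation(np.array(-3.0), ActivationSpec("prelu", a=0.0)) == 0.0

    def test_sigmoid_range_and_extremes(self):
        spec = ActivationSpec("sigmoid")
        out = apply_activation(np.array([-1000.0, 0.0, 1000.0]), spec)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0], atol=1e-12)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            ActivationSpec("prelu", a=-0.1)


class TestExtractFeatures:
    def test_stack_shape_and_ordering(self, small_model, noisy_sigma3):
        feats = extract_features(noisy_sigma3, small_model)
        assert feats.shape == (16,) + noisy_sigma3.shape

    def test_constant_image_gives_zero_features(self, small_model):
        # learned kernels with positive eigenvalue are orthogonal to the
        # constant patch because training patches are mean-removed
        feats = extract_features(np.full((32, 32), 77.0), small_model)
        np.testing.assert_allclose(feats, 0.0, atol=1e-7)

    def test_translation_consistency_in_interior(self, small_model, noisy_sigma3):
        feats = extract_features(noisy_sigma3, small_model)
        shifted = extract_features(np.roll(noisy_sigma3, 1, axis=0), small_model)
        band = 16  # exclude boundary effects of padding and roll wrap
        np.testing.assert_allclose(
            feats[:, band:-band, band:-band],
            np.roll(shifted, -1, axis=1)[:, band:-band, band:-band],
            atol=1e-9,
        )

    def test_hash_activation_yields_bounded_integers(self, noisy_sigma3, small_model):
        model = PCANetModel(
            stage1=small_model.stage1,
            stage2=small_model.stage2,
            patch=small_model.patch,
            activation=ActivationSpec("hash"),
        )
        feats = extract_features(noisy_sigma3, model)
        assert feats.shape == (4,) + noisy_sigma3.shape
        np.testing.assert_array_equal(feats, np.rint(feats))
        assert feats.min() >= 0 and feats.max() <= 2 ** len(model.stage2) - 1

    def test_relu_features_equal_prelu_zero_slope(self, noisy_sigma3, small_model):
        kw = dict(
            stage1=small_model.stage1,
            stage2=small_model.stage2,
            patch=small_model.patch,
        )
        m_relu = PCANetModel(activation=ActivationSpec("relu"), **kw)
        m_p0 = PCANetModel(activation=ActivationSpec("prelu", a=0.0), **kw)
        np.testing.assert_array_equal(
            extract_features(noisy_sigma3, m_relu), extract_features(noisy_sigma3, m_p0)
        )

    def test_image_smaller_than_patch_rejected(self, small_model):
        with pytest.raises(ValueError):
            extract_features(np.ones((5, 5)), small_model)


def test_model_serialization_roundtrip(tmp_path, small_model):
    path = tmp_path / "model.npz"
    save_model(small_model, path)
    loaded = load_model(path)
    np.testing.assert_array_equal(loaded.stage1.kernels, small_model.stage1.kernels)
    np.testing.assert_array_equal(loaded.stage2.kernels, small_model.stage2.kernels)
    assert loaded.patch == small_model.patch
    assert loaded.activation == small_model.activation
    assert loaded.padding == small_model.padding
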