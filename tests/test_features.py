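import numpy as np
import pytest

from agonalert.audio import AudioClip
from agonalert.features import (
    FeaturizerModel,
    MelParams,
    UnfittedModelError,
    embed,
    embed_many,
    fit_featurizer,
    flatten_logmels,
    log_mel,
    mel_filterbank,
    project_flat,
    stft,
)

SR = 16000
SMALL = MelParams(win_s=0.025, hop_s=0.010, n_fft=512, n_mels=32)


def tone(freq, duration_s=0.5, sr=SR):
    t = np.arange(int(duration_s * sr)) / sr
    return np.sin(2 * np.pi * freq * t)


class TestSTFT:
    def test_tone_argmax_bin(self):
        spec = stft(tone(1000.0), 0.025, 0.010, 512, SR)
        expected_bin = round(1000 / (SR / 512))
        argmax = np.argmax(np.abs(spec), axis=1)
        assert np.all(argmax == expected_bin)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, int(0.1 * SR))
        win_n, hop_n, n_fft = 400, 160, 512
        fast = stft(x, 0.025, 0.010, n_fft, SR)
        window = np.hanning(win_n)
        n_frames = 1 + (len(x) - win_n) // hop_n
        assert fast.shape[0] == n_frames
        k = np.arange(n_fft // 2 + 1)
        n = np.arange(n_fft)
        dft = np.exp(-2j * np.pi * np.outer(k, n) / n_fft)  # O(N^2) oracle
        for i in range(n_frames):
            frame = np.zeros(n_fft)
            frame[:win_n] = x[i * hop_n : i * hop_n + win_n] * window
            np.testing.assert_allclose(fast[i], dft @ frame, atol=1e-9)

    def test_zero_input_zero_magnitudes(self):
        spec = stft(np.zeros(SR), 0.025, 0.010, 512, SR)
        assert np.all(np.abs(spec) == 0.0)

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(ValueError):
            stft(np.zeros(100), 0.025, 0.010, 512, SR)


class TestMelFilterbank:
    def test_rows_positive_with_compact_support(self):
        fb = mel_filterbank(32, 512, SR, 125.0, 7500.0)
        assert fb.shape == (32, 257)
        assert np.all(fb.sum(axis=1) > 0)
        for row in fb:
            support = np.nonzero(row)[0]
            assert np.all(np.diff(support) == 1)  # one contiguous band

    def test_tone_at_band_center_dominates_that_band(self):
        fb = mel_filterbank(32, 512, SR, 125.0, 7500.0)
        freqs = np.arange(257) * SR / 512
        band = 15
        center = freqs[np.argmax(fb[band])]
        lm = log_mel(tone(center), SMALL)
        assert np.argmax(lm.values.mean(axis=0)) == band

    def test_white_noise_adjacent_band_difference_bounded(self):
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            lm = log_mel(rng.normal(0, 0.3, SR), SMALL)
            mean_energy = lm.values.mean(axis=0)
            diffs.append(np.mean(np.abs(np.diff(mean_energy))))
        assert np.mean(diffs) < 1.0

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError):
            mel_filterbank(1, 512, SR, 125.0, 7500.0)

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            mel_filterbank(32, 512, SR, 5000.0, 1000.0)
        with pytest.raises(ValueError):
            mel_filterbank(32, 512, SR, 125.0, 9000.0)


class TestLogMel:
    def test_silent_input_finite(self):
        lm = log_mel(np.zeros(SR), SMALL)
        assert np.all(np.isfinite(lm.values))

    def test_frame_count(self):
        lm = log_mel(np.zeros(40000), SMALL)
        assert lm.values.shape == (1 + (40000 - 400) // 160, 32)


class TestFeaturizer:
    def test_known_low_rank_subspace_recovered(self):
        # data lying in a 3-D subspace + tiny noise: top-3 variance > 99%
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(3, 40))
        X = rng.normal(size=(300, 3)) @ basis + rng.normal(0, 1e-3, (300, 40))
        from sklearn.decomposition import PCA as _PCA

        model = None
        from agonalert.features import fit_featurizer_flat

        model = fit_featurizer_flat(X, n_components=10)
        top3 = model.explained_variance[:3].sum()
        total = X.var(axis=0, ddof=1).sum()
        assert top3 / total > 0.99
        # cross-check the leading eigenvalue against a full eigendecomposition
        C = np.cov(X, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(model.explained_variance[:3], eigvals[:3],
                                   rtol=1e-6)

    def test_explained_variance_non_increasing(self, small_bundle):
        ev = small_bundle.featurizer.explained_variance
        assert np.all(np.diff(ev) <= 1e-9)

    def test_components_orthonormal(self, small_bundle):
        C = small_bundle.featurizer.pca_components
        np.testing.assert_allclose(C @ C.T, np.eye(C.shape[0]), atol=1e-6)

    def test_refit_deterministic_up_to_sign(self, small_corpus):
        a = fit_featurizer(small_corpus[:260], n_components=16, seed=3)
        b = fit_featurizer(small_corpus[:260], n_components=16, seed=3)
        dots = np.abs(np.sum(a.pca_components * b.pca_components, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_too_few_segments_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            fit_featurizer(small_corpus[:10], n_components=256)


class TestEmbed:
    def test_mean_maps_to_zero(self, small_bundle):
        fz = small_bundle.featurizer
        z = project_flat(fz.pca_mean, fz)
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_identical_segments_identical_embeddings(self, small_bundle, small_corpus):
        z1 = embed(small_corpus[0], small_bundle.featurizer)
        z2 = embed(small_corpus[0], small_bundle.featurizer)
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (128,)

    def test_unfitted_model_raises(self, small_corpus):
        with pytest.raises(UnfittedModelError):
            embed(small_corpus[0], FeaturizerModel(MelParams()))

    def test_more_components_reconstruct_better(self, small_corpus):
        flats = flatten_logmels(small_corpus[:201])
        from agonalert.features import fit_featurizer_flat

        held = flats[200]
        big = fit_featurizer_flat(flats[:200], n_components=128)
        small = fit_featurizer_flat(flats[:200], n_components=16)

        def recon_err(model):
            z = project_flat(held, model)[0]
            back = model.pca_mean + z @ model.pca_components
            return np.sum((back - held) ** 2)

        assert recon_err(big) <= recon_err(small)

    def test_projection_is_contraction(self, small_corpus):
        # reconstruction MSE can never exceed the centered input energy
        flats = flatten_logmels(small_corpus[:150])
        from agonalert.features import fit_featurizer_flat

        model = fit_featurizer_flat(flats[:128], n_components=32)
        X = flats[128:]
        Z = project_flat(X, model)
        back = model.pca_mean + Z @ model.pca_components
        mse = np.mean((back - X) ** 2)
        centered = np.mean((X - model.pca_mean) ** 2)
        assert mse <= centered + 1e-12

    def test_classes_linearly_separable_in_embedding_space(self, small_bundle,
                                                           small_corpus):
        from sklearn.svm import LinearSVC

        Z = embed_many(small_corpus, small_bundle.featurizer)
        y = np.array([c.meta["label"] for c in small_corpus])
        clf = LinearSVC(C=10.0, max_iter=20000).fit(Z, y)
        assert clf.score(Z, y) > 0.97


class TestPersistence:
    def test_save_load_round_trip(self, small_bundle, small_corpus, tmp_path):
        path = tmp_path / "featurizer.npz"
        small_bundle.featurizer.save(path)
        back = FeaturizerModel.load(path)
        z1 = embed(small_corpus[0], small_bundle.featurizer)
        z2 = embed(small_corpus[0], back)
        np.testing.assert_allclose(z1, z2, atol=1e-12)
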