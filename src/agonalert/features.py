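"""Segment featurization: STFT -> log-mel spectrogram -> PCA embedding.

Each 2.5 s segment at 16 kHz is transformed into a 256-dimensional embedding:
a Hann-windowed short-time Fourier transform (25 ms window, 10 ms hop), a
64-band triangular mel filterbank over the power spectrum with logarithmic
compression, then projection of the flattened log-mel matrix onto principal
components fitted on training segments only.  The featurizer is trainable
end-to-end from data, with every spectral parameter exposed in
:class:`MelParams`.

The mel filterbank uses the standard mel scale
``mel(f) = 2595 log10(1 + f / 700)`` with triangular filters between equally
mel-spaced edge frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .audio import AudioClip


@dataclass(frozen=True)
class MelParams:
    sample_rate_hz: int = 16000
    win_s: float = 0.025
    hop_s: float = 0.010
    n_fft: int = 512
    n_mels: int = 64
    fmin_hz: float = 125.0
    fmax_hz: float = 7500.0
    log_offset: float = 0.01


@dataclass(frozen=True)
class LogMelSpectrogram:
    values: np.ndarray  # frames x n_mels log-energies, finite
    frame_hop_s: float
    n_mels: int
    fmin_hz: float
    fmax_hz: float


class UnfittedModelError(RuntimeError):
    """Raised when embedding is requested from an unfitted featurizer."""


def stft(samples: np.ndarray, win_s: float, hop_s: float, n_fft: int,
         sample_rate_hz: int = 16000) -> np.ndarray:
    """Hann-windowed complex STFT, frames x (n_fft // 2 + 1).

    No padding or centering: frame count is ``1 + floor((N - win) / hop)``
    and frame ``i`` covers samples ``[i * hop, i * hop + win)``.
    """
    x = np.asarray(samples, dtype=np.float64)
    win_n = round(win_s * sample_rate_hz)
    hop_n = round(hop_s * sample_rate_hz)
    if win_n > len(x):
        raise ValueError(
            f"window of {win_n} samples exceeds segment of {len(x)} samples"
        )
    if n_fft < win_n:
        raise ValueError("n_fft must be >= the window length")
    n_frames = 1 + (len(x) - win_n) // hop_n
    idx = np.arange(win_n)[None, :] + hop_n * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(win_n)[None, :]
    return np.fft.rfft(frames, n=n_fft, axis=1)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate_hz: int,
                   fmin_hz: float, fmax_hz: float) -> np.ndarray:
    """Triangular mel filterbank, n_mels x (n_fft // 2 + 1)."""
    if n_mels < 2:
        raise ValueError("n_mels must be >= 2")
    nyquist = sample_rate_hz / 2
    if not (0 <= fmin_hz < fmax_hz <= nyquist):
        raise ValueError("need 0 <= fmin < fmax <= Nyquist")

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2))
    fft_freqs = np.arange(n_fft // 2 + 1) * sample_rate_hz / n_fft
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, center, hi = edges_hz[m : m + 3]
        up = (fft_freqs - lo) / (center - lo)
        down = (hi - fft_freqs) / (hi - center)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def log_mel(samples: np.ndarray, params: MelParams) -> LogMelSpectrogram:
    """Log-mel spectrogram of a segment: mel-pooled STFT power, log-compressed.

    The additive ``log_offset`` keeps every entry finite on silent input.
    """
    spec = stft(samples, params.win_s, params.hop_s, params.n_fft,
                params.sample_rate_hz)
    power = np.abs(spec) ** 2
    fb = mel_filterbank(params.n_mels, params.n_fft, params.sample_rate_hz,
                        params.fmin_hz, params.fmax_hz)
    values = np.log(power @ fb.T + params.log_offset)
    return LogMelSpectrogram(values, params.hop_s, params.n_mels,
                             params.fmin_hz, params.fmax_hz)


@dataclass
class FeaturizerModel:
    """Mel parameters plus a fitted PCA basis mapping flattened log-mel
    matrices to the embedding space (rows of ``pca_components`` orthonormal,
    sorted by decreasing explained variance)."""

    mel_params: MelParams
    pca_mean: np.ndarray | None = None
    pca_components: np.ndarray | None = None  # n_components x d
    explained_variance: np.ndarray | None = None
    whiten: bool = False

    @property
    def fitted(self) -> bool:
        return self.pca_components is not None

    @property
    def n_components(self) -> int:
        if not self.fitted:
            raise UnfittedModelError("featurizer has not been fitted")
        return self.pca_components.shape[0]

    def save(self, path) -> None:
        if not self.fitted:
            raise UnfittedModelError("cannot persist an unfitted featurizer")
        mp = self.mel_params
        np.savez(
            path,
            pca_mean=self.pca_mean,
            pca_components=self.pca_components,
            explained_variance=self.explained_variance,
            whiten=np.array(self.whiten),
            mel=np.array([mp.sample_rate_hz, mp.win_s, mp.hop_s, mp.n_fft,
                          mp.n_mels, mp.fmin_hz, mp.fmax_hz, mp.log_offset]),
        )

    @staticmethod
    def load(path) -> "FeaturizerModel":
        with np.load(path) as z:
            m = z["mel"]
            params = MelParams(int(m[0]), float(m[1]), float(m[2]), int(m[3]),
                               int(m[4]), float(m[5]), float(m[6]), float(m[7]))
            return FeaturizerModel(
                params,
                pca_mean=z["pca_mean"],
                pca_components=z["pca_components"],
                explained_variance=z["explained_variance"],
                whiten=bool(z["whiten"]),
            )


def _flat_logmel(clip_or_samples, params: MelParams) -> np.ndarray:
    samples = (clip_or_samples.samples
               if isinstance(clip_or_samples, AudioClip) else clip_or_samples)
    return log_mel(samples, params).values.ravel()


def flatten_logmels(segments, mel_params: MelParams | None = None) -> np.ndarray:
    """Flattened log-mel matrix per segment, stacked row-wise.

    The log-mel transform is deterministic preprocessing, so it can be
    computed once per corpus and reused across cross-validation folds.
    """
    params = mel_params or MelParams()
    return np.stack([_flat_logmel(s, params) for s in segments])


def fit_featurizer_flat(
    X_flat: np.ndarray,
    n_components: int = 256,
    mel_params: MelParams | None = None,
    whiten: bool = False,
    seed: int = 0,
) -> FeaturizerModel:
    """Fit the PCA basis on precomputed flattened log-mel rows."""
    params = mel_params or MelParams()
    if X_flat.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} training segments, got {X_flat.shape[0]}"
        )
    pca = PCA(n_components=n_components, whiten=whiten,
              svd_solver="randomized", random_state=seed)
    pca.fit(X_flat)
    return FeaturizerModel(
        params,
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        explained_variance=pca.explained_variance_,
        whiten=whiten,
    )


def fit_featurizer(
    training_segments,
    n_components: int = 256,
    mel_params: MelParams | None = None,
    whiten: bool = False,
    seed: int = 0,
) -> FeaturizerModel:
    """Fit the PCA basis on flattened log-mel matrices of training segments.

    Must be called with training-split segments only — fitting on validation
    segments would leak information across cross-validation folds.
    """
    params = mel_params or MelParams()
    segments = list(training_segments)
    if len(segments) < n_components:
        raise ValueError(
            f"need at least {n_components} training segments, got {len(segments)}"
        )
    return fit_featurizer_flat(
        flatten_logmels(segments, params), n_components, params, whiten, seed
    )


def embed(segment, model: FeaturizerModel) -> np.ndarray:
    """Project one segment onto the fitted PCA basis (the embedding)."""
    if not model.fitted:
        raise UnfittedModelError("featurizer has not been fitted")
    flat = _flat_logmel(segment, model.mel_params)
    if flat.shape[0] != model.pca_mean.shape[0]:
        raise ValueError(
            f"segment produces {flat.shape[0]} log-mel values, model expects "
            f"{model.pca_mean.shape[0]} (check segment length and sample rate)"
        )
    z = (flat - model.pca_mean) @ model.pca_components.T
    if model.whiten:
        z = z / np.sqrt(model.explained_variance)
    return z


def project_flat(X_flat: np.ndarray, model: FeaturizerModel) -> np.ndarray:
    """Project precomputed flattened log-mel rows onto the fitted basis."""
    if not model.fitted:
        raise UnfittedModelError("featurizer has not been fitted")
    Z = (np.atleast_2d(X_flat) - model.pca_mean) @ model.pca_components.T
    if model.whiten:
        Z = Z / np.sqrt(model.explained_variance)
    return Z


def embed_many(segments, model: FeaturizerModel) -> np.ndarray:
    """Vectorized :func:`embed` over an iterable of segments."""
    if not model.fitted:
        raise UnfittedModelError("featurizer has not been fitted")
    return project_flat(flatten_logmels(segments, model.mel_params), model)
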