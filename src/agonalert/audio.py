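"""Audio I/O, normalization, resampling and fixed-length segmentation.

This is the front of the detection pipeline: every downstream stage (feature
extraction, classification, temporal filtering) consumes the non-overlapping
2.5 s segments produced here.  Audio is mono throughout; amplitudes live in
[-1, 1] after :func:`normalize`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

#: sample rates the pipeline is exercised at: telephony (8 kHz), device
#: capture (16 kHz) and consumer recording (44.1 kHz)
SUPPORTED_RATES = (8000, 16000, 44100)

DEFAULT_SEGMENT_S = 2.5


class AudioFormatError(ValueError):
    """Raised for unreadable, multi-channel or otherwise unsupported audio."""


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform with its sample rate and free-form condition tags.

    ``meta`` carries provenance used by the evaluation harness and the grouped
    cross-validation split: ``source_id``, ``label``, ``distance_m``,
    ``interference_kind``, ``device`` and the like.
    """

    samples: np.ndarray
    sample_rate_hz: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioFormatError(f"mono audio required, got shape {samples.shape}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def with_meta(self, **tags) -> "AudioClip":
        return replace(self, meta={**self.meta, **tags})


@dataclass(frozen=True)
class SegmentStream:
    """Ordered fixed-length segments with absolute start times (seconds).

    Start times increase by ``hop_s``; every segment holds exactly
    ``round(segment_len_s * sample_rate)`` samples.  Intervals are half-open,
    ``[start, start + segment_len_s)``.
    """

    segments: list  # of (start_s, AudioClip)
    segment_len_s: float
    hop_s: float

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def start_times(self) -> np.ndarray:
        return np.array([s for s, _ in self.segments])


def read_wav(path) -> AudioClip:
    """Read a mono PCM16 or float32 WAV file into an :class:`AudioClip`.

    Integer PCM is rescaled to [-1, 1] (PCM16 by 2**15); float data is taken
    as-is.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on junk input
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.ndim != 1:
        raise AudioFormatError(
            f"{path!r} has {data.shape[1]} channels; only mono is supported"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV encoding {data.dtype}")
    return AudioClip(samples, int(rate))


def write_wav(clip: AudioClip, path, dtype: str = "int16") -> None:
    """Write a clip as mono PCM16 (default) or float32 WAV.

    A PCM16 write→read round trip reproduces samples to within one
    quantization step (2**-15).
    """
    x = np.clip(clip.samples, -1.0, 1.0)
    if dtype == "int16":
        quantized = np.round(x * 32767.0).astype(np.int16)
        wavfile.write(path, clip.sample_rate_hz, quantized)
    elif dtype == "float32":
        wavfile.write(path, clip.sample_rate_hz, x.astype(np.float32))
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")


def normalize(clip: AudioClip) -> AudioClip:
    """Peak-normalize to [-1, 1]; silent input is returned unchanged."""
    if len(clip.samples) == 0:
        raise ValueError("cannot normalize an empty clip")
    peak = np.max(np.abs(clip.samples))
    if peak == 0.0:
        return clip
    return replace(clip, samples=clip.samples / peak)


def resample(clip: AudioClip, target_hz: int) -> AudioClip:
    """Band-limited polyphase resampling to ``target_hz``.

    Duration is preserved to within one sample period of the coarser rate.
    Resampling to the clip's own rate is the identity.
    """
    if target_hz <= 0:
        raise ValueError(f"target rate must be positive, got {target_hz}")
    if target_hz == clip.sample_rate_hz:
        return clip
    ratio = Fraction(target_hz, clip.sample_rate_hz)
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator)
    return AudioClip(out, target_hz, dict(clip.meta))


def segment(
    clip: AudioClip,
    segment_len_s: float = DEFAULT_SEGMENT_S,
    hop_s: float | None = None,
) -> SegmentStream:
    """Cut a clip into fixed-length segments.

    The default hop equals the segment length (non-overlapping windows).  A
    trailing remainder shorter than ``segment_len_s`` is dropped, so the count
    is ``floor((duration - segment_len) / hop) + 1``.  A clip shorter than one
    segment yields an empty stream with a warning.
    """
    if hop_s is None:
        hop_s = segment_len_s
    if segment_len_s <= 0 or hop_s <= 0:
        raise ValueError("segment_len_s and hop_s must be positive")
    sr = clip.sample_rate_hz
    seg_n = round(segment_len_s * sr)
    hop_n = round(hop_s * sr)
    n = len(clip.samples)
    if n < seg_n:
        warnings.warn(
            f"clip of {clip.duration_s:.3f} s is shorter than one "
            f"{segment_len_s} s segment; returning an empty stream",
            stacklevel=2,
        )
        log.warning("segment(): clip shorter than one segment, empty stream")
        return SegmentStream([], segment_len_s, hop_s)
    count = (n - seg_n) // hop_n + 1
    segments = []
    for i in range(count):
        start = i * hop_n
        piece = AudioClip(clip.samples[start : start + seg_n], sr, dict(clip.meta))
        segments.append((start / sr, piece))
    return SegmentStream(segments, segment_len_s, hop_s)
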