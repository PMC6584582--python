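"""FMCW chirp synchronization for over-the-air benchmark recordings.

When test clips are played over the air and re-recorded, each clip is
prepended with a linear frequency-modulated (FMCW) chirp.  The chirp's sharp
autocorrelation lets the harness cross-correlate the recording with the
template, recover the exact onset timestamp of every played clip, and cut the
clips back out for classification.

The default template sweeps 500 -> 4000 Hz over 100 ms with Hann-tapered
edges; the band sits inside telephony bandwidth so 8 kHz material can be
synchronized too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio import AudioClip


@dataclass(frozen=True)
class ChirpTemplate:
    f_start_hz: float
    f_end_hz: float
    duration_s: float
    sample_rate_hz: int
    waveform: np.ndarray

    def autocorrelation_sharpness(self) -> float:
        """Main-lobe peak over largest sidelobe of the autocorrelation.

        The main lobe is taken as +/- one sweep-bandwidth-inverse around zero
        lag; the template contract requires a ratio >= 5.
        """
        w = self.waveform
        ac = np.abs(signal.correlate(w, w, mode="full"))
        center = len(w) - 1
        lobe_halfwidth = max(
            2, int(round(self.sample_rate_hz / (self.f_end_hz - self.f_start_hz))) * 2
        )
        main = ac[center]
        outside = np.concatenate(
            [ac[: center - lobe_halfwidth], ac[center + lobe_halfwidth + 1 :]]
        )
        return float(main / np.max(outside))


def make_chirp(
    f_start_hz: float = 500.0,
    f_end_hz: float = 4000.0,
    duration_s: float = 0.1,
    sample_rate_hz: int = 16000,
    taper_fraction: float = 0.1,
) -> ChirpTemplate:
    """Linear instantaneous-frequency sweep, unit peak, Hann-tapered edges."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 0 < f_start_hz < f_end_hz:
        raise ValueError("need 0 < f_start < f_end")
    if f_end_hz > sample_rate_hz / 2:
        raise ValueError(
            f"f_end {f_end_hz} Hz exceeds Nyquist {sample_rate_hz / 2} Hz"
        )
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    w = signal.chirp(t, f0=f_start_hz, f1=f_end_hz, t1=duration_s, method="linear")
    w *= signal.windows.tukey(n, alpha=2 * taper_fraction)
    w /= np.max(np.abs(w))
    return ChirpTemplate(f_start_hz, f_end_hz, duration_s, sample_rate_hz, w)


def locate(
    recording: AudioClip,
    template: ChirpTemplate,
    min_separation_s: float | None = None,
    detection_threshold: float = 0.5,
) -> list[float]:
    """Find chirp onsets by normalized cross-correlation peak picking.

    The correlation is normalized by the template energy and the local signal
    energy under the template window, so the threshold is level-independent
    (a perfect noiseless match scores 1).  Peaks above ``detection_threshold``
    are picked greedily (highest first) subject to ``min_separation_s``
    spacing, and returned sorted ascending.
    """
    if recording.sample_rate_hz != template.sample_rate_hz:
        raise ValueError("recording and template sample rates differ")
    if min_separation_s is None:
        min_separation_s = template.duration_s + 2.5
    x = recording.samples
    w = template.waveform
    n, m = len(x), len(w)
    if n < m:
        return []
    num = signal.fftconvolve(x, w[::-1], mode="valid")  # correlation at each lag
    energy = signal.fftconvolve(x**2, np.ones(m), mode="valid")
    denom = np.sqrt(np.maximum(energy, 0.0) * float(w @ w)) + 1e-12
    ncc = num / denom
    sep = int(round(min_separation_s * template.sample_rate_hz))
    candidates = np.argsort(ncc)[::-1]
    picked: list[int] = []
    for i in candidates:
        if ncc[i] < detection_threshold:
            break
        if all(abs(i - p) >= sep for p in picked):
            picked.append(int(i))
    return sorted(p / template.sample_rate_hz for p in picked)


def extract_clips(
    recording: AudioClip,
    onsets,
    chirp_duration_s: float,
    clip_len_s: float = 2.5,
) -> list[AudioClip]:
    """Cut out the clip that follows each located chirp.

    Clip i spans ``[onset_i + chirp_duration, onset_i + chirp_duration +
    clip_len)``; a clip extending past the recording end is dropped with a
    warning.
    """
    sr = recording.sample_rate_hz
    clip_n = int(round(clip_len_s * sr))
    out = []
    for onset in onsets:
        i0 = int(round((onset + chirp_duration_s) * sr))
        if i0 + clip_n > len(recording.samples):
            warnings.warn(
                f"clip at onset {onset:.3f} s extends past recording end; dropped",
                stacklevel=2,
            )
            continue
        out.append(
            AudioClip(
                recording.samples[i0 : i0 + clip_n],
                sr,
                {**recording.meta, "chirp_onset_s": float(onset)},
            )
        )
    return out
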