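"""Seeded synthetic acoustic scenes for training and benchmarking.

Real agonal-breathing audio (9-1-1 call extracts) and polysomnography sleep
audio are not publicly distributable, so this module generates labeled
surrogate scenes with the same statistical structure: sparse agonal gasp
trains at 3-6 events/min against negative-class sleep sounds (snoring, normal
breathing, hypopnea, central and obstructive apnea) plus bedroom interference,
1/r distance attenuation and an additive Gaussian noise floor.

Acoustic templates are engineering surrogates, not physiological models.  A
gasp is rendered as a broadband noise burst with a sharp (~50 ms) attack, a
slow (~400 ms) decay and a low-frequency 80-150 Hz harmonic component --
"gasping" as a short, effortful inhalation.  All randomness flows from one
integer seed per scene through counter-based ``numpy.random.SeedSequence``
splits, so identical specs render bit-identical waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .audio import AudioClip

NEGATIVE_KINDS = ("snore", "normal_breath", "hypopnea", "central_apnea", "obstructive_apnea")
INTERFERENCE_KINDS = ("speech_like", "traffic_like", "white", "soundscape")
EVENT_KINDS = ("agonal_gasp", "snore_cycle", "breath_cycle", "apnea_gap")

# seed-derivation roles: keeps the noise floor / interference / event draws
# independent so single-event scenes mix linearly with the noise-only scene
_ROLE_NOISE = 0
_ROLE_INTERFERENCE = 1
_ROLE_EVENT = 2


def _child_rng(seed: int, role: int, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(role, index))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SceneEvent:
    onset_s: float
    kind: str  # one of EVENT_KINDS
    duration_s: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene; rendering is a pure function of it."""

    duration_s: float
    sample_rate_hz: int = 16000
    event_track: tuple = ()  # of SceneEvent
    interference: tuple = ()  # of (kind, level_dBFS)
    distance_m: float = 1.0
    noise_floor_dbfs: float = -60.0
    seed: int = 0

    def __post_init__(self):
        events = tuple(
            e if isinstance(e, SceneEvent) else SceneEvent(*e) for e in self.event_track
        )
        object.__setattr__(self, "event_track", events)
        if self.duration_s <= 0:
            raise ValueError("scene duration must be positive")
        if self.distance_m < 0.1:
            raise ValueError("distance_m must be >= 0.1 m")
        last = -np.inf
        for ev in events:
            if ev.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {ev.kind!r}")
            if ev.onset_s <= last:
                raise ValueError("event onsets must be strictly increasing")
            if ev.onset_s + ev.duration_s > self.duration_s:
                raise ValueError("event extends past scene end")
            last = ev.onset_s
        gasps = [e for e in events if e.kind == "agonal_gasp"]
        for a, b in zip(gasps, gasps[1:]):
            if b.onset_s < a.onset_s + a.duration_s:
                raise ValueError("agonal gasps must not overlap")
        for kind, _level in self.interference:
            if kind not in INTERFERENCE_KINDS:
                raise ValueError(f"unknown interference kind {kind!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-segment labels plus the agonal gasp onset list for one scene."""

    segment_labels: np.ndarray  # uint8, one per fixed-length segment
    event_times: tuple  # onset_s of every agonal gasp
    segment_len_s: float = 2.5

    @staticmethod
    def from_events(
        event_track, duration_s: float, segment_len_s: float = 2.5
    ) -> "GroundTruth":
        """Label a segment positive iff it overlaps at least half of some
        agonal gasp's support."""
        n_seg = int(duration_s // segment_len_s)
        labels = np.zeros(n_seg, dtype=np.uint8)
        gasps = [e for e in event_track if e.kind == "agonal_gasp"]
        for i in range(n_seg):
            lo, hi = i * segment_len_s, (i + 1) * segment_len_s
            for ev in gasps:
                overlap = min(hi, ev.onset_s + ev.duration_s) - max(lo, ev.onset_s)
                if ev.duration_s > 0 and overlap >= 0.5 * ev.duration_s:
                    labels[i] = 1
                    break
        return GroundTruth(labels, tuple(e.onset_s for e in gasps), segment_len_s)


def _envelope(n: int, sr: int, attack_s: float, decay_tau_s: float) -> np.ndarray:
    """Sharp-attack / exponential-decay amplitude envelope, peak 1."""
    t = np.arange(n) / sr
    attack_n = max(1, int(round(attack_s * sr)))
    env = np.exp(-(t - attack_s) / decay_tau_s)
    env[:attack_n] = np.linspace(0.0, 1.0, attack_n, endpoint=False) ** 2
    return np.clip(env, 0.0, 1.0)


def make_agonal_gasp(duration_s: float, sample_rate_hz: int, seed: int) -> AudioClip:
    """Render one surrogate agonal gasp: shaped broadband noise plus a
    low-frequency harmonic, peak amplitude 1.

    The attack is ~50 ms and the decay time constant ~400 ms (compressed for
    short gasps), so the attack half of the clip carries more energy than the
    decay half.
    """
    if not (0.2 <= duration_s <= 2.0):
        raise ValueError("gasp duration must be in [0.2, 2.0] s")
    rng = np.random.default_rng(seed)
    sr = sample_rate_hz
    n = int(round(duration_s * sr))
    noise = rng.standard_normal(n)
    # breathy coloration: band-pass the noise into the 200-3000 Hz region
    sos = signal.butter(4, [200, min(3000, 0.45 * sr)], "bandpass", fs=sr, output="sos")
    noise = signal.sosfilt(sos, noise)
    f0 = rng.uniform(80.0, 150.0)
    t = np.arange(n) / sr
    harmonic = np.sin(2 * np.pi * f0 * t) + 0.4 * np.sin(2 * np.pi * 2 * f0 * t)
    attack = min(0.05, 0.25 * duration_s)
    tau = min(0.4, duration_s / 3.0)
    env = _envelope(n, sr, attack, tau)
    x = env * (noise / (np.max(np.abs(noise)) + 1e-12) + 0.6 * harmonic)
    x /= np.max(np.abs(x))
    return AudioClip(x, sr, {"kind": "agonal_gasp", "f0_hz": f0})


def _breath_cycle(
    rng: np.random.Generator, sr: int, cycle_s: float, kind: str
) -> np.ndarray:
    """One respiratory cycle: inhale burst, quiet exhale, pause."""
    n = int(round(cycle_s * sr))
    out = np.zeros(n)
    inhale_s = min(1.2, 0.35 * cycle_s)
    n_in = int(inhale_s * sr)
    t = np.arange(n_in) / sr
    ramp = np.hanning(2 * n_in)[:n_in] if n_in else np.zeros(0)
    if kind == "snore":
        # palatal flutter: low-frequency buzz amplitude-modulating filtered noise
        f_snore = rng.uniform(60.0, 120.0)
        buzz = signal.square(2 * np.pi * f_snore * t) * 0.5 + 0.5
        noise = rng.standard_normal(n_in)
        sos = signal.butter(4, [80, 800], "bandpass", fs=sr, output="sos")
        cyc = buzz * signal.sosfilt(sos, noise)
    else:  # soft turbulent airflow
        noise = rng.standard_normal(n_in)
        sos = signal.butter(4, [300, 2000], "bandpass", fs=sr, output="sos")
        cyc = signal.sosfilt(sos, noise)
    if n_in:
        cyc = cyc / (np.max(np.abs(cyc)) + 1e-12) * np.hanning(n_in)
        out[:n_in] = cyc
        # faint exhale
        n_ex = min(n - n_in, n_in)
        exhale = rng.standard_normal(n_ex) * 0.1
        sos = signal.butter(2, 1000, "lowpass", fs=sr, output="sos")
        out[n_in : n_in + n_ex] = signal.sosfilt(sos, exhale) * np.hanning(n_ex)
    return out


def make_negative_track(
    kind: str,
    duration_s: float,
    rate_per_min: float = 15.0,
    sample_rate_hz: int = 16000,
    seed: int = 0,
) -> AudioClip:
    """Render a negative-class sleep track of the given kind.

    ``snore`` and ``normal_breath`` are periodic cycles at ``rate_per_min``;
    ``hypopnea`` is the same breathing with amplitude reduced to 30%;
    ``central_apnea`` inserts a >= 10 s silent gap with no respiratory effort;
    ``obstructive_apnea`` inserts a gap containing residual struggle bursts.
    """
    if kind not in NEGATIVE_KINDS:
        raise ValueError(f"unknown negative-track kind {kind!r}")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if kind in ("snore", "normal_breath", "hypopnea") and not (6 <= rate_per_min <= 30):
        raise ValueError("rate_per_min must be in [6, 30] for cyclic tracks")
    rng = np.random.default_rng(seed)
    sr = sample_rate_hz
    n = int(round(duration_s * sr))
    out = np.zeros(n)
    cycle_s = 60.0 / rate_per_min
    base_kind = "snore" if kind == "snore" else "breath"
    gap_lo = gap_hi = None
    if kind in ("central_apnea", "obstructive_apnea"):
        gap_s = min(max(10.0, 0.3 * duration_s), max(10.0, duration_s - 2 * cycle_s))
        gap_s = min(gap_s, duration_s)
        start_max = max(0.0, duration_s - gap_s)
        gap_start = rng.uniform(0.25, 0.75) * start_max
        gap_lo, gap_hi = gap_start, gap_start + gap_s
    onset = 0.0
    while onset + cycle_s <= duration_s + 1e-9:
        if gap_lo is not None and onset + cycle_s > gap_lo and onset < gap_hi:
            onset += cycle_s
            continue
        cyc = _breath_cycle(rng, sr, cycle_s, base_kind)
        if kind == "hypopnea":
            cyc = cyc * 0.3
        i0 = int(round(onset * sr))
        out[i0 : i0 + len(cyc)] += cyc[: max(0, n - i0)]
        onset += cycle_s
    if kind == "obstructive_apnea" and gap_lo is not None:
        # continued effort against a closed airway: brief weak transients
        t0 = gap_lo + 1.0
        while t0 + 0.2 < gap_hi - 0.5:
            burst_n = int(0.1 * sr)
            burst = rng.standard_normal(burst_n) * np.hanning(burst_n) * 0.08
            i0 = int(round(t0 * sr))
            out[i0 : i0 + burst_n] += burst[: max(0, n - i0)]
            t0 += rng.uniform(1.5, 3.0)
    peak = np.max(np.abs(out))
    if peak > 0:
        out /= peak
    return AudioClip(out, sr, {"kind": kind, "rate_per_min": rate_per_min})


def make_interference(
    kind: str, duration_s: float, sample_rate_hz: int = 16000, seed: int = 0
) -> AudioClip:
    """Render an interference surrogate, unit peak amplitude.

    ``speech_like``: formant-band noise with a syllabic 3-7 Hz amplitude
    modulation; ``traffic_like``: low-pass rumble (< ~250 Hz) with occasional
    transients; ``white``: flat-spectrum noise; ``soundscape``: narrowband
    filtered noise resembling a sleep-soundscape track.
    """
    if kind not in INTERFERENCE_KINDS:
        raise ValueError(f"unknown interference kind {kind!r}")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    sr = sample_rate_hz
    n = int(round(duration_s * sr))
    t = np.arange(n) / sr
    noise = rng.standard_normal(n)
    if kind == "white":
        x = noise
    elif kind == "speech_like":
        sos = signal.butter(4, [300, min(3000, 0.45 * sr)], "bandpass", fs=sr, output="sos")
        x = signal.sosfilt(sos, noise)
        syllabic = rng.uniform(3.0, 7.0)
        x *= 0.5 * (1 + np.sin(2 * np.pi * syllabic * t + rng.uniform(0, 2 * np.pi)))
    elif kind == "traffic_like":
        sos = signal.butter(6, 200, "lowpass", fs=sr, output="sos")
        x = signal.sosfilt(sos, noise)
        for _ in range(max(1, int(duration_s / 5))):  # passing vehicles
            c = rng.uniform(0, max(duration_s - 1, 0.1))
            x *= 1 + 0.5 * np.exp(-0.5 * ((t - c) / 0.5) ** 2)
    else:  # soundscape
        center = rng.uniform(400, 900)
        sos = signal.butter(4, [center * 0.8, center * 1.2], "bandpass", fs=sr, output="sos")
        x = signal.sosfilt(sos, noise)
    x = x / (np.max(np.abs(x)) + 1e-12)
    return AudioClip(x, sr, {"kind": kind})


def _render_event(ev: SceneEvent, sr: int, seed: int, index: int) -> np.ndarray:
    rng_seed = int(_child_rng(seed, _ROLE_EVENT, index).integers(0, 2**31 - 1))
    if ev.kind == "agonal_gasp":
        clip = make_agonal_gasp(ev.duration_s, sr, rng_seed)
        return clip.samples * ev.amplitude
    if ev.kind == "apnea_gap":
        return np.zeros(int(round(ev.duration_s * sr)))
    base = "snore" if ev.kind == "snore_cycle" else "breath"
    rng = np.random.default_rng(rng_seed)
    return _breath_cycle(rng, sr, ev.duration_s, base) * ev.amplitude


def render_scene(spec: SceneSpec) -> tuple[AudioClip, GroundTruth]:
    """Render a scene spec to a waveform plus its ground truth.

    Events are placed at their onsets and attenuated by ``1 / distance_m``
    relative to 1 m; interference tracks are added at their stated RMS dBFS
    level and the Gaussian noise floor at ``noise_floor_dbfs``.  If the mix
    would clip, the whole waveform is scaled down (never clipped), keeping
    mixing linear.
    """
    sr = spec.sample_rate_hz
    n = int(round(spec.duration_s * sr))
    mix = np.zeros(n)
    for i, ev in enumerate(spec.event_track):
        rendered = _render_event(ev, sr, spec.seed, i)
        i0 = int(round(ev.onset_s * sr))
        take = min(len(rendered), n - i0)
        mix[i0 : i0 + take] += rendered[:take] / spec.distance_m
    for j, (kind, level_db) in enumerate(spec.interference):
        seed_j = int(_child_rng(spec.seed, _ROLE_INTERFERENCE, j).integers(0, 2**31 - 1))
        track = make_interference(kind, spec.duration_s, sr, seed_j).samples[:n]
        rms = np.sqrt(np.mean(track**2))
        target = 10.0 ** (level_db / 20.0)
        if rms > 0 and np.isfinite(target):
            mix += track * (target / rms)
    if np.isfinite(spec.noise_floor_dbfs):
        rng = _child_rng(spec.seed, _ROLE_NOISE)
        mix += rng.standard_normal(n) * 10.0 ** (spec.noise_floor_dbfs / 20.0)
    peak = np.max(np.abs(mix)) if n else 0.0
    if peak > 1.0:
        mix /= peak
    clip = AudioClip(
        mix,
        sr,
        {
            "distance_m": spec.distance_m,
            "interference_kind": ",".join(k for k, _ in spec.interference) or None,
            "seed": spec.seed,
        },
    )
    truth = GroundTruth.from_events(spec.event_track, spec.duration_s)
    return clip, truth


def gasp_train_spec(
    duration_s: float,
    gap_s: float = 12.0,
    gasp_duration_s: float = 0.8,
    sample_rate_hz: int = 16000,
    seed: int = 0,
    **scene_kwargs,
) -> SceneSpec:
    """Convenience: a scene whose agonal gasps recur every ``gap_s`` seconds,
    the 3-6 breaths/min physiologic pattern the alarm filter targets."""
    events = []
    onset = 0.0
    while onset + gasp_duration_s <= duration_s:
        events.append(SceneEvent(onset, "agonal_gasp", gasp_duration_s))
        onset += gap_s
    return SceneSpec(
        duration_s,
        sample_rate_hz,
        tuple(events),
        seed=seed,
        **scene_kwargs,
    )


def build_clip_corpus(
    n_sources_per_class: int = 100,
    sample_rate_hz: int = 16000,
    clip_len_s: float = 2.5,
    distances_m: tuple = (1.0, 3.0, 6.0),
    interference_levels_dbfs: tuple = (None, -25.0),
    seed: int = 0,
) -> list[AudioClip]:
    """Build the labeled 2.5 s clip corpus used for cross-validation.

    Mirrors the structure of the training data the detector is meant for:
    each positive source is one agonal gasp cut from its onset; each negative
    source is a slice of a sleep track (the five negative kinds cycled) or an
    interference-only clip.  Every source is rendered under several recording
    conditions (distance x interference), all variants sharing the source's
    ``source_id`` so grouped cross-validation can keep them on one side of
    the split.
    """
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    neg_cycle = NEGATIVE_KINDS + INTERFERENCE_KINDS
    for label in (1, 0):
        for s in range(n_sources_per_class):
            source_id = f"{'pos' if label else 'neg'}-{s:04d}"
            src_seed = int(rng.integers(0, 2**31 - 1))
            if label:
                src_rng = np.random.default_rng(src_seed)
                gasp_dur = float(src_rng.uniform(0.4, 1.2))
            else:
                kind = neg_cycle[s % len(neg_cycle)]
            variant = 0
            for dist in distances_m:
                for level in interference_levels_dbfs:
                    interference = ()
                    if level is not None:
                        ikind = INTERFERENCE_KINDS[variant % len(INTERFERENCE_KINDS)]
                        interference = ((ikind, level),)
                    if label:
                        # gasp onset jittered per variant: streamed segments
                        # are not aligned to gasp starts
                        onset = float(src_rng.uniform(0.0, clip_len_s - gasp_dur))
                        events = (SceneEvent(onset, "agonal_gasp", gasp_dur),)
                        spec = SceneSpec(
                            clip_len_s,
                            sample_rate_hz,
                            events,
                            interference,
                            distance_m=dist,
                            noise_floor_dbfs=-50.0,
                            seed=src_seed,
                        )
                        clip, _ = render_scene(spec)
                    else:
                        if kind in NEGATIVE_KINDS:
                            track = make_negative_track(
                                kind, clip_len_s * 4, 15.0, sample_rate_hz, src_seed
                            )
                        else:
                            track = make_interference(
                                kind, clip_len_s * 4, sample_rate_hz, src_seed
                            )
                        off = int(variant % 4 * clip_len_s * sample_rate_hz)
                        piece = track.samples[off : off + int(clip_len_s * sample_rate_hz)]
                        noise_rng = np.random.default_rng(src_seed + 7 * variant + 1)
                        piece = piece / dist + noise_rng.standard_normal(len(piece)) * 10 ** (
                            -50.0 / 20.0
                        )
                        if level is not None:
                            ikind = INTERFERENCE_KINDS[variant % len(INTERFERENCE_KINDS)]
                            itrack = make_interference(
                                ikind, clip_len_s, sample_rate_hz, src_seed + 13
                            ).samples
                            irms = np.sqrt(np.mean(itrack**2))
                            piece = piece + itrack * (10 ** (level / 20.0) / irms)
                        peak = np.max(np.abs(piece))
                        if peak > 1.0:
                            piece = piece / peak
                        clip = AudioClip(piece, sample_rate_hz)
                    clips.append(
                        clip.with_meta(
                            source_id=source_id,
                            label=label,
                            distance_m=dist,
                            interference_level_dbfs=level,
                            variant=variant,
                        )
                    )
                    variant += 1
    return clips
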