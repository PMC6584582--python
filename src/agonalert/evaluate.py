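"""Metrics and experiment harness.

Covers the numbers a detection study reports — ROC/AUC, operating points with
95% Wald confidence intervals, streaming false-positive accounting before and
after the breathing-rate filter — plus the benchmark condition matrix
(distance x interference x cancellation) and the end-to-end pipeline runner.

Percentages are formatted half-up at 2 decimal places for operating-point
metrics and 5 decimal places for streaming false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from . import agonal_filter as af
from . import synthgen
from .audio import AudioClip, segment as segment_clip
from .cancel import LMSConfig, cancel
from .detector import DetectorModel, crossvalidate, predict_stream, train
from .features import FeaturizerModel, embed_many, fit_featurizer

Z_95 = 1.96


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Format a fraction as a half-up-rounded percentage string."""
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value}%"


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Empirical ROC (threshold sweep over unique scores) and trapezoidal AUC.

    Equals the Mann-Whitney statistic U / (n1 * n0) with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc


def wald_ci(p_hat: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """Normal-approximation binomial interval p +/- z*sqrt(p(1-p)/n), clipped."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return max(0.0, p_hat - half), min(1.0, p_hat + half)


def fp_rate(pred_stream, truth_stream) -> float:
    """Streaming false-positive percentage.

    ``100 * (positive predictions on truly negative segments) / (negative
    segments)`` over aligned equal-length binary streams.
    """
    pred = np.asarray(pred_stream, dtype=int)
    truth = np.asarray(truth_stream, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth streams must be equal length")
    neg = truth == 0
    n_neg = int(np.sum(neg))
    if n_neg == 0:
        raise ValueError("no negative segments in the truth stream")
    fp = int(np.sum(pred[neg] == 1))
    return 100.0 * fp / n_neg


@dataclass
class EvalReport:
    auc: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    fp_rate_percent: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    sensitivity_ci: tuple | None = None
    specificity_ci: tuple | None = None
    extras: dict = field(default_factory=dict)

    @staticmethod
    def from_predictions(pred, truth, scores=None) -> "EvalReport":
        pred = np.asarray(pred, dtype=int)
        truth = np.asarray(truth, dtype=int)
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        rep = EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fn:
            rep.sensitivity = tp / (tp + fn)
            rep.sensitivity_ci = wald_ci(rep.sensitivity, tp + fn)
        if tn + fp:
            rep.specificity = tn / (tn + fp)
            rep.specificity_ci = wald_ci(rep.specificity, tn + fp)
            rep.fp_rate_percent = 100.0 * fp / (tn + fp)
        if scores is not None and len(np.unique(truth)) == 2:
            _, rep.auc = roc_auc(scores, truth)
        return rep


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    stream: AudioClip,
    featurizer: FeaturizerModel,
    model: DetectorModel,
    filter_config: af.FilterConfig = af.FilterConfig(),
    lms_config: LMSConfig | None = None,
    playback_reference: AudioClip | None = None,
    segment_len_s: float = 2.5,
) -> tuple[pd.DataFrame, af.AlarmTrace, EvalReport]:
    """Segment -> (optional LMS cancel) -> embed -> classify -> rate filter.

    Deterministic given fixed models and inputs.  Returns the per-segment
    prediction table (start_s, prob, label), the alarm trace, and a report.
    """
    if lms_config is not None and playback_reference is not None:
        stream, _ = cancel(stream, playback_reference, lms_config)
    stream_segments = segment_clip(stream, segment_len_s)
    if len(stream_segments) == 0:
        empty = pd.DataFrame(columns=["start_s", "prob", "label"])
        return empty, af.AlarmTrace(), EvalReport()
    clips = [c for _, c in stream_segments]
    Z = embed_many(clips, featurizer)
    labels, probs = predict_stream(model, Z)
    preds = pd.DataFrame(
        {"start_s": stream_segments.start_times(), "prob": probs, "label": labels}
    )
    trace = af.run_stream(preds[["start_s", "label"]].itertuples(index=False),
                          filter_config)
    report = EvalReport(extras={"n_segments": len(preds),
                                "n_alarms": len(trace.alarms)})
    return preds, trace, report


# ---------------------------------------------------------------------------
# reference training bundle (shared by benchmarks, tests and the acceptance
# script so every experiment runs against the same models)


@dataclass
class TrainedBundle:
    featurizer: FeaturizerModel
    model: DetectorModel


def train_reference_bundle(
    n_sources_per_class: int = 40,
    n_components: int = 256,
    seed: int = 0,
) -> TrainedBundle:
    """Fit the featurizer and detector once on a synthetic clip corpus."""
    clips = synthgen.build_clip_corpus(n_sources_per_class, seed=seed)
    featurizer = fit_featurizer(clips, n_components=n_components, seed=seed)
    Z = embed_many(clips, featurizer)
    y = np.array([c.meta["label"] for c in clips])
    model = train(Z, y, seed=seed)
    return TrainedBundle(featurizer, model)


def synthetic_cv_experiment(
    n_sources_per_class: int = 100,
    k: int = 10,
    seed: int = 0,
    n_components: int = 256,
):
    """Grouped k-fold CV of the full pipeline on a fresh synthetic corpus."""
    clips = synthgen.build_clip_corpus(n_sources_per_class, seed=seed)
    return crossvalidate(clips, k=k, seed=seed, n_components=n_components)


def fp_cascade_experiment(
    n_streams: int = 100,
    stream_hours: float = 1.0,
    p_positive: float = 0.00144,
    segment_len_s: float = 2.5,
    seed: int = 0,
) -> dict:
    """False-positive cascade on simulated all-negative prediction streams.

    Positives arrive i.i.d. with probability ``p_positive`` per segment (the
    order of magnitude of the raw classifier FP rate on sleep audio).  Reports
    the raw segment FP percentage and the alarm percentages after the 2- and
    3-breath rate filters; the cascade must be monotone non-increasing.
    """
    rng = np.random.default_rng(seed)
    n_seg = int(stream_hours * 3600 / segment_len_s)
    totals = {"segments": 0, "raw": 0, "two_breath": 0, "three_breath": 0}
    per_stream = []
    for _ in range(n_streams):
        labels = rng.random(n_seg) < p_positive
        starts = np.arange(n_seg) * segment_len_s
        stream_rows = list(zip(starts, labels.astype(int)))
        two = af.run_stream(stream_rows, af.FilterConfig(breaths_required=2))
        three = af.run_stream(stream_rows, af.FilterConfig(breaths_required=3))
        totals["segments"] += n_seg
        totals["raw"] += int(labels.sum())
        totals["two_breath"] += len(two.alarms)
        totals["three_breath"] += len(three.alarms)
        per_stream.append((int(labels.sum()), len(two.alarms), len(three.alarms)))
    n = totals["segments"]
    return {
        "raw_percent": 100.0 * totals["raw"] / n,
        "two_breath_percent": 100.0 * totals["two_breath"] / n,
        "three_breath_percent": 100.0 * totals["three_breath"] / n,
        "counts": totals,
        "per_stream": per_stream,
    }


def _delayed(x: np.ndarray, delay: int) -> np.ndarray:
    out = np.zeros_like(x)
    out[delay:] = x[: len(x) - delay]
    return out


def _scene_with_playback(
    scene_seed: int,
    duration_s: float = 60.0,
    playback_gain: float = 0.9,
    echo_gain: float = 0.7,
    echo_delay: int = 12,
    sample_rate_hz: int = 16000,
):
    """Gasp-train scene plus the echo of a known self-playback signal."""
    spec = synthgen.gasp_train_spec(
        duration_s, gap_s=12.0, gasp_duration_s=0.8,
        sample_rate_hz=sample_rate_hz, seed=scene_seed, noise_floor_dbfs=-55.0,
    )
    scene, truth = synthgen.render_scene(spec)
    playback = synthgen.make_interference(
        "speech_like", duration_s, sample_rate_hz, seed=scene_seed + 10_000
    ).samples * playback_gain
    received = scene.samples + echo_gain * _delayed(playback, echo_delay)
    peak = np.max(np.abs(received))
    if peak > 1.0:
        received = received / peak
    return (
        AudioClip(received, sample_rate_hz),
        AudioClip(playback, sample_rate_hz),
        truth,
    )


def cancellation_experiment(
    bundle: TrainedBundle,
    n_scenes: int = 20,
    seed: int = 0,
    lms_config: LMSConfig = LMSConfig(),
) -> dict:
    """Paired with/without-LMS segment accuracy on self-playback scenes.

    Each scene contains an agonal gasp train masked by the echo of a known
    speech-like playback signal.  Accuracy is the fraction of 2.5 s segments
    classified with their ground-truth label.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_scenes):
        scene_seed = int(rng.integers(0, 2**31 - 1))
        received, playback, truth = _scene_with_playback(scene_seed)
        accs = {}
        for use_lms in (False, True):
            clip = received
            if use_lms:
                clip, _ = cancel(received, playback, lms_config)
            segs = [c for _, c in segment_clip(clip)]
            Z = embed_many(segs, bundle.featurizer)
            labels, _ = predict_stream(bundle.model, Z)
            y = truth.segment_labels[: len(labels)]
            accs[use_lms] = float(np.mean(labels[: len(y)] == y))
        pairs.append((accs[True], accs[False]))
    wins = sum(1 for w, wo in pairs if w > wo)
    return {
        "wins": wins,
        "n_scenes": n_scenes,
        "pairs": pairs,
        "mean_accuracy_with": float(np.mean([w for w, _ in pairs])),
        "mean_accuracy_without": float(np.mean([wo for _, wo in pairs])),
    }


def benchmark_matrix(
    bundle: TrainedBundle,
    distances_m=(1.0, 3.0, 6.0),
    interference_kinds=(None, "speech_like", "traffic_like"),
    cancellation=(False,),
    n_scenes: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition detection accuracy over the benchmark grid.

    Each cell renders ``n_scenes`` positive (single gasp) and ``n_scenes``
    negative 2.5 s clips under that condition — optionally with self-playback
    plus LMS cancellation — and reports the fraction of clips classified with
    their true label (mean and standard deviation across clips).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for dist in distances_m:
        for ikind in interference_kinds:
            for with_lms in cancellation:
                correct = []
                for label in (1, 0):
                    for j in range(n_scenes):
                        s = int(rng.integers(0, 2**31 - 1))
                        interference = (((ikind, -25.0),) if ikind else ())
                        if label:
                            gasp = synthgen.SceneEvent(
                                float(np.random.default_rng(s).uniform(0, 1.5)),
                                "agonal_gasp",
                                0.8,
                            )
                            spec = synthgen.SceneSpec(
                                2.5, 16000, (gasp,), interference,
                                distance_m=dist, noise_floor_dbfs=-50.0, seed=s,
                            )
                        else:
                            spec = synthgen.SceneSpec(
                                2.5, 16000, (), interference,
                                distance_m=dist, noise_floor_dbfs=-50.0, seed=s,
                            )
                        clip, _ = synthgen.render_scene(spec)
                        if not label:
                            # negative clips carry a slice of sleep audio at
                            # the cell's distance, matching the corpus recipe
                            kind = synthgen.NEGATIVE_KINDS[
                                j % len(synthgen.NEGATIVE_KINDS)
                            ]
                            track = synthgen.make_negative_track(
                                kind, 10.0, 15.0, 16000, s
                            )
                            clip = AudioClip(
                                clip.samples + track.samples[: len(clip.samples)]
                                / dist,
                                16000,
                            )
                        received = clip
                        reference = None
                        if with_lms:
                            playback = synthgen.make_interference(
                                "speech_like", 2.5, 16000, s + 1
                            ).samples * 0.8
                            mixed = clip.samples + 0.7 * _delayed(playback, 12)
                            peak = np.max(np.abs(mixed))
                            if peak > 1:
                                mixed = mixed / peak
                            received = AudioClip(mixed, 16000)
                            reference = AudioClip(playback, 16000)
                            received, _ = cancel(received, reference)
                        Z = embed_many([received], bundle.featurizer)
                        pred, _ = predict_stream(bundle.model, Z)
                        correct.append(int(pred[0] == label))
                if correct:
                    rows.append(
                        {
                            "distance_m": dist,
                            "interference": ikind or "none",
                            "cancellation": with_lms,
                            "accuracy": float(np.mean(correct)),
                            "accuracy_sd": float(np.std(correct)),
                            "n_clips": len(correct),
                        }
                    )
    return pd.DataFrame(rows)
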