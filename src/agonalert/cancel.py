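"""Sign-Data LMS cancellation of the device's own playback.

A smart speaker that plays music (or a sleep soundscape) while listening
hears its own transmission on top of the room audio.  Because the played
signal is known exactly, an adaptive filter can subtract its acoustic echo
before featurization.  The update is the Sign-Data LMS variant with 100
weights and step size mu = 0.05:

    y_hat[k] = w . x[k]          (x[k] = last n_weights reference samples)
    e[k]     = received[k] - y_hat[k]
    w       <- w + mu * e[k] * sign(x[k])

with ``sign(0) = 0`` so an all-zero reference is a strict no-op.  The
reference is normalized by its running peak (times ``1/sqrt(n_weights)``)
before the update, so the fixed step size behaves consistently across
playback levels and the sign-data loop gain ``mu * ||x||_1`` stays inside
its stability bound for any input.  The filter
models echo delays of at most ``n_weights`` samples (6.25 ms at 16 kHz);
coarse alignment of the reference is the caller's job (see ``chirpsync``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .audio import AudioClip


@dataclass(frozen=True)
class LMSConfig:
    n_weights: int = 100
    step_size: float = 0.05

    def __post_init__(self):
        if self.n_weights < 1:
            raise ValueError("n_weights must be >= 1")
        if self.step_size < 0:
            raise ValueError("step_size must be >= 0")


@njit(cache=True)
def _sign_data_lms(received, reference, n_weights, mu):  # pragma: no cover
    n = received.shape[0]
    w = np.zeros(n_weights)
    cleaned = np.empty(n)
    x = np.zeros(n_weights)  # x[0] newest
    peak = 0.0
    # running-peak normalization plus a 1/sqrt(n_weights) factor keeps the
    # sign-data loop gain mu*||x||_1 below its stability bound of 2 for any
    # input level (worst case mu*sqrt(n_weights))
    scale = 1.0 / np.sqrt(n_weights)
    for k in range(n):
        r = reference[k]
        if abs(r) > peak:
            peak = abs(r)
        for j in range(n_weights - 1, 0, -1):
            x[j] = x[j - 1]
        x[0] = r * scale / peak if peak > 0.0 else 0.0
        y_hat = 0.0
        for j in range(n_weights):
            y_hat += w[j] * x[j]
        e = received[k] - y_hat
        cleaned[k] = e
        step = mu * e
        for j in range(n_weights):
            xj = x[j]
            if xj > 0.0:
                w[j] += step
            elif xj < 0.0:
                w[j] -= step
    return cleaned, w


def cancel(
    received: AudioClip,
    reference: AudioClip,
    config: LMSConfig = LMSConfig(),
) -> tuple[AudioClip, np.ndarray]:
    """Subtract the adaptively-estimated echo of ``reference`` from ``received``.

    Returns the cleaned clip (the error signal) and the final weight vector.
    The reference must share the received clip's sample rate and be
    time-aligned; if shorter it is zero-padded with a warning.
    """
    if received.sample_rate_hz != reference.sample_rate_hz:
        raise ValueError(
            f"sample-rate mismatch: received {received.sample_rate_hz} Hz, "
            f"reference {reference.sample_rate_hz} Hz"
        )
    d = received.samples
    x = reference.samples
    if len(x) < len(d):
        warnings.warn(
            f"reference ({len(x)} samples) shorter than received ({len(d)}); "
            "zero-padding",
            stacklevel=2,
        )
        x = np.concatenate([x, np.zeros(len(d) - len(x))])
    cleaned, w = _sign_data_lms(
        np.ascontiguousarray(d, dtype=np.float64),
        np.ascontiguousarray(x[: len(d)], dtype=np.float64),
        config.n_weights,
        config.step_size,
    )
    return replace(received, samples=cleaned), w
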