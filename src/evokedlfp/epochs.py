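"""Stimulus-aligned epoching and time-domain evoked-potential features.

Conventions: epoch windows are half-open ``[stim − pre, stim + post)``;
the sample at t = 0 is the first post-stimulus sample; all indexing is
0-based.  Feature extraction works on the baseline-corrected across-trial
average, so evoked-potential features are invariant to any constant offset
of the raw recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "EpochSet",
    "Evoked",
    "EPFeatures",
    "EpochingError",
    "segment",
    "baseline_correct_and_average",
    "extract_ep_features",
    "ep_features_table",
]


class EpochingError(ValueError):
    """Raised when a stimulus window falls outside the recording."""


@dataclass
class EpochSet:
    """Stimulus-aligned signal segments (epoch × sample, µV)."""

    epochs: np.ndarray
    pre_window: float
    post_window: float
    sampling_rate: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_pre(self) -> int:
        """Index of the first post-stimulus sample (t = 0)."""
        return round(self.pre_window * self.sampling_rate)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class Evoked:
    """An averaged, baseline-corrected epoch."""

    data: np.ndarray
    sampling_rate: float
    pre_window: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_pre(self) -> int:
        return round(self.pre_window * self.sampling_rate)


@dataclass
class EPFeatures:
    """Evoked-potential features from an averaged epoch.

    ``peak_amplitude`` is the magnitude of the largest absolute deflection
    in the search window; its sign is carried separately in ``polarity``.
    ``onset_latency_ms`` is ``None`` when no supra-threshold deflection was
    found (distinct from an onset at 0).
    """

    peak_amplitude: float
    peak_latency_ms: float
    onset_latency_ms: Optional[float]
    polarity: int
    flags: tuple = ()


def segment(rec: Recording, pre: float, post: float) -> EpochSet:
    """Cut a recording into stimulus-aligned epochs of ``pre + post`` seconds.

    Epoch ``k`` spans ``[stim_k − pre, stim_k + post)``; every epoch has
    exactly ``round((pre + post) · rate)`` samples.  A stimulus whose window
    would be truncated raises :class:`EpochingError` naming the epoch.
    """
    fs = rec.sampling_rate
    n_pre = round(pre * fs)
    n_post = round(post * fs)
    if n_pre + n_post < 1:
        raise ValueError("epoch window is empty")
    n = rec.n_samples
    rows = []
    for k, t in enumerate(rec.stim_times):
        s = round(t * fs)
        if s - n_pre < 0 or s + n_post > n:
            raise EpochingError(
                f"epoch {k}: window [{t - pre:.3f}, {t + post:.3f}) s "
                f"extends outside the {n / fs:.3f}-s recording"
            )
        rows.append(rec.samples[s - n_pre : s + n_post])
    epochs = np.stack(rows) if rows else np.empty((0, n_pre + n_post))
    return EpochSet(
        epochs=epochs,
        pre_window=pre,
        post_window=post,
        sampling_rate=fs,
        provenance={
            "subject_id": rec.subject_id,
            "age_group": rec.age_group,
            "condition": rec.condition,
            "n_stimuli": len(rec.stim_times),
        },
    )


def baseline_correct_and_average(es: EpochSet) -> Evoked:
    """Subtract each epoch's pre-stimulus mean, then average across epochs.

    The result has zero pre-stimulus mean to numerical tolerance.
    """
    if es.n_epochs == 0:
        raise ValueError("cannot average an empty EpochSet")
    if es.n_pre < 1:
        raise ValueError("baseline correction needs a pre-stimulus window")
    base = es.epochs[:, : es.n_pre].mean(axis=1, keepdims=True)
    avg = (es.epochs - base).mean(axis=0)
    return Evoked(avg, es.sampling_rate, es.pre_window, dict(es.provenance))


def extract_ep_features(
    evoked: Evoked,
    search_window_ms: tuple[float, float] = (0.0, 300.0),
    onset_k: float = 3.0,
    artifact_blank_ms: float = 2.0,
    hold_ms: float = 3.0,
) -> EPFeatures:
    """Peak amplitude and onset latency of an averaged evoked potential.

    The peak is the maximum absolute deflection within ``search_window_ms``
    post-stimulus (the first ``artifact_blank_ms`` are excluded as stimulus
    artifact).  Onset is the first post-stimulus time at which ``|signal|``
    exceeds ``onset_k`` × the pre-stimulus baseline standard deviation and
    stays above threshold for at least ``hold_ms``; if no such crossing
    exists the onset is reported missing with a ``"no_onset"`` flag.
    """
    fs = evoked.sampling_rate
    x = np.asarray(evoked.data, dtype=float)
    n_pre = evoked.n_pre
    post = x[n_pre:]
    if len(post) == 0:
        raise ValueError("averaged epoch has no post-stimulus samples")
    span_ms = len(post) / fs * 1000.0
    w0, w1 = search_window_ms
    if not (0 <= w0 < w1 <= span_ms + 1e-9):
        raise ValueError(
            f"search window {search_window_ms} ms outside post-stimulus span (0, {span_ms:.1f}) ms"
        )
    blank = math.ceil(artifact_blank_ms * fs / 1000.0)
    i0 = max(blank, math.ceil(w0 * fs / 1000.0))
    i1 = min(len(post), math.floor(w1 * fs / 1000.0))
    if i1 <= i0:
        raise ValueError("search window contains no samples after artifact blanking")

    seg = post[i0:i1]
    ip = int(np.argmax(np.abs(seg))) + i0
    peak_amplitude = float(abs(post[ip]))
    polarity = int(np.sign(post[ip])) or 1
    peak_latency_ms = ip / fs * 1000.0

    baseline_sd = float(x[:n_pre].std()) if n_pre > 0 else 0.0
    threshold = onset_k * baseline_sd
    above = np.abs(post) > threshold
    above[:blank] = False
    hold = max(1, round(hold_ms * fs / 1000.0))

    onset_idx = None
    # sustained crossing: `hold` consecutive supra-threshold samples
    run = 0
    for j in range(blank, ip + 1):
        run = run + 1 if above[j] else 0
        if run == 1:
            start = j
        if run >= hold or (above[j] and j == ip):
            onset_idx = start
            break
    flags: tuple = ()
    if onset_idx is None:
        flags = ("no_onset",)
        onset_ms = None
    else:
        onset_ms = onset_idx / fs * 1000.0
    return EPFeatures(peak_amplitude, peak_latency_ms, onset_ms, polarity, flags)


def ep_features_table(
    recordings,
    pre: float = 0.15,
    post: float = 1.35,
    **feature_kw,
) -> pd.DataFrame:
    """Tidy EP-feature table: one row per recording (subject × condition)."""
    rows = []
    for rec in recordings:
        es = segment(rec, pre, post)
        feats = extract_ep_features(baseline_correct_and_average(es), **feature_kw)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age_group": rec.age_group,
                "condition": rec.condition,
                "peak_amplitude_uV": feats.peak_amplitude,
                "onset_latency_ms": feats.onset_latency_ms,
                "peak_latency_ms": feats.peak_latency_ms,
                "polarity": feats.polarity,
            }
        )
    return pd.DataFrame(rows)
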