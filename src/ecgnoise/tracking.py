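"""Inline noise tracking: sliding-window classification of a whole recording.

A trained model (with the scaler fit on its training data) slides over the
recording in 5-s windows with 4-s overlap (1-s hop).  Each window is
conditioned, featurized, scaled and classified; windows that straddle an
annotation boundary are reported separately since their ground truth is
mixed.  Degenerate (flatline) windows are labelled noisy and flagged —
signal-free stretches carry no clinical information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import CLEAN, EXCLUDED, NOISY, apply_feature_scaler, map_noise_type
from .features import extract_features
from .io import AnnotationInterval, Recording, ValidationError, validate_continuous
from .models import (
    MetricsReport,
    compute_metrics,
    confusion_from_predictions,
)
from .preprocess import DegenerateBlockError


@dataclass
class NoiseTrack:
    """Windowed clean/noisy decisions over one recording."""

    starts: np.ndarray          # window start times, s (strictly increasing by hop)
    labels: list[str]           # predicted label per window
    scores: np.ndarray          # decision score (P(clean) or margin)
    degenerate: np.ndarray      # True where the window was a flatline
    window: float
    hop: float

    def __post_init__(self) -> None:
        d = np.diff(self.starts)
        if d.size and not np.allclose(d, self.hop):
            raise ValidationError("window starts must advance by the hop")


def expected_window_count(duration: float, window: float, hop: float) -> int:
    """floor((duration - window)/hop) + 1 fully-contained windows."""
    return int(np.floor((duration - window) / hop + 1e-9)) + 1


def track_recording(
    rec: Recording,
    model,
    scaler,
    window: float = 5.0,
    overlap: float = 4.0,
) -> NoiseTrack:
    """Classify every sliding window of a recording.

    ``model`` and ``scaler`` come from a rotation in which this patient was
    held out when available; any trained pair is accepted.
    """
    if rec.duration < window:
        raise ValidationError(
            f"recording of {rec.duration:.1f} s shorter than the {window}-s window"
        )
    if not (0 <= overlap < window):
        raise ValidationError(f"overlap {overlap} must be in [0, window)")
    hop = window - overlap
    n_windows = expected_window_count(rec.duration, window, hop)
    L = int(round(window * rec.fs))
    starts, labels, scores, degen = [], [], [], []
    for w in range(n_windows):
        t0 = w * hop
        i0 = int(round(t0 * rec.fs))
        seg = rec.samples[i0 : i0 + L]
        starts.append(t0)
        try:
            fv = extract_features(seg, rec.fs)
        except DegenerateBlockError:
            labels.append(NOISY)
            scores.append(0.0)
            degen.append(True)
            continue
        z = apply_feature_scaler(fv.as_array()[None, :], scaler)
        if hasattr(model, "predict_proba"):
            score = float(model.predict_proba(z)[0, list(model.classes_).index(1)])
            pred = 1 if score >= 0.5 else 0
        else:
            pred = int(model.predict(z)[0])
            score = float(pred)
        labels.append(CLEAN if pred == 1 else NOISY)
        scores.append(score)
        degen.append(False)
    return NoiseTrack(
        starts=np.asarray(starts),
        labels=labels,
        scores=np.asarray(scores),
        degenerate=np.asarray(degen, dtype=bool),
        window=window,
        hop=hop,
    )


@dataclass
class TrackEvaluation:
    """Windowed scoring of a track against continuous annotations."""

    metrics: MetricsReport
    n_scored: int
    n_mixed: int
    mixed_windows: list[float] = field(default_factory=list)  # start times
    n_excluded: int = 0


def window_ground_truth(
    annotations: Sequence[AnnotationInterval],
    t0: float,
    t1: float,
) -> tuple[str, bool]:
    """Majority-by-duration label of a window, and whether it is mixed.

    The majority noise type over [t0, t1) is mapped to clean/noisy/excluded;
    a tie between a clean-mapped and a noisy-mapped type breaks toward noisy
    (conservative for clinical use).  ``mixed`` is True when more than one
    noise type overlaps the window.
    """
    durations: dict[str, float] = {}
    for iv in annotations:
        ov = min(iv.offset, t1) - max(iv.onset, t0)
        if ov > 1e-9:
            durations[iv.noise_type] = durations.get(iv.noise_type, 0.0) + ov
    if not durations:
        raise ValidationError(f"window [{t0}, {t1}) not covered by annotations")
    mixed = len(durations) > 1
    best = max(durations.values())
    top = [ty for ty, d in durations.items() if abs(d - best) <= 1e-9]
    if len(top) > 1:
        noisy_top = [ty for ty in top if map_noise_type(ty) == NOISY]
        choice = noisy_top[0] if noisy_top else top[0]
    else:
        choice = top[0]
    return map_noise_type(choice), mixed


def evaluate_track(
    track: NoiseTrack,
    annotations: Sequence[AnnotationInterval],
) -> TrackEvaluation:
    """Score windowed decisions against the continuous ground truth.

    Windows whose majority type maps to *excluded* (T4) are dropped from the
    confusion counts; boundary-straddling (mixed) windows are listed in the
    transition report since their label is ambiguous by construction.
    """
    validate_continuous(annotations)
    y_true, y_pred, mixed_starts = [], [], []
    n_excluded = 0
    for t0, pred in zip(track.starts, track.labels):
        truth, mixed = window_ground_truth(annotations, t0, t0 + track.window)
        if truth == EXCLUDED:
            n_excluded += 1
            continue
        if mixed:
            mixed_starts.append(float(t0))
        y_true.append(1 if truth == CLEAN else 0)
        y_pred.append(1 if pred == CLEAN else 0)
    if not y_true:
        raise ValidationError("no scorable windows")
    conf = confusion_from_predictions(np.array(y_true), np.array(y_pred))
    return TrackEvaluation(
        metrics=compute_metrics(conf),
        n_scored=len(y_true),
        n_mixed=len(mixed_starts),
        mixed_windows=mixed_starts,
        n_excluded=n_excluded,
    )
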