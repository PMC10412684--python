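"""From continuously annotated recordings to a labelled instance set.

Blocks are fixed-length (default 5 s), single-category excerpts placed
left-to-right inside each annotation interval with a guard gap (default 1 s)
between consecutive blocks, so instances are non-overlapping and mutually
decorrelated.  Noise types map onto the binary target: T0/T1 -> clean,
T2/T3 -> noisy, T4 -> excluded.  Patients whose instances are less than 25%
in either class are discarded before model design, and features are z-scored
with statistics estimated on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .features import FEATURE_NAMES, extract_features
from .io import AnnotationInterval, Recording, ValidationError, validate_continuous
from .preprocess import DegenerateBlockError

CLEAN, NOISY, EXCLUDED = "clean", "noisy", "excluded"

#: binary label per clinical-noise type
LABEL_MAP = {"T0": CLEAN, "T1": CLEAN, "T2": NOISY, "T3": NOISY, "T4": EXCLUDED}


def map_noise_type(noise_type: str) -> str:
    """T0/T1 -> clean, T2/T3 -> noisy, T4 -> excluded."""
    try:
        return LABEL_MAP[noise_type]
    except KeyError:
        raise ValidationError(f"unknown noise type {noise_type!r}") from None


@dataclass
class Block:
    """One fixed-length, single-category signal excerpt."""

    samples: np.ndarray = field(repr=False)
    patient_id: str
    noise_type: str
    label: str
    onset: float           # seconds from recording start
    fs: float
    block_id: str = ""

    def __post_init__(self) -> None:
        if map_noise_type(self.noise_type) != self.label:
            raise ValidationError(
                f"label {self.label!r} inconsistent with type {self.noise_type!r}"
            )


def segment_labeled_recording(
    rec: Recording,
    annotations: Sequence[AnnotationInterval],
    t_b: float = 5.0,
    gap: float = 1.0,
    offset_rng: np.random.Generator | None = None,
) -> list[Block]:
    """Cut non-overlapping single-category blocks out of a recording.

    Within each maximal single-category interval, blocks are placed
    left-to-right from the interval onset, each pair separated by ``gap``
    seconds; no block crosses a category boundary.  Blocks of excluded types
    (T4) are dropped.  ``offset_rng``, when given, draws a random start
    offset inside each interval's slack (augmentation mode); the default is
    deterministic placement at the onset.
    """
    validate_continuous(annotations, duration=rec.duration)
    blocks: list[Block] = []
    L = int(round(t_b * rec.fs))
    for iv in sorted(annotations, key=lambda iv: iv.onset):
        label = map_noise_type(iv.noise_type)
        if label == EXCLUDED:
            continue
        n_fit = int(np.floor((iv.duration + gap) / (t_b + gap) + 1e-9))
        if n_fit < 1:
            continue
        slack = iv.duration - (n_fit * t_b + (n_fit - 1) * gap)
        start = iv.onset
        if offset_rng is not None and slack > 0:
            start += offset_rng.uniform(0, slack)
        for k in range(n_fit):
            onset = start + k * (t_b + gap)
            i0 = int(round(onset * rec.fs))
            if i0 + L > rec.samples.size:
                break
            blocks.append(
                Block(
                    samples=rec.samples[i0 : i0 + L].copy(),
                    patient_id=rec.patient_id,
                    noise_type=iv.noise_type,
                    label=label,
                    onset=onset,
                    fs=rec.fs,
                    block_id=f"{rec.patient_id}:{rec.lead_id}:{onset:.3f}",
                )
            )
    return blocks


def segment_cohort(
    cohort: Iterable[tuple[Recording, Sequence[AnnotationInterval]]],
    t_b: float = 5.0,
    gap: float = 1.0,
) -> list[Block]:
    blocks: list[Block] = []
    for rec, anns in cohort:
        blocks.extend(segment_labeled_recording(rec, anns, t_b=t_b, gap=gap))
    return blocks


def filter_patients(blocks: Sequence[Block], min_fraction: float = 0.25) -> set[str]:
    """Patients retained for model design: both class shares >= ``min_fraction``.

    Shares are over the patient's clean+noisy instances; a patient strictly
    below the threshold in either class is discarded.
    """
    if not blocks:
        raise ValidationError("no blocks to filter")
    counts: dict[str, dict[str, int]] = {}
    for b in blocks:
        counts.setdefault(b.patient_id, {CLEAN: 0, NOISY: 0})[b.label] += 1
    retained = set()
    for pid, c in counts.items():
        total = c[CLEAN] + c[NOISY]
        if total == 0:
            continue
        if c[CLEAN] / total >= min_fraction and c[NOISY] / total >= min_fraction:
            retained.add(pid)
    return retained


def summarize_dataset(blocks: Sequence[Block]) -> dict:
    """Counts and two-decimal percentage shares per class and per noise type."""
    by_class: dict[str, int] = {CLEAN: 0, NOISY: 0}
    by_type: dict[str, int] = {}
    for b in blocks:
        by_class[b.label] = by_class.get(b.label, 0) + 1
        by_type[b.noise_type] = by_type.get(b.noise_type, 0) + 1
    total = sum(by_class.values())

    def pct(k: int) -> float:
        return round(100.0 * k / total, 2) if total else 0.0

    return {
        "total": total,
        "class_counts": dict(by_class),
        "class_percent": {k: pct(v) for k, v in by_class.items()},
        "type_counts": dict(by_type),
        "type_percent": {k: pct(v) for k, v in by_type.items()},
    }


def class_share_percent(count: int, total: int) -> float:
    """Share of a class in percent, rounded to two decimals."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round(100.0 * count / total, 2)


@dataclass
class DatasetMatrix:
    """Feature matrix with binary targets and patient identities."""

    X: np.ndarray
    y: np.ndarray              # 1 = clean (positive class), 0 = noisy
    patient_ids: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.patient_ids = np.asarray(self.patient_ids)
        if not (self.X.shape[0] == self.y.size == self.patient_ids.size):
            raise ValidationError("X, y and patient_ids row counts disagree")
        if np.isnan(self.X).any():
            raise ValidationError("NaN entries in feature matrix")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]


def build_dataset(
    blocks: Sequence[Block],
    patients: set[str] | None = None,
) -> DatasetMatrix:
    """Extract features for every (optionally patient-filtered) block.

    Degenerate (flatline) blocks are skipped; they correspond to signal-free
    excerpts that the taxonomy already excludes.
    """
    rows, ys, pids = [], [], []
    for b in blocks:
        if patients is not None and b.patient_id not in patients:
            continue
        try:
            fv = extract_features(b.samples, b.fs)
        except DegenerateBlockError:
            continue
        rows.append(fv.as_array())
        ys.append(1 if b.label == CLEAN else 0)
        pids.append(b.patient_id)
    if not rows:
        raise ValidationError("no usable blocks")
    return DatasetMatrix(np.vstack(rows), np.array(ys), np.array(pids))


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature z-score parameters estimated on the train split only."""

    mu: np.ndarray
    sigma: np.ndarray


def fit_feature_scaler(X_train: np.ndarray) -> ScalingParams:
    """Column means and population standard deviations of the train split."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValidationError("need at least 2 training rows")
    mu = X_train.mean(axis=0)
    sigma = X_train.std(axis=0)          # population convention (ddof=0)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        names = [f"x{j + 1}" for j in bad]
        raise ValidationError(f"zero-variance feature(s): {names}")
    return ScalingParams(mu=mu, sigma=sigma)


def apply_feature_scaler(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """z = (x - mu) / sigma with train-split parameters (never refit)."""
    return (np.asarray(X, dtype=float) - params.mu) / params.sigma
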