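"""Reading and writing recordings, continuous annotations, and feature tables.

A recording is one lead of ambulatory ECG with a patient identity and a
sampling rate.  Noise annotations are continuous: every sample of the
recording belongs to exactly one half-open interval ``[onset, offset)``
labeled with one of the five clinical-noise types T0..T4 (noise-free, low,
moderate, hard, other).

The on-disk containers are plain delimited text:

* recordings — CSV with one header row, a leading time-or-index column, and
  one column per lead;
* annotations — CSV with columns ``onset_s,offset_s,noise_type``;
* feature tables — TSV/CSV with header ``x1..x16,label,patient_id,block_id``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NOISE_TYPES = ("T0", "T1", "T2", "T3", "T4")

#: Stable feature-column order used in every feature table.
FEATURE_COLUMNS = tuple(f"x{j}" for j in range(1, 17))


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending content."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant (e.g. a labelling hole)."""


@dataclass
class Recording:
    """One lead of continuously recorded ECG.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    lead_id : str
        Lead identifier (leads are processed independently).
    fs : float
        Sampling rate in Hz.
    samples : numpy.ndarray
        Amplitude sequence in millivolts; finite values only.
    """

    patient_id: str
    lead_id: str
    fs: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValidationError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValidationError(f"non-finite sample at index {bad}")
        if not (1.0 <= self.duration <= 24 * 3600):
            raise ValidationError(
                f"duration {self.duration:.3f} s outside [1 s, 24 h]"
            )

    @property
    def duration(self) -> float:
        """Recording length in seconds (= n_samples / fs)."""
        return self.samples.size / self.fs


@dataclass(frozen=True)
class AnnotationInterval:
    """Half-open labelled interval ``[onset, offset)`` in seconds."""

    onset: float
    offset: float
    noise_type: str

    def __post_init__(self) -> None:
        if self.noise_type not in NOISE_TYPES:
            raise ParseError(
                f"unknown noise_type {self.noise_type!r}; expected one of {NOISE_TYPES}"
            )
        if not (0 <= self.onset < self.offset):
            raise ValidationError(
                f"invalid interval [{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def validate_continuous(
    intervals: Sequence[AnnotationInterval],
    duration: float | None = None,
    tol: float = 1e-9,
) -> None:
    """Check that sorted intervals tile ``[0, duration)`` without overlap or hole.

    Raises :class:`ValidationError` naming the first gap or overlap found.
    """
    if not intervals:
        raise ValidationError("no annotation intervals")
    ivs = sorted(intervals, key=lambda iv: iv.onset)
    if ivs[0].onset > tol:
        raise ValidationError(f"hole at (0, {ivs[0].onset})")
    for a, b in zip(ivs, ivs[1:]):
        if b.onset - a.offset > tol:
            raise ValidationError(f"hole at ({a.offset}, {b.onset})")
        if a.offset - b.onset > tol:
            raise ValidationError(f"overlap at ({b.onset}, {a.offset})")
    if duration is not None and abs(ivs[-1].offset - duration) > tol:
        if ivs[-1].offset < duration:
            raise ValidationError(f"hole at ({ivs[-1].offset}, {duration})")
        raise ValidationError(
            f"interval offset {ivs[-1].offset} exceeds duration {duration}"
        )


def read_recording(
    path: str | Path,
    format: str = "csv",
    fs: float = 200.0,
    patient_id: str | None = None,
) -> list[Recording]:
    """Read one :class:`Recording` per lead from a CSV file.

    The CSV has one header row; the first column is time or sample index and
    each remaining column is one lead.  ``fs`` comes from configuration (the
    file stores no rate).  ``patient_id`` defaults to the file stem.
    """
    if format == "wfdb":
        raise NotImplementedError(
            "WFDB input is not supported in this build; convert to the CSV "
            "dialect (time/index column + one column per lead)"
        )
    if format != "csv":
        raise ParseError(f"unknown recording format {format!r}")
    if fs <= 0:
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ParseError(f"{path}: header needs a time column plus >=1 lead")
        lead_names = [h.strip() for h in header[1:]]
        columns: list[list[float]] = [[] for _ in lead_names]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            for j, val in enumerate(row[1:]):
                try:
                    columns[j].append(float(val))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {val!r} in column "
                        f"{lead_names[j]!r}"
                    ) from None
    if not columns[0]:
        raise ParseError(f"{path}: no data rows")
    pid = patient_id if patient_id is not None else path.stem
    return [
        Recording(patient_id=pid, lead_id=name, fs=fs, samples=np.array(col))
        for name, col in zip(lead_names, columns)
    ]


def write_recording(recordings: Sequence[Recording], path: str | Path) -> None:
    """Write leads sharing a time base to the CSV dialect read by ``read_recording``."""
    recs = list(recordings)
    if not recs:
        raise ValidationError("no recordings to write")
    n = recs[0].samples.size
    fs = recs[0].fs
    if any(r.samples.size != n or r.fs != fs for r in recs):
        raise ValidationError("all leads of one file must share length and fs")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"] + [r.lead_id for r in recs])
        t = np.arange(n) / fs
        for i in range(n):
            writer.writerow(
                [f"{t[i]:.6f}"] + [f"{r.samples[i]:.12g}" for r in recs]
            )


def read_annotations(
    path: str | Path,
    continuous: bool = True,
    duration: float | None = None,
) -> list[AnnotationInterval]:
    """Read annotation intervals from a CSV with columns onset_s, offset_s, noise_type.

    Intervals are returned sorted by onset.  With ``continuous=True`` the set
    must tile the full duration with no hole or overlap.
    """
    path = Path(path)
    intervals: list[AnnotationInterval] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        try:
            i_on = header.index("onset_s")
            i_off = header.index("offset_s")
            i_ty = header.index("noise_type")
        except ValueError:
            raise ParseError(
                f"{path}: header must contain onset_s, offset_s, noise_type"
            ) from None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                onset = float(row[i_on])
                offset = float(row[i_off])
            except (ValueError, IndexError):
                raise ParseError(f"{path}:{lineno}: malformed row {row!r}") from None
            noise_type = row[i_ty].strip()
            if noise_type not in NOISE_TYPES:
                raise ParseError(
                    f"{path}:{lineno}: unknown noise_type {noise_type!r}"
                )
            intervals.append(AnnotationInterval(onset, offset, noise_type))
    intervals.sort(key=lambda iv: iv.onset)
    if continuous:
        validate_continuous(intervals, duration=duration)
    return intervals


def write_annotations(
    intervals: Iterable[AnnotationInterval], path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "offset_s", "noise_type"])
        for iv in sorted(intervals, key=lambda iv: iv.onset):
            writer.writerow([f"{iv.onset:.6f}", f"{iv.offset:.6f}", iv.noise_type])


def write_feature_table(
    rows: Sequence[tuple[str, object, Sequence[float], str]],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write feature rows ``(patient_id, block_id, features, label)`` as delimited text.

    Column order is ``x1..x16, label, patient_id, block_id``; values round-trip
    at 12 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(FEATURE_COLUMNS) + ["label", "patient_id", "block_id"])
        for patient_id, block_id, feats, label in rows:
            feats = list(feats)
            if len(feats) != len(FEATURE_COLUMNS):
                raise ValidationError(
                    f"row for patient {patient_id!r} block {block_id!r} has "
                    f"{len(feats)} features, expected {len(FEATURE_COLUMNS)}"
                )
            if not all(math.isfinite(float(v)) for v in feats):
                raise ValidationError(
                    f"non-finite feature in row {patient_id!r}/{block_id!r}"
                )
            writer.writerow(
                [f"{float(v):.12g}" for v in feats]
                + [label, patient_id, str(block_id)]
            )


def read_feature_table(path: str | Path, delimiter: str | None = None):
    """Read a feature table written by :func:`write_feature_table`.

    Returns a pandas DataFrame with columns x1..x16, label, patient_id, block_id.
    """
    import pandas as pd

    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str, "block_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing feature columns {missing}")
    return df
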