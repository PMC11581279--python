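"""Coded patient cohorts: records, CSV I/O, splitting, 5-year labels.

A cohort stores integer-coded categorical predictors plus follow-up months
(1..60) and a binary death indicator. The 5-year outcome label is derived,
not stored: a patient censored alive before 60 months is *indeterminate*
for classification (still usable for Cox fitting and the C-index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .codebook import VariableCodebook, default_codebook

__all__ = [
    "FiveYearLabel",
    "PatientRecord",
    "Cohort",
    "five_year_label",
    "read_cohort",
    "write_cohort",
    "split_cohort",
]

HORIZON_MONTHS = 60

TIME_COL = "follow_up_months"
EVENT_COL = "event"


class FiveYearLabel(Enum):
    ALIVE = "Alive"
    DEAD = "Dead"
    INDETERMINATE = "Indeterminate"


@dataclass(frozen=True)
class PatientRecord:
    """One coded patient: level indices, follow-up months, death indicator."""

    levels: tuple[int, ...]
    follow_up_months: int
    event: int

    def __post_init__(self) -> None:
        if not 1 <= self.follow_up_months <= HORIZON_MONTHS:
            raise ValueError(
                f"follow_up_months must lie in [1, {HORIZON_MONTHS}], "
                f"got {self.follow_up_months}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def five_year_label(record: PatientRecord) -> FiveYearLabel:
    """Dead if the event occurred; Alive only if followed the full 60 months."""
    if record.event == 1:
        return FiveYearLabel.DEAD
    if record.follow_up_months >= HORIZON_MONTHS:
        return FiveYearLabel.ALIVE
    return FiveYearLabel.INDETERMINATE


class Cohort:
    """A sequence of patient records coded against a shared codebook.

    Internally columnar (numpy arrays) for fast counting; records are
    materialized on demand.
    """

    def __init__(
        self,
        codebook: VariableCodebook,
        levels: np.ndarray,
        months: np.ndarray,
        events: np.ndarray,
    ) -> None:
        levels = np.asarray(levels, dtype=np.int64)
        months = np.asarray(months, dtype=np.int64)
        events = np.asarray(events, dtype=np.int64)
        if levels.ndim != 2 or levels.shape[1] != len(codebook):
            raise ValueError(
                f"levels must be (n, {len(codebook)}), got {levels.shape}"
            )
        n = levels.shape[0]
        if months.shape != (n,) or events.shape != (n,):
            raise ValueError("months/events length mismatch")
        for j, var in enumerate(codebook):
            col = levels[:, j]
            if n and (col.min() < 0 or col.max() >= var.n_levels):
                bad = int(np.argmax((col < 0) | (col >= var.n_levels)))
                raise ValueError(
                    f"row {bad}: level {col[bad]} out of range for "
                    f"variable {var.name!r}"
                )
        if n:
            if months.min() < 1 or months.max() > HORIZON_MONTHS:
                bad = int(np.argmax((months < 1) | (months > HORIZON_MONTHS)))
                raise ValueError(
                    f"row {bad}: follow_up_months {months[bad]} outside "
                    f"[1, {HORIZON_MONTHS}]"
                )
            if not np.isin(events, (0, 1)).all():
                bad = int(np.argmax(~np.isin(events, (0, 1))))
                raise ValueError(f"row {bad}: event {events[bad]} not in {{0,1}}")
        self.codebook = codebook
        self.levels = levels
        self.months = months
        self.events = events

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_records(
        cls, codebook: VariableCodebook, records: Sequence[PatientRecord]
    ) -> "Cohort":
        if records:
            levels = np.array([r.levels for r in records], dtype=np.int64)
            months = np.array([r.follow_up_months for r in records])
            events = np.array([r.event for r in records])
        else:
            levels = np.empty((0, len(codebook)), dtype=np.int64)
            months = np.empty(0, dtype=np.int64)
            events = np.empty(0, dtype=np.int64)
        return cls(codebook, levels, months, events)

    @classmethod
    def empty(cls, codebook: VariableCodebook | None = None) -> "Cohort":
        return cls.from_records(codebook or default_codebook(), [])

    # -- basic protocol --------------------------------------------------
    def __len__(self) -> int:
        return self.levels.shape[0]

    def __getitem__(self, i: int) -> PatientRecord:
        return PatientRecord(
            tuple(int(x) for x in self.levels[i]),
            int(self.months[i]),
            int(self.events[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Cohort)
            and self.codebook == other.codebook
            and np.array_equal(self.levels, other.levels)
            and np.array_equal(self.months, other.months)
            and np.array_equal(self.events, other.events)
        )

    # -- derived ---------------------------------------------------------
    def labels(self) -> list[FiveYearLabel]:
        return [five_year_label(r) for r in self]

    def label_array(self) -> np.ndarray:
        """Per-record label code: 1 Alive, 0 Dead, -1 Indeterminate."""
        out = np.full(len(self), -1, dtype=np.int64)
        out[self.events == 1] = 0
        out[(self.events == 0) & (self.months >= HORIZON_MONTHS)] = 1
        return out

    def determinate(self) -> "Cohort":
        """Sub-cohort with a definite Alive/Dead 5-year outcome."""
        keep = self.label_array() >= 0
        return self.take(np.flatnonzero(keep))

    def take(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx, dtype=np.int64)
        return Cohort(
            self.codebook, self.levels[idx], self.months[idx], self.events[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=list(self.codebook.names))
        df[TIME_COL] = self.months
        df[EVENT_COL] = self.events
        return df


def read_cohort(path, codebook: VariableCodebook) -> Cohort:
    """Read an integer-coded cohort CSV validated against ``codebook``.

    Any row with an out-of-range level, month, or event indicator is rejected
    with its (1-based data) row number; only complete, mappable rows are kept
    — mirroring registry practice of analysing complete cases only.
    """
    df = pd.read_csv(path)
    required = list(codebook.names) + [TIME_COL, EVENT_COL]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {missing}")
    df = df[required]
    if not all(pd.api.types.is_integer_dtype(df[c]) for c in required):
        try:
            df = df.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-integer codes in {path}: {exc}") from exc
    try:
        return Cohort(
            codebook,
            df[list(codebook.names)].to_numpy(),
            df[TIME_COL].to_numpy(),
            df[EVENT_COL].to_numpy(),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as an integer-coded CSV (header + one row per record)."""
    cohort.to_frame().to_csv(path, index=False)


def split_cohort(
    cohort: Cohort, train_fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Seeded random train/test partition.

    The training size is ``round-half-up(n * train_fraction)`` — e.g. 618
    records at 0.75 give 464/154. The same seed always yields the same split.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError("train_fraction must lie in (0, 1]")
    n_train = int(math.floor(n * train_fraction + 0.5))
    n_train = min(n_train, n)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return cohort.take(train_idx), cohort.take(test_idx)
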