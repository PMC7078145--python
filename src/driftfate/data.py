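"""Encounter records, CSV I/O, validation, and m-array construction.

The unit of observation is one floating carcass released on a known study
day and either recovered on a beach on a later (or the same) day, or never
recovered within the study window.  The sufficient statistic for the
dead-recovery likelihood is the m-array: per-cohort counts of recoveries by
occasion plus the never-recovered remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "EncounterRecord",
    "MArray",
    "ValidationError",
    "read_encounters",
    "write_encounters",
    "build_marray",
    "summarize",
]


class ValidationError(ValueError):
    """Raised when input data violate the study-design constraints."""


@dataclass(frozen=True)
class StudyDesign:
    """Daily-occasion study layout.

    Parameters
    ----------
    n_occasions:
        Number of daily occasions D; occasions are 1-based study days and
        every carcass shares the global window [1, D].
    release_occasions:
        Days on which releases occur (each in [1, D]).
    """

    n_occasions: int
    release_occasions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_occasions < 1:
            raise ValidationError("n_occasions must be >= 1")
        occs = tuple(sorted(set(int(o) for o in self.release_occasions)))
        object.__setattr__(self, "release_occasions", occs)
        for o in occs:
            if not 1 <= o <= self.n_occasions:
                raise ValidationError(
                    f"release occasion {o} outside study window [1, {self.n_occasions}]"
                )


@dataclass(frozen=True)
class EncounterRecord:
    """One carcass: release day and beaching day (None if never recovered)."""

    id: str
    release_day: int
    recovery_day: int | None = None

    @property
    def fate_label(self) -> str:
        return "beached" if self.recovery_day is not None else "lost"

    def validate(self, design: StudyDesign, row: object = None) -> None:
        where = f" (row {row})" if row is not None else f" (record {self.id!r})"
        D = design.n_occasions
        if not 1 <= self.release_day <= D:
            raise ValidationError(
                f"release_day {self.release_day} outside [1, {D}]{where}"
            )
        if self.recovery_day is not None:
            if self.recovery_day < self.release_day:
                raise ValidationError(
                    f"recovery_day {self.recovery_day} before release_day "
                    f"{self.release_day}{where}"
                )
            if self.recovery_day > D:
                raise ValidationError(
                    f"recovery_day {self.recovery_day} beyond study window [1, {D}]{where}"
                )


@dataclass(frozen=True)
class MArray:
    """Cohort-by-occasion recovery counts.

    ``R[i-1]`` carcasses released on occasion i, ``m[i-1, j-1]`` of them
    recovered on occasion j (j >= i), ``never[i-1]`` never recovered.
    Conservation: for every cohort, sum_j m_ij + never_i = R_i.
    """

    design: StudyDesign
    R: np.ndarray
    m: np.ndarray
    never: np.ndarray

    def __post_init__(self) -> None:
        D = self.design.n_occasions
        R = np.asarray(self.R, dtype=np.int64)
        m = np.asarray(self.m, dtype=np.int64)
        never = np.asarray(self.never, dtype=np.int64)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "never", never)
        if R.shape != (D,) or never.shape != (D,) or m.shape != (D, D):
            raise ValidationError("m-array shapes inconsistent with design")
        if (R < 0).any() or (m < 0).any() or (never < 0).any():
            raise ValidationError("negative counts in m-array")
        if np.tril(m, k=-1).any():
            raise ValidationError("recovery before release in m-array")
        if not np.array_equal(m.sum(axis=1) + never, R):
            raise ValidationError("m-array conservation violated: sum m_ij + never_i != R_i")

    @property
    def n_total(self) -> int:
        """Total carcasses released (the AICc effective sample size)."""
        return int(self.R.sum())

    @property
    def cohorts(self) -> np.ndarray:
        """1-based occasions with at least one release."""
        return np.flatnonzero(self.R > 0) + 1

    def fingerprint(self) -> bytes:
        return self.R.tobytes() + self.m.tobytes() + self.never.tobytes()

    def to_frame(self) -> pd.DataFrame:
        """Export as a table: one row per release occasion."""
        D = self.design.n_occasions
        df = pd.DataFrame(self.m, index=pd.Index(range(1, D + 1), name="release_day"),
                          columns=[str(j) for j in range(1, D + 1)])
        df["never"] = self.never
        df["released"] = self.R
        return df


Source = Union[str, IO[str]]


def read_encounters(source: Source, design: StudyDesign) -> list[EncounterRecord]:
    """Read encounter records from CSV (columns id,release_day,recovery_day).

    A blank recovery_day means the carcass was never recovered.  Extra
    columns (e.g. calendar dates) are ignored.  Malformed rows and days
    outside the study window raise :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(source, dtype={"id": str}, comment="#")
    required = {"id", "release_day", "recovery_day"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"CSV must have columns id,release_day,recovery_day; got {list(df.columns)}"
        )
    records: list[EncounterRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            release = int(row.release_day)
        except (TypeError, ValueError):
            raise ValidationError(f"malformed release_day {row.release_day!r} (row {row_no})")
        raw = row.recovery_day
        if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
            recovery = None
        else:
            try:
                recovery = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"malformed recovery_day {raw!r} (row {row_no})")
        rec = EncounterRecord(id=str(row.id), release_day=release, recovery_day=recovery)
        rec.validate(design, row=row_no)
        records.append(rec)
    return records


def write_encounters(records: Iterable[EncounterRecord], dest: Source) -> None:
    """Write records as the canonical encounter CSV (round-trips with read)."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "release_day": [r.release_day for r in records],
            "recovery_day": [
                "" if r.recovery_day is None else r.recovery_day for r in records
            ],
        }
    )
    df.to_csv(dest, index=False)


def build_marray(records: Sequence[EncounterRecord], design: StudyDesign) -> MArray:
    """Collapse encounter records into the m-array sufficient statistic."""
    D = design.n_occasions
    R = np.zeros(D, dtype=np.int64)
    m = np.zeros((D, D), dtype=np.int64)
    never = np.zeros(D, dtype=np.int64)
    for rec in records:
        rec.validate(design)
        i = rec.release_day - 1
        R[i] += 1
        if rec.recovery_day is None:
            never[i] += 1
        else:
            m[i, rec.recovery_day - 1] += 1
    return MArray(design=design, R=R, m=m, never=never)


def summarize(records: Sequence[EncounterRecord]) -> dict:
    """Crude beaching summary: counts and the observed beached fraction."""
    if not records:
        raise ValidationError("cannot summarize an empty record list")
    n = len(records)
    n_beached = sum(1 for r in records if r.recovery_day is not None)
    return {
        "n_released": n,
        "n_beached": n_beached,
        "n_lost": n - n_beached,
        "beached_fraction": n_beached / n,
    }
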