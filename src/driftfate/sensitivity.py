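"""Dataset perturbations probing the model assumptions.

Each operation returns a new record list implementing one of the study's
assumption checks: earlier beach-arrival times than first ground contact
(shift_arrivals), a stricter findability standard (reclassify_to_lost),
a missed beaching (reclassify_to_beached), and transmitter failure, which
makes some never-recovered carcasses unobservable rather than truly lost
and so shrinks the release denominator.  ``run_sensitivity`` reruns the
full candidate analysis on each perturbed variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .brownie import ModelSpec
from .data import EncounterRecord, StudyDesign, build_marray
from .derived import overall_beaching
from .fitting import FitOptions
from .selection import SelectionTable, run_candidate_analysis

__all__ = [
    "PerturbationSpec",
    "shift_arrivals",
    "reclassify_to_lost",
    "reclassify_to_beached",
    "transmitter_failure",
    "apply_perturbation",
    "run_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative description of one dataset perturbation."""

    kind: str  # shift_arrivals | reclassify_to_lost | reclassify_to_beached | transmitter_failure
    days: int = 0  # shift magnitude, or the new recovery day for reclassify_to_beached
    rate: float = 0.0  # transmitter failure rate
    ids: tuple[str, ...] = field(default=())
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        kinds = {"shift_arrivals", "reclassify_to_lost",
                 "reclassify_to_beached", "transmitter_failure"}
        if self.kind not in kinds:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.days < 0:
            raise ValueError("days must be >= 0")
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        object.__setattr__(self, "ids", tuple(self.ids))
        if not self.label:
            object.__setattr__(self, "label", self.kind)


def shift_arrivals(
    records: Sequence[EncounterRecord], k_days: int
) -> list[EncounterRecord]:
    """Move every recovery day k_days earlier, floored at the release day.

    Emulates carcasses having come ashore before ground crews first made
    contact.  Never-recovered records are unchanged.
    """
    if k_days < 0:
        raise ValueError("k_days must be >= 0")
    out = []
    for r in records:
        if r.recovery_day is None:
            out.append(r)
        else:
            out.append(
                EncounterRecord(r.id, r.release_day,
                                max(r.release_day, r.recovery_day - k_days))
            )
    return out


def _index_by_id(records: Sequence[EncounterRecord]) -> dict[str, EncounterRecord]:
    return {r.id: r for r in records}


def reclassify_to_lost(
    records: Sequence[EncounterRecord], ids: Iterable[str]
) -> list[EncounterRecord]:
    """Strip the recovery day from the given beached records (a stricter
    definition of findable)."""
    wanted = set(ids)
    by_id = _index_by_id(records)
    for i in wanted:
        if i not in by_id:
            raise ValueError(f"unknown record id {i!r}")
        if by_id[i].recovery_day is None:
            raise ValueError(f"record {i!r} is already lost")
    return [
        EncounterRecord(r.id, r.release_day, None) if r.id in wanted else r
        for r in records
    ]


def reclassify_to_beached(
    records: Sequence[EncounterRecord], rec_id: str, day: int,
    design: StudyDesign | None = None,
) -> list[EncounterRecord]:
    """Give one lost record a recovery day (a beaching the crews missed)."""
    by_id = _index_by_id(records)
    if rec_id not in by_id:
        raise ValueError(f"unknown record id {rec_id!r}")
    target = by_id[rec_id]
    if target.recovery_day is not None:
        raise ValueError(f"record {rec_id!r} is already beached")
    if day < target.release_day:
        raise ValueError(f"recovery day {day} before release day {target.release_day}")
    if design is not None and day > design.n_occasions:
        raise ValueError(f"recovery day {day} beyond study window")
    return [
        EncounterRecord(r.id, r.release_day, day) if r.id == rec_id else r
        for r in records
    ]


def transmitter_failure(
    records: Sequence[EncounterRecord], rate: float, seed: int = 0
) -> list[EncounterRecord]:
    """Remove round(rate * n) randomly chosen never-recovered records.

    Failed transmitters are indistinguishable from permanent losses, so the
    affected carcasses drop out of the release denominator entirely rather
    than being counted as true losses.  Deterministic given the seed.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n_remove = int(round(rate * len(records)))
    lost_ids = [r.id for r in records if r.recovery_day is None]
    if n_remove > len(lost_ids):
        raise ValueError(
            f"cannot remove {n_remove} records: only {len(lost_ids)} lost records"
        )
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(lost_ids, size=n_remove, replace=False))
    return [r for r in records if r.id not in drop]


def apply_perturbation(
    records: Sequence[EncounterRecord], p: PerturbationSpec,
    design: StudyDesign | None = None,
) -> list[EncounterRecord]:
    if p.kind == "shift_arrivals":
        return shift_arrivals(records, p.days)
    if p.kind == "reclassify_to_lost":
        return reclassify_to_lost(records, p.ids)
    if p.kind == "reclassify_to_beached":
        if len(p.ids) != 1:
            raise ValueError("reclassify_to_beached needs exactly one id")
        return reclassify_to_beached(records, p.ids[0], p.days, design)
    return transmitter_failure(records, p.rate, p.seed)


def run_sensitivity(
    records: Sequence[EncounterRecord],
    perturbations: Sequence[PerturbationSpec],
    design: StudyDesign,
    candidate_set: list[ModelSpec] | None = None,
    options: FitOptions | None = None,
) -> dict[str, dict]:
    """Rerun the candidate analysis on the baseline and on each perturbed
    variant independently (perturbations are not stacked).

    Returns per variant: the selection table, the best model name, and the
    overall beaching probability from the best fit.
    """
    results: dict[str, dict] = {}
    variants: list[tuple[str, Sequence[EncounterRecord]]] = [("baseline", list(records))]
    for p in perturbations:
        variants.append((p.label, apply_perturbation(records, p, design)))
    for label, recs in variants:
        try:
            marr = build_marray(recs, design)
            fits, table = run_candidate_analysis(marr, design, options,
                                                 candidates=candidate_set)
            best_name = table.best["model"]
            best_fit = fits[best_name]
            beta = overall_beaching(best_fit.estimates, np.inf, best_fit.spec)
            results[label] = {
                "table": table,
                "best_model": best_name,
                "beta": beta,
                "n_records": len(recs),
            }
        except Exception as exc:
            logger.warning("sensitivity variant %r failed: %s", label, exc)
            results[label] = {"error": str(exc)}
    return results
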