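"""Brownie dead-recovery model adapted to daily carcass fates.

Each day a floating carcass beaches with probability f, is permanently
lost (sinks, is scavenged, drifts out of the study area) with probability
omega = 1 - S - f, or remains afloat with probability S.  A carcass
released on day i and beached on day j (age a = j - i + 1) contributes the
multinomial cell probability

    P(i, j) = f_[class of beaching day] * prod over survived days of S_[class]

with beaching possible on the release day itself (b_1 = f).  The cohort's
remaining mass 1 - sum_j P(i, j) is the never-recovered cell.  Parameter
structures may be constant, fully time-dependent (indexed by calendar study
day), or age-dependent with contiguous age classes (indexed by days since
release, release day = age 1).

The log-likelihood omits multinomial coefficients (constant in the
parameters), so -2 log L is comparable across models and with the
saturated-model value computed here under the same convention; deviances
and AICc differences are unaffected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit, log_expit, logit

from .data import MArray, StudyDesign

__all__ = [
    "ParameterStructure",
    "ModelSpec",
    "ParameterVector",
    "CellModel",
    "cell_probability",
    "never_recovered_probability",
    "log_likelihood",
    "saturated_minus2logl",
    "build_candidate_set",
]


@dataclass(frozen=True)
class ParameterStructure:
    """Structure of one parameter (S or f) across days/ages.

    kind:
        "constant" — one value; "time" — one value per calendar study day;
        "age" — one value per age class, classes given by their starting
        ages (first must be 1, last class open-ended).
    """

    kind: str
    class_starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "time", "age"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.kind == "age":
            starts = tuple(int(s) for s in self.class_starts)
            if not starts or starts[0] != 1 or list(starts) != sorted(set(starts)):
                raise ValueError(
                    "age class starts must be strictly increasing and begin at 1"
                )
            object.__setattr__(self, "class_starts", starts)
        elif self.class_starts:
            raise ValueError("class_starts only meaningful for kind='age'")

    def n_classes(self, design: StudyDesign) -> int:
        if self.kind == "constant":
            return 1
        if self.kind == "time":
            return design.n_occasions
        return len(self.class_starts)

    def index(self, *, age: int, day: int) -> int:
        """0-based parameter class for a carcass of ``age`` on study ``day``."""
        if self.kind == "constant":
            return 0
        if self.kind == "time":
            return day - 1
        return int(np.searchsorted(self.class_starts, age, side="right")) - 1

    @staticmethod
    def constant() -> "ParameterStructure":
        return ParameterStructure("constant")

    @staticmethod
    def time() -> "ParameterStructure":
        return ParameterStructure("time")

    @staticmethod
    def age(class_starts: tuple[int, ...]) -> "ParameterStructure":
        return ParameterStructure("age", tuple(class_starts))

    @staticmethod
    def full_age(design: StudyDesign) -> "ParameterStructure":
        return ParameterStructure("age", tuple(range(1, design.n_occasions + 1)))


@dataclass(frozen=True)
class ModelSpec:
    """Named pair of S- and f-structures, e.g. ``S(.) f(age-2)``."""

    name: str
    S_structure: ParameterStructure
    f_structure: ParameterStructure

    def n_nominal(self, design: StudyDesign) -> int:
        return self.S_structure.n_classes(design) + self.f_structure.n_classes(design)

    def to_json(self) -> str:
        def enc(ps: ParameterStructure) -> dict:
            d: dict = {"kind": ps.kind}
            if ps.kind == "age":
                d["class_starts"] = list(ps.class_starts)
            return d

        return json.dumps(
            {"name": self.name, "S": enc(self.S_structure), "f": enc(self.f_structure)}
        )

    @staticmethod
    def from_json(text: str) -> "ModelSpec":
        obj = json.loads(text)

        def dec(d: dict) -> ParameterStructure:
            return ParameterStructure(d["kind"], tuple(d.get("class_starts", ())))

        return ModelSpec(obj["name"], dec(obj["S"]), dec(obj["f"]))


@dataclass(frozen=True)
class ParameterVector:
    """Real-scale S and f values per class, with logit-link accessors."""

    S_values: tuple[float, ...]
    f_values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "S_values", tuple(float(v) for v in self.S_values))
        object.__setattr__(self, "f_values", tuple(float(v) for v in self.f_values))
        for v in self.S_values + self.f_values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability {v} outside [0, 1]")

    @property
    def link_values(self) -> np.ndarray:
        return logit(np.concatenate([self.S_values, self.f_values]))

    @staticmethod
    def from_link(eta: np.ndarray, n_S: int) -> "ParameterVector":
        eta = np.asarray(eta, dtype=float)
        return ParameterVector(tuple(expit(eta[:n_S])), tuple(expit(eta[n_S:])))

    @staticmethod
    def constant(S: float, f: float) -> "ParameterVector":
        return ParameterVector((S,), (f,))


class CellModel:
    """Precomputed cell structure for one (spec, design) pair.

    Flattens all admissible cells (i, j), i <= j <= D, and stores for each
    the f-class index and the per-S-class counts of survived days, so the
    log cell probability is an affine map of (log S, log f) and both the
    likelihood and its gradient are vectorized.
    """

    def __init__(self, spec: ModelSpec, design: StudyDesign):
        self.spec = spec
        self.design = design
        D = design.n_occasions
        self.n_S = spec.S_structure.n_classes(design)
        self.n_f = spec.f_structure.n_classes(design)
        cell_i, cell_j, f_idx = [], [], []
        rows = []
        for i in range(1, D + 1):
            for j in range(i, D + 1):
                a = j - i + 1
                cell_i.append(i)
                cell_j.append(j)
                f_idx.append(spec.f_structure.index(age=a, day=j))
                counts = np.zeros(self.n_S)
                for k in range(1, a):  # survived days: ages 1..a-1, days i..j-1
                    counts[spec.S_structure.index(age=k, day=i + k - 1)] += 1
                rows.append(counts)
        self.cell_i = np.array(cell_i)
        self.cell_j = np.array(cell_j)
        self.f_idx = np.array(f_idx)
        self.S_counts = np.vstack(rows)  # (n_cells, n_S)
        # cells are emitted cohort-major: reduceat boundaries per cohort
        self.cohort_starts = np.searchsorted(self.cell_i, np.arange(1, D + 1))
        self.cell_cohort = self.cell_i - 1

    # -- probabilities on the real scale ------------------------------------

    def log_cell_probs(self, log_S: np.ndarray, log_f: np.ndarray) -> np.ndarray:
        return log_f[self.f_idx] + self.S_counts @ log_S

    def cell_probs_matrix(self, params: ParameterVector) -> np.ndarray:
        """(D, D) matrix of P(i, j); zero where j < i."""
        with np.errstate(divide="ignore"):
            lp = self.log_cell_probs(
                np.log(np.asarray(params.S_values)), np.log(np.asarray(params.f_values))
            )
        D = self.design.n_occasions
        out = np.zeros((D, D))
        out[self.cell_i - 1, self.cell_j - 1] = np.exp(lp)
        return out

    def never_probs(self, params: ParameterVector) -> np.ndarray:
        """Per-cohort probability of never being recovered within [i, D]."""
        return 1.0 - self.cell_probs_matrix(params).sum(axis=1)

    # -- likelihood on the link scale ---------------------------------------

    def negloglik_and_grad(
        self, eta: np.ndarray, marray: MArray
    ) -> tuple[float, np.ndarray]:
        """Negative log-likelihood and analytic gradient at link values eta.

        S + f <= 1 is not enforced; if a cohort's recovery mass exceeds 1
        the never-recovered probability is clipped to a tiny positive value,
        which yields a large finite penalty steering the optimizer back.
        """
        n_S = self.n_S
        log_S = log_expit(eta[:n_S])
        log_f = log_expit(eta[n_S:])
        lp = self.log_cell_probs(log_S, log_f)
        p = np.exp(lp)
        m_flat = marray.m[self.cell_i - 1, self.cell_j - 1].astype(float)
        never = marray.never.astype(float)

        cohort_mass = np.add.reduceat(p, self.cohort_starts)
        p_never = np.clip(1.0 - cohort_mass, 1e-300, None)

        nll = -(m_flat @ lp + never @ np.log(p_never))

        # d log p_cell / d eta: for S class c, (1 - S_c) * S_counts[:, c];
        # for f class c, (1 - f_c) * [f_idx == c].  The never-cell term
        # d log p_never_i / d eta = -(sum_cells p * dlogp) / p_never_i folds
        # into a single per-cell coefficient m - (never_i / p_never_i) * p.
        one_m_S = expit(-eta[:n_S])
        one_m_f = expit(-eta[n_S:])
        coef = m_flat - (never / p_never)[self.cell_cohort] * p
        grad = np.empty_like(eta)
        grad[:n_S] = (coef @ self.S_counts) * one_m_S
        grad[n_S:] = np.bincount(
            self.f_idx, weights=coef, minlength=self.n_f
        ) * one_m_f
        return nll, -grad


@lru_cache(maxsize=64)
def _cached_cell_model(spec: ModelSpec, design: StudyDesign) -> CellModel:
    return CellModel(spec, design)


def get_cell_model(spec: ModelSpec, design: StudyDesign) -> CellModel:
    """Memoized CellModel (precomputation is per structure, not per dataset)."""
    return _cached_cell_model(spec, design)


def cell_probability(
    spec: ModelSpec,
    params: ParameterVector,
    design: StudyDesign,
    release_day: int,
    recovery_day: int,
) -> float:
    """P(released day i, beached day j) under the given structure."""
    D = design.n_occasions
    i, j = release_day, recovery_day
    if not (1 <= i <= j <= D):
        raise ValueError(f"require 1 <= release {i} <= recovery {j} <= {D}")
    a = j - i + 1
    f = params.f_values[spec.f_structure.index(age=a, day=j)]
    prod = f
    for k in range(1, a):
        prod *= params.S_values[spec.S_structure.index(age=k, day=i + k - 1)]
    return prod


def never_recovered_probability(
    spec: ModelSpec, params: ParameterVector, design: StudyDesign, release_day: int
) -> float:
    """1 minus the total beaching probability over the cohort's window."""
    D = design.n_occasions
    if not 1 <= release_day <= D:
        raise ValueError(f"release day {release_day} outside [1, {D}]")
    total = sum(
        cell_probability(spec, params, design, release_day, j)
        for j in range(release_day, D + 1)
    )
    return 1.0 - total


def log_likelihood(marray: MArray, spec: ModelSpec, params: ParameterVector) -> float:
    """Multinomial log-likelihood of the m-array (coefficients omitted).

    Returns -inf with a warning if an observed count sits in a
    zero-probability cell.
    """
    cm = get_cell_model(spec, marray.design)
    P = cm.cell_probs_matrix(params)
    p_never = 1.0 - P.sum(axis=1)
    total = 0.0
    obs = marray.m.astype(float)
    with np.errstate(divide="ignore"):
        logP = np.log(P, out=np.full_like(P, -np.inf), where=P > 0)
    bad = (obs > 0) & (P <= 0)
    if bad.any() or ((marray.never > 0) & (p_never <= 0)).any():
        warnings.warn("observed count in zero-probability cell; log-likelihood is -inf")
        return -np.inf
    total += float((obs * np.where(obs > 0, logP, 0.0)).sum())
    nz = marray.never > 0
    total += float((marray.never[nz] * np.log(p_never[nz])).sum())
    return total


def saturated_minus2logl(marray: MArray) -> float:
    """-2 log L of the saturated model (empirical cell proportions).

    Cells with zero counts contribute zero; cohorts with all carcasses in
    one cell (e.g. all never recovered) contribute zero.
    """
    total = 0.0
    D = marray.design.n_occasions
    for i in range(D):
        R = marray.R[i]
        if R == 0:
            continue
        counts = np.concatenate([marray.m[i], [marray.never[i]]]).astype(float)
        nz = counts > 0
        total += float((counts[nz] * np.log(counts[nz] / R)).sum())
    return -2.0 * total


def build_candidate_set(design: StudyDesign) -> list[ModelSpec]:
    """The 14 candidate S/f structures considered for the drift data.

    Constant, fully time-dependent, fully age-dependent, and reduced
    age-class structures for the beaching rate (reflecting the expectation
    that beaching odds change over the first few days adrift), plus two
    age-structured survival variants.
    """
    c = ParameterStructure.constant()
    t = ParameterStructure.time()
    age = ParameterStructure.age
    full = ParameterStructure.full_age(design)
    return [
        ModelSpec("S(.) f(.)", c, c),
        ModelSpec('S(.) f(age-4 w/1st "age" = 2 days)', c, age((1, 3, 4, 5))),
        ModelSpec("S(.) f(age-2)", c, age((1, 2))),
        ModelSpec("S(.) f(age-3)", c, age((1, 2, 3))),
        ModelSpec("S(.) f(age-5)", c, age((1, 2, 3, 4, 5))),
        ModelSpec('S(.) f(age-4 w/1st 2 "age" classes = 2 days)', c, age((1, 3, 5, 6))),
        ModelSpec("S(age-3) f(.)", age((1, 2, 3)), c),
        ModelSpec("S(.) f(age-4)", c, age((1, 2, 3, 4))),
        ModelSpec("S(age) f(age)", full, full),
        ModelSpec("S(age) f(.)", full, c),
        ModelSpec("S(.) f(t)", c, t),
        ModelSpec("S(.) f(age)", c, full),
        ModelSpec("S(t) f(.)", t, c),
        ModelSpec("S(t) f(t)", t, t),
    ]
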