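"""Quantities derived from the daily fate probabilities.

From daily at-sea survival S and beaching rate f follow: the daily loss
rate omega = 1 - S - f; the probability b_i = f * S**(i-1) of floating
i - 1 days then beaching on day i (age-generalized for class-structured f);
the overall beaching probability beta = sum_i b_i (closed form f/(1-S) for
the constant model at infinite horizon); the cumulative probability of
being lost at sea by day d, omega * (1 - S**d) / (1 - S); and the
probability S**d of still floating after d days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brownie import ModelSpec, ParameterStructure, ParameterVector
from .fitting import FitResult

__all__ = [
    "DerivedEstimates",
    "daily_loss",
    "beach_day_prob",
    "overall_beaching",
    "cumulative_loss",
    "survival_to_day",
    "derive",
    "b_series_frame",
]


def daily_loss(S: float, f: float) -> float:
    """omega = 1 - S - f; error if the three fates are not a distribution."""
    if not (0.0 <= S <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("S and f must be probabilities")
    omega = 1.0 - S - f
    if omega < -1e-12:
        raise ValueError(f"invalid fate probabilities: S + f = {S + f:.6f} > 1")
    return max(omega, 0.0)


def _classes(spec: ModelSpec | None):
    """(S starts, f starts) for age-style evaluation; constant => (1,)."""
    if spec is None:
        return (1,), (1,)
    for ps in (spec.S_structure, spec.f_structure):
        if ps.kind == "time":
            raise ValueError(
                "time-structured parameters have no age-indexed beaching series; "
                "use a finite horizon within the study window"
            )
    S_starts = spec.S_structure.class_starts or (1,)
    f_starts = spec.f_structure.class_starts or (1,)
    return S_starts, f_starts


def _class_of(starts: tuple[int, ...], age: int) -> int:
    return int(np.searchsorted(starts, age, side="right")) - 1


def beach_day_prob(
    params: ParameterVector, i: int, spec: ModelSpec | None = None
) -> float:
    """b_i: float i - 1 days then beach on day i.

    Constant model: f * S**(i-1).  Age-structured: f_{class(i)} *
    prod_{k<i} S_{class(k)}.
    """
    if i < 1:
        raise ValueError("day index must be >= 1")
    S_starts, f_starts = _classes(spec)
    b = params.f_values[_class_of(f_starts, i)]
    for k in range(1, i):
        b *= params.S_values[_class_of(S_starts, k)]
    return b


def overall_beaching(
    params: ParameterVector,
    horizon: int | float = np.inf,
    spec: ModelSpec | None = None,
) -> float:
    """beta = sum_{i=1}^{horizon} b_i, the probability of ever beaching.

    The infinite-horizon sum uses the geometric closed form once both
    structures reach their terminal class: constant model beta = f/(1-S).
    """
    S_starts, f_starts = _classes(spec)
    if np.isinf(horizon):
        a0 = max(S_starts[-1], f_starts[-1])
        S_term = params.S_values[_class_of(S_starts, a0)]
        if S_term >= 1.0:
            f_term = params.f_values[_class_of(f_starts, a0)]
            if f_term > 0:
                raise ValueError("S = 1 with f > 0: infinite-horizon sum undefined")
            S_term = 0.0  # nothing ever beaches past the head
        head = sum(beach_day_prob(params, i, spec) for i in range(1, a0))
        tail = beach_day_prob(params, a0, spec) / (1.0 - S_term)
        return head + tail
    horizon = int(horizon)
    if horizon < 1:
        raise ValueError("horizon must be a positive integer or infinite")
    total = 0.0
    afloat = 1.0  # running product of survival up to age a - 1
    for a in range(1, horizon + 1):
        total += params.f_values[_class_of(f_starts, a)] * afloat
        afloat *= params.S_values[_class_of(S_starts, a)]
    return total


def cumulative_loss(S: float, omega: float, d: int | float) -> float:
    """Probability of being permanently lost by day d:
    sum_{x=1}^{d} S**(x-1) * omega = omega * (1 - S**d) / (1 - S)."""
    if d < 1 and not np.isinf(d):
        raise ValueError("d must be >= 1")
    if S >= 1.0:
        return 0.0 if omega == 0 else float(omega * d)
    if np.isinf(d):
        return omega / (1.0 - S)
    return float(omega * (1.0 - S ** int(d)) / (1.0 - S))


def survival_to_day(S: float, d: int) -> float:
    """Probability of still floating after d days: S**d."""
    if d < 0:
        raise ValueError("d must be >= 0")
    return float(S) ** int(d)


@dataclass(frozen=True)
class DerivedEstimates:
    """Derived fate summary for one parameter set."""

    S: tuple[float, ...]
    f: tuple[float, ...]
    omega: tuple[float, ...]
    b_series: tuple[float, ...]
    beta: float
    horizon: int | float

    @property
    def constant(self) -> bool:
        return len(self.S) == 1 and len(self.f) == 1


def derive(
    source: FitResult | ParameterVector,
    horizon: int | float = np.inf,
    b_days: int = 35,
    spec: ModelSpec | None = None,
) -> DerivedEstimates:
    """Compute omega, the b_i series, and beta from estimates.

    ``source`` may be a FitResult (its structure is used) or a bare
    ParameterVector with an optional explicit structure.
    """
    if isinstance(source, FitResult):
        params, spec = source.estimates, source.spec
    else:
        params = source
    S_starts, f_starts = _classes(spec)
    ages = sorted(set(S_starts) | set(f_starts))
    omega = tuple(
        daily_loss(
            params.S_values[_class_of(S_starts, a)],
            params.f_values[_class_of(f_starts, a)],
        )
        for a in ages
    )
    b = tuple(beach_day_prob(params, i, spec) for i in range(1, b_days + 1))
    beta = overall_beaching(params, horizon, spec)
    return DerivedEstimates(
        S=params.S_values, f=params.f_values, omega=omega,
        b_series=b, beta=beta, horizon=horizon,
    )


def b_series_frame(est: DerivedEstimates) -> pd.DataFrame:
    """b_i series as a table (day, probability of beaching on that day)."""
    days = np.arange(1, len(est.b_series) + 1)
    return pd.DataFrame({"day": days, "b_i": est.b_series})
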