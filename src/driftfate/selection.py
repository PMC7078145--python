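"""AICc model selection: ranked tables with deltas, Akaike weights and
model likelihoods over the candidate structure set."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brownie import ModelSpec, build_candidate_set
from .data import MArray, StudyDesign
from .fitting import FitOptions, FitResult, fit

__all__ = ["SelectionTable", "aicc", "build_table", "run_candidate_analysis"]

logger = logging.getLogger(__name__)


def aicc(minus2logl: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 log L + 2K + 2K(K+1)/(n - K - 1), with n the number of
    carcasses released.  Undefined (error) when n <= K + 1.
    """
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return float(minus2logl + 2 * K + 2 * K * (K + 1) / (n - K - 1))


@dataclass(frozen=True)
class SelectionTable:
    """Models ranked by AICc with deltas, weights and model likelihoods."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.frame["weight"].to_numpy()
        assert abs(w.sum() - 1.0) < 1e-9

    @property
    def best(self) -> pd.Series:
        return self.frame.iloc[0]

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, dest) -> None:
        self.frame.to_csv(dest, index=False)


def build_table(fits: list[FitResult]) -> SelectionTable:
    """Assemble the ranked selection table from fits on one dataset.

    Delta = AICc - min AICc; model likelihood = exp(-Delta/2); weights are
    the model likelihoods normalized over the table.  Ties in AICc are
    broken by smaller K, then name.
    """
    if not fits:
        raise ValueError("need at least one fit")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were computed on differing m-arrays")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.spec.name,
                "AICc": aicc(f.minus2logl, f.K, f.n_effective),
                "n_params": f.K,
                "deviance": f.deviance,
                "minus2logL": f.minus2logl,
                "converged": f.converged,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "n_params", "model"], kind="mergesort"
    ).reset_index(drop=True)
    delta = df["AICc"] - df["AICc"].iloc[0]
    like = np.exp(-delta / 2.0)
    df.insert(2, "delta_AICc", delta)
    df.insert(3, "weight", like / like.sum())
    df.insert(4, "model_likelihood", like)
    df = df[["model", "AICc", "delta_AICc", "weight", "model_likelihood",
             "n_params", "deviance", "minus2logL", "converged"]]
    return SelectionTable(df)


def run_candidate_analysis(
    marray: MArray,
    design: StudyDesign | None = None,
    options: FitOptions | None = None,
    candidates: list[ModelSpec] | None = None,
) -> tuple[dict[str, FitResult], SelectionTable]:
    """Fit every candidate structure and rank them by AICc.

    Per-model failures are logged and excluded; an error is raised only if
    every fit fails.
    """
    design = design or marray.design
    specs = candidates if candidates is not None else build_candidate_set(design)
    fits: dict[str, FitResult] = {}
    for spec in specs:
        try:
            fits[spec.name] = fit(marray, spec, options)
        except Exception as exc:
            logger.warning("fit of %s failed: %s", spec.name, exc)
    if not fits:
        raise RuntimeError("all candidate fits failed")
    return fits, build_table(list(fits.values()))
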