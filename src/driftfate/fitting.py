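"""Maximum-likelihood fitting, Wald intervals, identifiability, and
parametric-bootstrap goodness of fit.

Parameters are estimated on the logit scale by quasi-Newton search
(L-BFGS-B with the analytic gradient) from several jittered moment-style
starting points.  The observed information is the finite-difference
Hessian of the negative log-likelihood at the optimum; its spectrum gives
both the Wald standard errors and the count of statistically identifiable
parameters (fully time-dependent structures confound the terminal survival
and recovery rates, so the effective count can fall below the nominal one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .brownie import (
    CellModel,
    ModelSpec,
    ParameterVector,
    get_cell_model,
    saturated_minus2logl,
)
from .data import MArray

__all__ = ["FitOptions", "FitResult", "fit", "wald_ci", "count_identifiable",
           "bootstrap_gof", "simulate_marray_from_fit"]

logger = logging.getLogger(__name__)

#: |logit| cap keeping boundary fits finite; hits are flagged.
LINK_CAP = 15.0
#: relative eigenvalue threshold below which a direction is non-identifiable
IDENT_TOL = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings; ``seed`` controls the start-point jitter only."""

    n_starts: int = 5
    seed: int = 0
    link_cap: float = LINK_CAP
    jitter_sd: float = 0.5
    gtol: float = 1e-8
    ident_tol: float = IDENT_TOL
    compute_se: bool = True


@dataclass(frozen=True)
class FitResult:
    """MLE of one model on one m-array."""

    spec: ModelSpec
    estimates: ParameterVector
    se: np.ndarray | None  # link scale, NaN where information is singular
    ci95: list[tuple[float, float]] | None  # real scale
    minus2logl: float
    K: int
    deviance: float
    converged: bool
    n_effective: int
    boundary: bool = False
    n_S: int = 0
    data_fingerprint: bytes = b""
    info: np.ndarray | None = field(default=None, repr=False)
    boundary_mask: np.ndarray | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "spec": self.spec.to_json(),
            "S_values": list(self.estimates.S_values),
            "f_values": list(self.estimates.f_values),
            "se_link": None if self.se is None else [
                None if not np.isfinite(v) else float(v) for v in self.se
            ],
            "ci95": self.ci95,
            "minus2logl": self.minus2logl,
            "K": self.K,
            "deviance": self.deviance,
            "AICc_n": self.n_effective,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _moment_start(cm: CellModel, marray: MArray, cap: float) -> np.ndarray:
    """Crude moment-style initial link values shared by all classes.

    S0 from the mean age at recovery (geometric mean ~ 1/(1-S)); f0 from
    the overall recovered fraction r via beta ~ f/(1-S) ~ r.
    """
    rows, cols = np.nonzero(marray.m)
    if rows.size:
        ages = cols - rows + 1
        weights = marray.m[rows, cols]
        mean_age = float((ages * weights).sum() / weights.sum())
    else:
        mean_age = 2.0
    S0 = float(np.clip(1.0 - 1.0 / max(mean_age, 1.05), 0.05, 0.95))
    n = max(marray.n_total, 1)
    r = marray.m.sum() / n
    f0 = float(np.clip(r * (1.0 - S0), 1e-4, 0.5))
    eta = np.empty(cm.n_S + cm.n_f)
    eta[: cm.n_S] = np.log(S0 / (1 - S0))
    eta[cm.n_S:] = np.log(f0 / (1 - f0))
    return np.clip(eta, -cap, cap)


def _hessian_fd(fun, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Symmetric finite-difference Hessian from an analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = step
        gp = fun(x + e)[1]
        gm = fun(x - e)[1]
        H[k] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def fit(marray: MArray, spec: ModelSpec, options: FitOptions | None = None) -> FitResult:
    """Fit one model structure to an m-array by maximum likelihood.

    Deterministic given ``options.seed``.  If no start converges the best
    point found is returned with ``converged=False`` and a warning logged.
    """
    opt = options or FitOptions()
    cm = get_cell_model(spec, marray.design)
    nll = lambda eta: cm.negloglik_and_grad(eta, marray)
    cap = opt.link_cap
    bounds = [(-cap, cap)] * (cm.n_S + cm.n_f)
    base = _moment_start(cm, marray, cap)
    rng = np.random.default_rng(opt.seed)

    best = None
    any_converged = False
    for s in range(max(opt.n_starts, 1)):
        x0 = base if s == 0 else np.clip(
            base + rng.normal(0.0, opt.jitter_sd, base.size), -cap, cap
        )
        res = minimize(nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 2000, "ftol": 1e-12, "gtol": opt.gtol})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        any_converged = any_converged or bool(res.success)
    assert best is not None
    if not any_converged:
        logger.warning("fit of %s: no start converged; returning best point", spec.name)

    eta_hat = np.asarray(best.x)
    boundary = bool(np.any(np.abs(eta_hat) >= cap - 1e-6))
    estimates = ParameterVector.from_link(eta_hat, cm.n_S)
    minus2logl = 2.0 * float(best.fun)
    deviance = minus2logl - saturated_minus2logl(marray)

    se = None
    ci95 = None
    info = None
    bmask = np.abs(eta_hat) >= cap - 1e-6
    K = cm.n_S + cm.n_f
    if opt.compute_se:
        info = _hessian_fd(nll, eta_hat)  # observed information, link scale
        K = _count_identifiable(info, bmask, opt.ident_tol)
        se = _se_from_info(info)
        ci95 = _wald_ci_from_link(eta_hat, se)

    return FitResult(
        spec=spec,
        estimates=estimates,
        se=se,
        ci95=ci95,
        minus2logl=minus2logl,
        K=K,
        deviance=deviance,
        converged=any_converged,
        n_effective=marray.n_total,
        boundary=boundary,
        n_S=cm.n_S,
        data_fingerprint=marray.fingerprint(),
        info=info,
        boundary_mask=bmask,
    )


def _se_from_info(info: np.ndarray) -> np.ndarray:
    """Link-scale SEs from the inverse observed information.

    Uses the pseudo-inverse; parameters whose diagonal variance is not
    positive (singular information) get NaN.
    """
    try:
        cov = np.linalg.pinv(info, hermitian=True)
    except np.linalg.LinAlgError:
        return np.full(info.shape[0], np.nan)
    var = np.diag(cov).copy()
    # flag directions the data cannot estimate
    eigvals = np.linalg.eigvalsh(info)
    if eigvals.size and eigvals[0] <= IDENT_TOL * max(eigvals[-1], 0.0):
        null = np.linalg.eigh(info)[1][:, eigvals <= IDENT_TOL * max(eigvals[-1], 0.0)]
        involved = (np.abs(null) > 1e-6).any(axis=1)
        var[involved] = np.nan
    var[var <= 0] = np.nan
    return np.sqrt(var)


def _wald_ci_from_link(
    eta: np.ndarray, se: np.ndarray, level: float = 0.95
) -> list[tuple[float, float]]:
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    out = []
    for e, s in zip(eta, se):
        if not np.isfinite(s):
            out.append((np.nan, np.nan))
        else:
            out.append((float(expit(e - z * s)), float(expit(e + z * s))))
    return out


def wald_ci(fit_result: FitResult, level: float = 0.95) -> list[tuple[float, float]]:
    """Per-parameter Wald interval: logit-scale estimate +/- z*SE,
    back-transformed to (0, 1).  NaN bounds mark singular-information
    parameters."""
    if fit_result.se is None:
        raise ValueError("fit was run without standard errors (compute_se=False)")
    eta = fit_result.estimates.link_values
    return _wald_ci_from_link(eta, fit_result.se, level)


def _count_identifiable(info: np.ndarray, boundary_mask: np.ndarray, tol: float) -> int:
    """Identifiable parameter count for AICc.

    Parameters estimated at the link-scale boundary were driven there by
    the data (zero observed recoveries in their class) and count as
    estimated parameters.  Among interior parameters, identifiable
    directions are eigenvalues of the observed-information sub-block above
    ``tol`` times the largest — this drops both confounded combinations
    (e.g. terminal survival x recovery in fully time-dependent structures)
    and parameter classes whose likelihood is entirely flat because no
    carcass was ever at risk in them.
    """
    k_boundary = int(boundary_mask.sum())
    interior = ~boundary_mask
    if not interior.any():
        return k_boundary
    sub = info[np.ix_(interior, interior)]
    eigvals = np.linalg.eigvalsh(sub)
    lam_max = float(eigvals[-1])
    if lam_max <= 0:
        return k_boundary
    return k_boundary + int((eigvals > tol * lam_max).sum())


def count_identifiable(fit_result: FitResult, ident_tol: float = IDENT_TOL) -> int:
    """Number of identifiable parameters (the AICc K); see
    :func:`_count_identifiable` for the convention."""
    if fit_result.info is None:
        raise ValueError("fit was run without the information matrix")
    return _count_identifiable(fit_result.info, fit_result.boundary_mask, ident_tol)


def simulate_marray_from_fit(
    fit_result: FitResult, marray: MArray, rng: np.random.Generator
) -> MArray:
    """Draw one dataset from the fitted model with the same release schedule,
    as per-cohort multinomial draws over (recovery day 1..D, never)."""
    cm = get_cell_model(fit_result.spec, marray.design)
    P = cm.cell_probs_matrix(fit_result.estimates)
    D = marray.design.n_occasions
    m = np.zeros((D, D), dtype=np.int64)
    never = np.zeros(D, dtype=np.int64)
    for i in range(D):
        R = int(marray.R[i])
        if R == 0:
            continue
        probs = np.append(P[i], max(1.0 - P[i].sum(), 0.0))
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        draw = rng.multinomial(R, probs)
        m[i] = draw[:D]
        never[i] = draw[D]
    return MArray(design=marray.design, R=marray.R.copy(), m=m, never=never)


def bootstrap_gof(
    marray: MArray,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    options: FitOptions | None = None,
) -> dict:
    """Parametric bootstrap goodness-of-fit test.

    Simulates ``B`` datasets from the fitted model (same release schedule),
    refits, and compares the observed deviance with the bootstrap deviance
    distribution: P = (1 + #{dev_b >= dev_obs}) / (B + 1).  Refit failures
    are dropped with a logged count.
    """
    if B <= 0:
        raise ValueError("B must be a positive integer")
    opt = options or FitOptions(n_starts=2, compute_se=False)
    base_fit = fit(marray, spec, replace(opt, seed=seed))
    rng = np.random.default_rng(seed)
    devs = []
    failures = 0
    for b in range(B):
        sim = simulate_marray_from_fit(base_fit, marray, rng)
        try:
            refit = fit(sim, spec, replace(opt, seed=seed + b + 1, compute_se=False))
        except Exception:  # pragma: no cover - defensive
            failures += 1
            continue
        devs.append(refit.deviance)
    if failures:
        logger.warning("bootstrap_gof: %d of %d refits failed and were dropped",
                       failures, B)
    devs_arr = np.asarray(devs)
    n_ok = devs_arr.size
    P = (1.0 + float((devs_arr >= base_fit.deviance - 1e-9).sum())) / (n_ok + 1.0)
    return {
        "P": P,
        "observed_deviance": base_fit.deviance,
        "bootstrap_deviances": devs_arr,
        "n_failures": failures,
        "fit": base_fit,
    }
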