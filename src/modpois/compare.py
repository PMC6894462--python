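"""Logistic and log-binomial comparators for the modified Poisson fit.

Two methodological contrasts matter when the outcome is common:

* Logistic regression estimates an odds ratio.  The OR approximates the
  risk ratio only when the outcome is rare; with a common outcome it is
  further from the null, overstating (for protective exposures,
  amplifying) the effect.
* Log-binomial regression targets the risk ratio directly via the
  binomial likelihood with a log link, but its Newton update divides by
  1 - exp(Z_i' beta), so the all-zero start fails immediately (every
  denominator is exactly zero), and iterates that push any fitted risk
  to or past 1 fail at the boundary.  Modified Poisson regression has
  neither problem: its score does not involve that denominator.

Both comparators share the Newton machinery of :mod:`modpois.model`
(log-binomial uses Fisher scoring, i.e. the expected information) so
that failures are attributable to the model, not the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .errors import (
    ConfigurationError,
    ModPoisError,
    NonConvergenceError,
    SingularSystemError,
)
from .model import (
    ConvergenceConfig,
    DesignData,
    FitResult,
    ModelSpec,
    _linear_predictor,
    check_convergence,
    fit_pooled,
    newton_step,
)

EXPOSURE_INDEX = 1

# failure taxonomy for the log-binomial comparator
ZERO_DENOMINATOR = "zero-denominator"
BOUNDARY = "boundary"
SINGULAR_MATRIX = "singular-matrix"
NON_CONVERGENCE = "non-convergence"


@dataclass
class ComparisonResult:
    """Outcome of one comparator fit: estimates or a structured failure."""

    method: str
    converged: bool
    estimates: Optional[dict[str, float]]
    exposure_effect: Optional[float]
    effect_scale: str  # "OR" or "RR"
    failure_reason: Optional[str] = None
    n_iterations: int = 0
    se: Optional[dict[str, float]] = None

    def __post_init__(self):
        if (self.estimates is None) == (self.failure_reason is None):
            raise ConfigurationError(
                "exactly one of estimates and failure_reason must be populated"
            )


def _names(data: DesignData, term_names: Optional[Sequence[str]]) -> list[str]:
    return list(term_names) if term_names else [f"b{l}" for l in range(data.p)]


def fit_logistic(
    data: DesignData,
    cfg: Optional[ConvergenceConfig] = None,
    term_names: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Maximum-likelihood logistic regression; reports exp(beta_E) as an OR."""
    cfg = cfg or ConvergenceConfig()
    y = data.require_outcome()
    names = _names(data, term_names)
    beta = np.zeros(data.p)
    r = 0
    try:
        for r in range(1, cfg.max_iterations + 1):
            mu = expit(_linear_predictor(data.Z, beta))
            S = data.Z.T @ (y - mu)
            w = mu * (1.0 - mu)
            H = -(data.Z * w[:, None]).T @ data.Z
            H = 0.5 * (H + H.T)
            beta_new = newton_step(beta, S, H)
            converged, _ = check_convergence(beta, beta_new, cfg)
            beta = beta_new
            if converged:
                cov = np.linalg.inv(-H)
                return ComparisonResult(
                    method="logistic",
                    converged=True,
                    estimates=dict(zip(names, map(float, beta))),
                    exposure_effect=float(np.exp(beta[EXPOSURE_INDEX])),
                    effect_scale="OR",
                    n_iterations=r,
                    se=dict(zip(names, map(float, np.sqrt(np.diag(cov))))),
                )
    except SingularSystemError:
        return ComparisonResult(
            method="logistic", converged=False, estimates=None,
            exposure_effect=None, effect_scale="OR",
            failure_reason=SINGULAR_MATRIX, n_iterations=r,
        )
    # perfect separation shows up as drifting coefficients, not a stop
    return ComparisonResult(
        method="logistic", converged=False, estimates=None,
        exposure_effect=None, effect_scale="OR",
        failure_reason=NON_CONVERGENCE, n_iterations=cfg.max_iterations,
    )


def fit_logbinomial(
    data: DesignData,
    cfg: Optional[ConvergenceConfig] = None,
    beta0: Optional[np.ndarray] = None,
    term_names: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Binomial likelihood with log link, fit by Fisher scoring.

    The score is sum_i Z_i (Y_i - mu_i) / (1 - mu_i) with mu_i =
    exp(Z_i' beta); the expected information is sum_i Z_i Z_i' mu_i /
    (1 - mu_i).  ``beta0`` must be supplied: no safe default exists,
    because beta0 = 0 makes every denominator 1 - exp(0) exactly zero.
    Failures are returned as structured categories, never raised.
    """
    cfg = cfg or ConvergenceConfig()
    y = data.require_outcome()
    names = _names(data, term_names)
    if beta0 is None:
        raise ConfigurationError(
            "log-binomial regression requires an explicit starting value; "
            "beta0 = 0 fails at once (1 - exp(0) = 0 in every denominator)"
        )
    beta = np.asarray(beta0, dtype=float).copy()
    if beta.shape != (data.p,):
        raise ConfigurationError(f"beta0 has shape {beta.shape}, expected ({data.p},)")

    def failure(reason, it):
        return ComparisonResult(
            method="log-binomial", converged=False, estimates=None,
            exposure_effect=None, effect_scale="RR",
            failure_reason=reason, n_iterations=it,
        )

    r = 0
    for r in range(1, cfg.max_iterations + 1):
        eta = _linear_predictor(data.Z, beta)
        if np.any(eta == 0.0):
            return failure(ZERO_DENOMINATOR, r)
        if np.any(eta > 0.0):
            return failure(BOUNDARY, r)
        mu = np.exp(eta)
        denom = 1.0 - mu
        S = data.Z.T @ ((y - mu) / denom)
        w = mu / denom
        info = (data.Z * w[:, None]).T @ data.Z
        info = 0.5 * (info + info.T)
        try:
            beta_new = newton_step(beta, S, -info)
        except SingularSystemError:
            return failure(SINGULAR_MATRIX, r)
        converged, _ = check_convergence(beta, beta_new, cfg)
        beta = beta_new
        if converged:
            cov = np.linalg.inv(info)
            return ComparisonResult(
                method="log-binomial", converged=True,
                estimates=dict(zip(names, map(float, beta))),
                exposure_effect=float(np.exp(beta[EXPOSURE_INDEX])),
                effect_scale="RR", n_iterations=r,
                se=dict(zip(names, map(float, np.sqrt(np.diag(cov))))),
            )
    return failure(NON_CONVERGENCE, cfg.max_iterations)


def fit_modified_poisson(
    data: DesignData,
    cfg: Optional[ConvergenceConfig] = None,
    beta0: Optional[np.ndarray] = None,
    term_names: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Modified Poisson fit wrapped in the common comparison container."""
    names = _names(data, term_names)
    try:
        fit = fit_pooled(data, cfg=cfg, beta0=beta0, term_names=names)
    except NonConvergenceError as exc:
        return ComparisonResult(
            method="modified-poisson", converged=False, estimates=None,
            exposure_effect=None, effect_scale="RR",
            failure_reason=NON_CONVERGENCE, n_iterations=len(exc.trace),
        )
    return ComparisonResult(
        method="modified-poisson", converged=True,
        estimates=dict(zip(names, map(float, fit.beta))),
        exposure_effect=float(np.exp(fit.beta[EXPOSURE_INDEX])),
        effect_scale="RR", n_iterations=fit.n_iterations,
        se=dict(zip(names, map(float, fit.se))),
    )


def starting_value_report(
    data: DesignData,
    starts: Mapping[str, np.ndarray],
    cfg: Optional[ConvergenceConfig] = None,
    term_names: Optional[Sequence[str]] = None,
) -> list[dict]:
    """Per-start log-binomial outcome table (the starting-value experiment).

    Each entry records the start label, whether the fit converged, the
    failure category otherwise, and exp(beta_E) where available.
    """
    rows = []
    for label, b0 in starts.items():
        res = fit_logbinomial(data, cfg=cfg, beta0=np.asarray(b0, float),
                              term_names=term_names)
        rows.append(
            {
                "start": label,
                "converged": res.converged,
                "failure_reason": res.failure_reason,
                "exposure_effect": res.exposure_effect,
                "n_iterations": res.n_iterations,
            }
        )
    return rows


def compare_methods(
    data: DesignData,
    methods: Sequence[str] = ("modpois", "logistic", "logbin"),
    starts: Sequence[str] = ("zero",),
    cfg: Optional[ConvergenceConfig] = None,
    term_names: Optional[Sequence[str]] = None,
) -> dict:
    """Run the requested comparators on one dataset.

    ``starts`` configures log-binomial starting values by name: "zero"
    (the all-zero vector, which fails by construction), "logistic"
    (coefficients from a logistic fit), "modpois" (coefficients from the
    modified Poisson fit).  Returns a JSON-ready dict keyed by method.
    """
    out: dict = {}
    modpois_res = None
    logistic_res = None
    if "modpois" in methods or "logbin" in methods:
        modpois_res = fit_modified_poisson(data, cfg=cfg, term_names=term_names)
    if "modpois" in methods:
        out["modpois"] = _result_dict(modpois_res)
    if "logistic" in methods or ("logbin" in methods and "logistic" in starts):
        logistic_res = fit_logistic(data, cfg=cfg, term_names=term_names)
    if "logistic" in methods:
        out["logistic"] = _result_dict(logistic_res)
    if "logbin" in methods:
        start_vectors: dict[str, np.ndarray] = {}
        for s in starts:
            if s == "zero":
                start_vectors["zero"] = np.zeros(data.p)
            elif s == "logistic":
                if logistic_res is None or not logistic_res.converged:
                    continue
                start_vectors["logistic"] = np.asarray(
                    list(logistic_res.estimates.values())
                )
            elif s == "modpois":
                if modpois_res is None or not modpois_res.converged:
                    continue
                start_vectors["modpois"] = np.asarray(
                    list(modpois_res.estimates.values())
                )
            else:
                raise ConfigurationError(f"unknown start {s!r}")
        out["logbin"] = {
            "starts": starting_value_report(
                data, start_vectors, cfg=cfg, term_names=term_names
            )
        }
    return out


def _result_dict(res: ComparisonResult) -> dict:
    return {
        "method": res.method,
        "converged": res.converged,
        "estimates": res.estimates,
        "se": res.se,
        "exposure_effect": res.exposure_effect,
        "effect_scale": res.effect_scale,
        "failure_reason": res.failure_reason,
        "n_iterations": res.n_iterations,
    }
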