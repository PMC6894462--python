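"""Modified Poisson regression on a single (pooled) dataset.

Modified Poisson regression estimates adjusted risk ratios for a binary
outcome by solving the Poisson score equations with a log link,

    sum_i { Y_i - exp(Z_i' beta) } Z_i = 0,

and replacing the Poisson variance with the robust sandwich estimator

    var(beta_hat) = H(beta_hat)^{-1} B(beta_hat) H(beta_hat)^{-1},

where H = -sum_i exp(Z_i' beta) Z_i Z_i' is the estimating-equation
derivative and B = sum_i {Y_i - exp(Z_i' beta)}^2 Z_i Z_i' is the outer
product of individual scores.  The coefficient on the exposure is a
log risk ratio; exponentiating gives the adjusted RR directly, without
the rare-disease assumption that an odds ratio would need.

The solver is plain Newton-Raphson:

    beta^(r) = beta^(r-1) - H^{-1} S,

with a mixed absolute/relative stopping rule on the coefficient change
(absolute change when a coefficient is near zero, relative otherwise).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    NonConvergenceError,
    NumericalOverflowError,
    SingularSystemError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: exp() overflows IEEE doubles near 709.78; stay clearly below.
MAX_LINEAR_PREDICTOR = 700.0

#: below this magnitude a coefficient's step is judged on the absolute
#: scale rather than the relative scale (relative change is unstable
#: around zero).
RELATIVE_SWITCH_DEFAULT = 0.01

INTERCEPT_NAME = "Intercept"
EXPOSURE_NAME = "Exposure"


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declares how the regressor vector Z is built from (E, X).

    Column order is fixed and documented: intercept, exposure, the
    covariates in declared order, then exposure-by-covariate interaction
    columns in declared order.

    Parameters
    ----------
    covariate_names
        Ordered labels of the covariates entering as main effects.
    interaction_terms
        Subset of ``covariate_names`` interacted with the exposure.
    include_intercept
        Always true for this model family; kept explicit for clarity.
    """

    covariate_names: tuple[str, ...]
    interaction_terms: tuple[str, ...] = ()
    include_intercept: bool = True

    def __post_init__(self):
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "interaction_terms", tuple(self.interaction_terms))
        if not self.include_intercept:
            raise ConfigurationError("the log-linear risk model always includes an intercept")
        names = list(self.covariate_names)
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate covariate labels: {names}")
        unknown = [t for t in self.interaction_terms if t not in names]
        if unknown:
            raise ConfigurationError(
                f"interaction terms {unknown} are not declared covariates"
            )
        if len(set(self.interaction_terms)) != len(self.interaction_terms):
            raise ConfigurationError("duplicate interaction terms")

    @property
    def term_names(self) -> list[str]:
        return (
            [INTERCEPT_NAME, EXPOSURE_NAME]
            + list(self.covariate_names)
            + [f"{EXPOSURE_NAME}:{c}" for c in self.interaction_terms]
        )

    @property
    def n_terms(self) -> int:
        return 2 + len(self.covariate_names) + len(self.interaction_terms)

    #: position of the exposure coefficient in the regressor vector
    exposure_index: int = field(default=1, init=False, repr=False)

    def interaction_indices(self) -> list[int]:
        off = 2 + len(self.covariate_names)
        return [off + j for j in range(len(self.interaction_terms))]


@dataclass
class DesignData:
    """A design matrix with its binary outcome vector.

    ``Z`` has the intercept in its first column.  ``y`` may be ``None``
    for design-only objects (e.g. when constructing Z for prediction);
    fitting requires it.
    """

    Z: np.ndarray
    y: Optional[np.ndarray] = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValidationError(f"Z must be 2-dimensional, got ndim={self.Z.ndim}")
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError("Z contains non-finite entries")
        if not np.all(self.Z[:, 0] == 1.0):
            raise ValidationError("first column of Z must be the intercept (all ones)")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.Z.shape[0],):
                raise ValidationError(
                    f"y has shape {self.y.shape}, expected ({self.Z.shape[0]},)"
                )
            bad = ~np.isin(self.y, (0.0, 1.0))
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"y must be binary 0/1; first offending row {i} has value {self.y[i]!r}"
                )

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def require_outcome(self) -> np.ndarray:
        if self.y is None:
            raise ValidationError("this operation requires an outcome vector y")
        return self.y


def build_design(
    E: Sequence[float],
    X,
    spec: ModelSpec,
    y: Optional[Sequence[float]] = None,
) -> DesignData:
    """Assemble Z = (1, E, X, E*X_interactions) in the documented order.

    ``X`` may be a DataFrame (columns matched to ``spec.covariate_names``
    by label) or an array whose columns are already in declared order.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 1:
        raise ValidationError("E must be a 1-dimensional vector")
    if not np.all(np.isin(E, (0.0, 1.0))):
        bad = int(np.flatnonzero(~np.isin(E, (0.0, 1.0)))[0])
        raise ValidationError(f"E must be binary 0/1; row {bad} has value {E[bad]!r}")

    m = len(spec.covariate_names)
    if isinstance(X, pd.DataFrame):
        missing = [c for c in spec.covariate_names if c not in X.columns]
        if missing:
            raise ConfigurationError(f"covariates {missing} not found in data columns")
        Xmat = X.loc[:, list(spec.covariate_names)].to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        if Xmat.ndim == 1:
            Xmat = Xmat.reshape(-1, 1)
        if Xmat.shape[1] != m:
            raise ConfigurationError(
                f"X has {Xmat.shape[1]} columns but spec declares {m} covariates"
            )
    if Xmat.shape[0] != E.shape[0]:
        raise ValidationError(
            f"E has {E.shape[0]} rows but X has {Xmat.shape[0]}"
        )

    cols = [np.ones_like(E), E]
    for j in range(m):
        cols.append(Xmat[:, j])
    name_to_col = dict(zip(spec.covariate_names, range(m)))
    for term in spec.interaction_terms:
        cols.append(E * Xmat[:, name_to_col[term]])
    Z = np.column_stack(cols)
    return DesignData(Z=Z, y=None if y is None else np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# convergence configuration and fit result
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvergenceConfig:
    """Stopping rule for the Newton iterations.

    ``tol`` bounds the largest per-coefficient change delta_l, where
    delta_l is the absolute change when |beta_l| < ``switch_threshold``
    and the relative change otherwise.
    """

    tol: float = 1e-8
    switch_threshold: float = RELATIVE_SWITCH_DEFAULT
    max_iterations: int = 50

    def __post_init__(self):
        if not self.tol > 0:
            raise ConfigurationError("tol must be positive")
        if not self.switch_threshold > 0:
            raise ConfigurationError("switch_threshold must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class FitResult:
    """Converged estimates with sandwich covariance and the iteration trace."""

    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    n_iterations: int
    converged: bool
    trace: list[tuple[np.ndarray, float]]
    term_names: Optional[list[str]] = None
    n_obs: Optional[int] = None

    def coef_table(self) -> pd.DataFrame:
        names = self.term_names or [f"b{l}" for l in range(len(self.beta))]
        return pd.DataFrame({"term": names, "estimate": self.beta, "se": self.se})

    def to_json_dict(self) -> dict:
        names = self.term_names or [f"b{l}" for l in range(len(self.beta))]
        return {
            "beta": {name: float(b) for name, b in zip(names, self.beta)},
            "se": {name: float(s) for name, s in zip(names, self.se)},
            "covariance": [[float(v) for v in row] for row in self.cov],
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# score, Hessian, Newton machinery
# ---------------------------------------------------------------------------


def _linear_predictor(Z: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = Z @ beta
    worst = float(np.max(np.abs(eta))) if eta.size else 0.0
    if worst > MAX_LINEAR_PREDICTOR:
        raise NumericalOverflowError(
            f"linear predictor magnitude {worst:.3g} exceeds {MAX_LINEAR_PREDICTOR:g}; "
            "exp() would overflow"
        )
    return eta


def score_and_hessian(
    data: DesignData, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Estimating-equation score S(beta) and its derivative H(beta).

    S = sum_i (Y_i - mu_i) Z_i and H = -sum_i mu_i Z_i Z_i' with
    mu_i = exp(Z_i' beta).  H is symmetric negative semi-definite.
    """
    y = data.require_outcome()
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.p,):
        raise ValidationError(f"beta has shape {beta.shape}, expected ({data.p},)")
    if not np.all(np.isfinite(beta)):
        raise ValidationError("beta contains non-finite entries")
    mu = np.exp(_linear_predictor(data.Z, beta))
    S = data.Z.T @ (y - mu)
    H = -(data.Z * mu[:, None]).T @ data.Z
    H = 0.5 * (H + H.T)  # enforce exact symmetry against rounding
    return S, H


def _check_conditioning(H: np.ndarray, context: str) -> None:
    """Raise SingularSystemError when H is numerically rank-deficient.

    The suspect columns reported are those loading most heavily on the
    smallest singular direction — usually a collinear or constant column.
    """
    u, s, vt = np.linalg.svd(H)
    rcond = float(s[-1] / s[0]) if s[0] > 0 else 0.0
    if rcond < 1e-12:
        v = np.abs(vt[-1])
        suspects = [int(j) for j in np.flatnonzero(v > 0.5 * v.max())]
        raise SingularSystemError(
            f"{context}: Hessian numerically singular "
            f"(reciprocal condition {rcond:.3g}); suspect columns {suspects}",
            suspect_columns=suspects,
        )


def newton_step(beta_prev: np.ndarray, S: np.ndarray, H: np.ndarray) -> np.ndarray:
    """One Newton-Raphson update beta - H^{-1} S, via a symmetric solve."""
    beta_prev = np.asarray(beta_prev, dtype=float)
    S = np.asarray(S, dtype=float)
    H = np.asarray(H, dtype=float)
    _check_conditioning(H, "newton_step")
    delta = linalg.solve(H, S, assume_a="sym")
    return beta_prev - delta


def check_convergence(
    beta_prev: np.ndarray, beta_new: np.ndarray, cfg: ConvergenceConfig
) -> tuple[bool, np.ndarray]:
    """Mixed absolute/relative stopping rule.

    delta_l is the raw difference when |beta_prev_l| < switch_threshold
    (strict inequality) and the difference divided by beta_prev_l
    otherwise; converged iff max_l |delta_l| < tol.
    """
    beta_prev = np.asarray(beta_prev, dtype=float)
    beta_new = np.asarray(beta_new, dtype=float)
    if beta_prev.shape != beta_new.shape:
        raise ValidationError("coefficient vectors have mismatched lengths")
    diff = beta_new - beta_prev
    small = np.abs(beta_prev) < cfg.switch_threshold
    deltas = np.where(small, diff, diff / np.where(small, 1.0, beta_prev))
    converged = bool(np.max(np.abs(deltas)) < cfg.tol) if deltas.size else True
    return converged, deltas


def _validate_for_fit(data: DesignData) -> None:
    data.require_outcome()
    if data.n < data.p:
        raise ValidationError(
            f"need at least as many rows as regressors (n={data.n}, p={data.p})"
        )
    # constant columns other than the intercept make H singular by construction
    for j in range(1, data.p):
        col = data.Z[:, j]
        if np.all(col == col[0]):
            raise ValidationError(
                f"regressor column {j} is constant ({col[0]!r}); drop it before fitting"
            )


def _sandwich_from_pieces(H: np.ndarray, B: np.ndarray) -> np.ndarray:
    """H^{-1} B H^{-1} via two linear solves; never forms H^{-1} explicitly."""
    _check_conditioning(H, "sandwich variance")
    inner = linalg.solve(H, B, assume_a="sym")
    cov = linalg.solve(H, inner.T, assume_a="sym").T
    return 0.5 * (cov + cov.T)


def meat_matrix(data: DesignData, beta: np.ndarray) -> np.ndarray:
    """B(beta) = sum_i (Y_i - mu_i)^2 Z_i Z_i', the score outer product."""
    y = data.require_outcome()
    mu = np.exp(_linear_predictor(data.Z, np.asarray(beta, dtype=float)))
    resid = y - mu
    B = (data.Z * (resid**2)[:, None]).T @ data.Z
    return 0.5 * (B + B.T)


def sandwich_variance(data: DesignData, beta_hat: np.ndarray) -> np.ndarray:
    """Robust covariance H^{-1} B H^{-1} evaluated at the converged estimate.

    This is the HC0-type sandwich: consistent for the variance of the
    estimating-equation root even though the outcome is Bernoulli rather
    than Poisson.
    """
    _, H = score_and_hessian(data, beta_hat)
    B = meat_matrix(data, beta_hat)
    mu = np.exp(_linear_predictor(data.Z, np.asarray(beta_hat, dtype=float)))
    n_above = int(np.sum(mu > 1.0))
    if n_above:
        logger.warning(
            "log link does not bound fitted risks: %d of %d fitted values exceed 1 "
            "(max %.4g)", n_above, data.n, float(mu.max()),
        )
    return _sandwich_from_pieces(H, B)


def fit_pooled(
    data: DesignData,
    cfg: Optional[ConvergenceConfig] = None,
    beta0: Optional[np.ndarray] = None,
    term_names: Optional[list[str]] = None,
) -> FitResult:
    """Fit modified Poisson regression by Newton-Raphson on pooled rows.

    Starts from the zero vector unless ``beta0`` is given.  Raises
    :class:`NonConvergenceError` (carrying the trace) if the stopping
    rule is not met within ``cfg.max_iterations`` updates.
    """
    cfg = cfg or ConvergenceConfig()
    _validate_for_fit(data)
    beta = (
        np.zeros(data.p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    )
    if beta.shape != (data.p,):
        raise ConfigurationError(f"beta0 has shape {beta.shape}, expected ({data.p},)")
    trace: list[tuple[np.ndarray, float]] = []
    converged = False
    r = 0
    for r in range(1, cfg.max_iterations + 1):
        S, H = score_and_hessian(data, beta)
        beta_new = newton_step(beta, S, H)
        converged, deltas = check_convergence(beta, beta_new, cfg)
        trace.append((beta_new.copy(), float(np.max(np.abs(deltas)))))
        beta = beta_new
        if converged:
            break
    if not converged:
        raise NonConvergenceError(
            f"no convergence after {cfg.max_iterations} iterations "
            f"(last max |delta| = {trace[-1][1]:.3g})",
            trace=trace,
        )
    cov = sandwich_variance(data, beta)
    return FitResult(
        beta=beta,
        cov=cov,
        se=np.sqrt(np.diag(cov)),
        n_iterations=r,
        converged=True,
        trace=trace,
        term_names=term_names,
        n_obs=data.n,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def risk_ratio_report(
    fit: FitResult,
    spec: ModelSpec,
    alpha: float = 0.05,
    at_x: Optional[Mapping[str, float]] = None,
    z_value: Optional[float] = None,
) -> pd.DataFrame:
    """Risk-ratio table: term, log-scale estimate and CI, RR and its CI.

    Without interactions the exposure row's RR is exp(beta_E).  With
    interactions the exposure effect depends on the covariate values, so
    ``at_x`` must supply a value for every interacted covariate; the
    combined effect beta_E + sum_j beta_{E:Xj} x_j gets a delta-method
    (linear-combination) standard error.

    ``z_value`` overrides the normal critical value (default
    ``norm.ppf(1 - alpha/2)``), e.g. 1.96 for the conventional rounded
    multiplier.
    """
    if not fit.converged:
        raise ValidationError("risk_ratio_report requires a converged fit")
    if len(fit.beta) != spec.n_terms:
        raise ConfigurationError(
            f"fit has {len(fit.beta)} coefficients but spec declares {spec.n_terms} terms"
        )
    z = float(z_value) if z_value is not None else float(sps.norm.ppf(1 - alpha / 2))

    rows = []

    def add_row(term, est, se):
        lo, hi = est - z * se, est + z * se
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "ci_low_log": lo,
                "ci_high_log": hi,
                "RR": float(np.exp(est)),
                "CI_low": float(np.exp(lo)),
                "CI_high": float(np.exp(hi)),
            }
        )

    names = spec.term_names
    for l, name in enumerate(names):
        add_row(name, float(fit.beta[l]), float(fit.se[l]))

    if spec.interaction_terms:
        if at_x is None:
            raise ConfigurationError(
                "model has exposure interactions; supply at_x with values for "
                f"{list(spec.interaction_terms)}"
            )
        missing = [t for t in spec.interaction_terms if t not in at_x]
        if missing:
            raise ConfigurationError(f"at_x is missing values for {missing}")
        a = np.zeros(len(fit.beta))
        a[spec.exposure_index] = 1.0
        for idx, term in zip(spec.interaction_indices(), spec.interaction_terms):
            a[idx] = float(at_x[term])
        est = float(a @ fit.beta)
        se = float(np.sqrt(a @ fit.cov @ a))
        label = ", ".join(f"{t}={at_x[t]:g}" for t in spec.interaction_terms)
        add_row(f"{EXPOSURE_NAME} (at {label})", est, se)

    return pd.DataFrame(rows)
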