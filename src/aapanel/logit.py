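"""Maximum-likelihood logistic regression on an analyte subset.

The injury probability of a sample with analyte concentrations
``X1..Xp`` is modelled as

    logit P = ln(P / (1 - P)) = beta0 + beta1*X1 + ... + betap*Xp

fitted by iteratively reweighted least squares (IRLS) on the Bernoulli
log-likelihood.  Coefficients stay on raw nmol/mL scales — no standardization
is applied, so fitted coefficients are directly comparable to published
regression tables.  Perfect or quasi-separation, which small biomarker panels
commonly exhibit, is detected and flagged rather than silently repaired; an
optional tiny ridge keeps the Hessian invertible so that clamped likelihoods
remain finite for information-criterion comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import DegenerateDesignError, RankDeficiencyError
from .panel import AnalytePanel

#: Probabilities are clamped to [EPS, 1-EPS] in likelihood evaluations.
EPS = float(np.finfo(float).eps)

#: |standardized coefficient| above this triggers the separation flag.
SEPARATION_GUARD = 10.0


@dataclass
class FitOptions:
    """Numerical controls for the IRLS fit.

    tol
        Convergence threshold on the relative log-likelihood change.
    max_iter
        Iteration cap; fits hitting it are returned with ``converged=False``.
    ridge
        Tiny L2 term (on the Hessian only) stabilising near-singular
        information matrices; set to 0 to disable.
    guard
        Divergence guard: |beta_j| * sd(X_j) beyond this flags separation.
    """

    tol: float = 1e-10
    max_iter: int = 100
    ridge: float = 1e-8
    guard: float = SEPARATION_GUARD


@dataclass
class LogitModel:
    """A fitted logistic regression on one analyte subset."""

    variable_names: list[str]
    beta0: float
    betas: np.ndarray
    log_likelihood: float
    n: int
    p: int
    converged: bool
    separation_flag: bool
    standard_errors: np.ndarray = field(default=None)  # intercept first
    z_values: np.ndarray = field(default=None)
    p_values: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) != self.p or self.p != len(self.variable_names):
            raise ValueError("betas / variable_names / p are inconsistent")
        if self.n <= 0:
            raise ValueError("n must be positive")

    @property
    def coefficients(self) -> np.ndarray:
        """Intercept followed by the slope coefficients."""
        return np.concatenate([[self.beta0], self.betas])

    # -- prediction ------------------------------------------------------

    def logit_score(self, sample: Mapping[str, float] | np.ndarray) -> float:
        """Raw linear predictor beta0 + sum(beta_i * X_i) for one sample."""
        if isinstance(sample, Mapping):
            try:
                x = np.array([sample[name] for name in self.variable_names], float)
            except KeyError as exc:
                raise KeyError(f"sample is missing variable {exc.args[0]!r}") from exc
        else:
            x = np.asarray(sample, dtype=float)
            if x.shape[-1] != self.p:
                raise ValueError(f"expected {self.p} values, got {x.shape[-1]}")
        return float(self.beta0 + x @ self.betas)

    def scores(self, panel: AnalytePanel) -> np.ndarray:
        """Linear predictor for every sample in the panel."""
        return self.beta0 + panel.values(self.variable_names) @ self.betas


def predict_probability(model: LogitModel, sample: Mapping[str, float] | np.ndarray) -> float:
    """Estimated injury probability P = 1 / (1 + exp(-logit score))."""
    return float(expit(model.logit_score(sample)))


def log_likelihood_at(model: LogitModel, panel: AnalytePanel) -> float:
    """Bernoulli log-likelihood of ``model`` on ``panel`` (clamped at eps)."""
    eta = model.scores(panel)
    return bernoulli_log_likelihood(panel.labels, eta)


def bernoulli_log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    p = np.clip(expit(eta), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def null_log_likelihood(y: np.ndarray) -> float:
    """Maximum log-likelihood of the intercept-only model."""
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar in (0.0, 1.0):  # single class; caller should have rejected this
        return 0.0
    n = len(y)
    return float(n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))


def fit_logit(
    panel: AnalytePanel,
    subset: Sequence[str],
    options: FitOptions | None = None,
) -> LogitModel:
    """Fit the logistic model on ``subset`` by IRLS.

    Raises
    ------
    DegenerateDesignError
        If the panel contains a single class.
    RankDeficiencyError
        If an analyte in the subset is constant-valued (naming it).
    """
    options = options or FitOptions()
    subset = list(subset)
    y = panel.labels
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError("panel contains a single class; logit undefined")
    X = panel.values(subset)
    sd = X.std(axis=0)
    for j, name in enumerate(subset):
        if sd[j] == 0.0:
            raise RankDeficiencyError(f"analyte {name!r} is constant-valued")

    beta, ll, converged = _irls(X, y, options)
    separation = bool(np.any(np.abs(beta[1:]) * sd > options.guard)) or not np.all(
        np.isfinite(beta)
    )

    # Wald inference from the inverse observed information at the optimum.
    se = z = pv = None
    Xd = np.column_stack([np.ones(len(y)), X])
    mu = np.clip(expit(Xd @ beta), EPS, 1 - EPS)
    w = mu * (1.0 - mu)
    info = Xd.T @ (Xd * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        from scipy.stats import norm

        pv = 2.0 * norm.sf(np.abs(z))
    except np.linalg.LinAlgError:
        pass

    return LogitModel(
        variable_names=subset,
        beta0=float(beta[0]),
        betas=beta[1:].copy(),
        log_likelihood=ll,
        n=len(y),
        p=len(subset),
        converged=converged,
        separation_flag=separation,
        standard_errors=se,
        z_values=z,
        p_values=pv,
    )


def _irls(X: np.ndarray, y: np.ndarray, options: FitOptions):
    """Newton/IRLS iterations with step-halving; returns (beta, ll, converged)."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    q = Xd.shape[1]
    beta = np.zeros(q)
    yf = y.astype(float)
    ll = bernoulli_log_likelihood(yf, Xd @ beta)
    converged = False
    ridge_eye = options.ridge * np.eye(q)
    for _ in range(options.max_iter):
        eta = np.clip(Xd @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Xd.T @ (yf - mu)
        hess = Xd.T @ (Xd * w[:, None]) + ridge_eye
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        new_beta = beta + delta
        new_ll = bernoulli_log_likelihood(yf, Xd @ new_beta)
        # step-halving keeps the likelihood non-decreasing under separation
        for _h in range(30):
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
            new_beta = beta + step * delta
            new_ll = bernoulli_log_likelihood(yf, Xd @ new_beta)
        rel_change = abs(new_ll - ll) / max(1.0, abs(new_ll))
        beta, ll = new_beta, new_ll
        if rel_change < options.tol:
            converged = True
            break
    return beta, ll, converged
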