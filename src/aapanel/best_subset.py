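"""Exhaustive best-subset search scored by penalized-likelihood criteria.

Every combination of analytes (all 2^pp subsets, including the intercept-only
model) is fitted by logistic regression and scored with

    criterion = -2*l + A_n * p

where ``l`` is the maximum Bernoulli log-likelihood, ``p`` the number of
analyte variables in the subset (the intercept is not counted; the constant
offset cancels in within-criterion comparisons), and ``A_n`` the sample-size
penalty: 2 for AIC, ln(n) for BIC, ln(n)+1 for the Consistent AIC (CAIC).
CAIC is the operative criterion throughout — its stiffer penalty favours the
parsimonious panels this kind of biomarker search is after.

The search is exact, not stepwise: for 17 analytes that is 131072 models per
training fold.  To keep that desk-scale, subsets of equal size are fitted
simultaneously by a batched Newton solver operating on stacked design
matrices; a conventional one-model-at-a-time path (`score_subset`) backs the
same arithmetic for single fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DegenerateDesignError
from .logit import (
    EPS,
    FitOptions,
    LogitModel,
    bernoulli_log_likelihood,
    fit_logit,
    null_log_likelihood,
)
from .panel import AnalytePanel

#: Criterion values within this of the minimum are treated as ties.
TIE_TOL = 1e-9

try:  # compiled scan kernel; the numpy batched path below is the fallback
    from ._fastscan import newton_scan as _newton_scan
except Exception:  # pragma: no cover - numba genuinely absent
    _newton_scan = None


@dataclass(frozen=True)
class CriterionSpec:
    """A penalized-likelihood criterion -2*l + A_n * p.

    ``penalty_fn`` maps the sample count n to the per-variable penalty A_n.
    """

    name: str
    penalty_fn: Callable[[int], float]

    def penalty(self, n: int) -> float:
        a_n = float(self.penalty_fn(n))
        if n >= 2 and a_n <= 0:
            raise ConfigurationError(f"penalty A_n must be positive, got {a_n}")
        return a_n

    def value(self, log_likelihood: float, n: int, p: int) -> float:
        return -2.0 * log_likelihood + self.penalty(n) * p


AIC = CriterionSpec("AIC", lambda n: 2.0)
BIC = CriterionSpec("BIC", lambda n: math.log(n))
CAIC = CriterionSpec("CAIC", lambda n: math.log(n) + 1.0)

_CRITERIA = {"aic": AIC, "bic": BIC, "caic": CAIC}


def get_criterion(name: str) -> CriterionSpec:
    try:
        return _CRITERIA[name.lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown criterion {name!r}; choose from {sorted(_CRITERIA)}"
        ) from None


@dataclass
class SubsetScore:
    """One analyte subset with its fitted model and criterion value."""

    subset: tuple[str, ...]
    size: int
    criterion_value: float
    log_likelihood: float
    model: LogitModel | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.size != len(self.subset):
            raise ValueError("size does not match subset length")


def enumerate_subsets(
    analyte_names: Sequence[str],
    min_size: int = 0,
    max_size: int | None = None,
) -> Iterator[tuple[str, ...]]:
    """Yield every analyte combination of size min_size..max_size.

    Subsets are produced in deterministic order: by size, then
    lexicographically by position in ``analyte_names``.  Size 0 (the
    intercept-only model) is a legal member of the enumeration, so the total
    over sizes 0..pp is 2^pp.
    """
    names = list(analyte_names)
    pp = len(names)
    if max_size is None:
        max_size = pp
    if not (0 <= min_size <= max_size <= pp):
        raise ConfigurationError(
            f"invalid size bounds [{min_size}, {max_size}] for {pp} analytes"
        )
    for p in range(min_size, max_size + 1):
        yield from combinations(names, p)


def score_subset(
    panel: AnalytePanel,
    subset: Sequence[str],
    criterion: CriterionSpec,
    options: FitOptions | None = None,
) -> SubsetScore:
    """Fit the logit on one subset and return its criterion value."""
    subset = tuple(subset)
    n = panel.n_samples
    if len(subset) == 0:
        y = panel.labels
        if len(np.unique(y)) < 2:
            raise DegenerateDesignError("panel contains a single class")
        ll = null_log_likelihood(y)
        return SubsetScore(subset, 0, criterion.value(ll, n, 0), ll, model=None)
    model = fit_logit(panel, subset, options)
    value = criterion.value(model.log_likelihood, n, len(subset))
    return SubsetScore(
        subset,
        len(subset),
        value,
        model.log_likelihood,
        model=model,
        flagged=model.separation_flag or not model.converged,
    )


def best_subsets_by_size(
    panel: AnalytePanel,
    criterion: CriterionSpec,
    sizes: Sequence[int] | range | None = None,
    options: FitOptions | None = None,
    refit_winners: bool = True,
) -> dict[int, SubsetScore]:
    """Exhaustively find the criterion-minimizing subset of each size.

    Ties within ``TIE_TOL`` resolve to the lexicographically first subset.
    Separation-flagged fits keep their clamped-likelihood scores but carry
    the flag into the returned :class:`SubsetScore`.

    With ``refit_winners`` (default) each winning subset is refitted through
    :func:`fit_logit` so the returned models carry Wald standard errors.
    """
    options = options or FitOptions()
    names = panel.analyte_names
    pp = len(names)
    if sizes is None:
        sizes = range(1, pp + 1)
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and (sizes[0] < 0 or sizes[-1] > pp):
        raise ConfigurationError(f"sizes out of bounds for {pp} analytes")

    y = panel.labels
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError("panel contains a single class")
    X = panel.values()
    sd = X.std(axis=0)
    n = panel.n_samples
    a_n = criterion.penalty(n)

    result: dict[int, SubsetScore] = {}
    for p in sizes:
        if p == 0:
            ll = null_log_likelihood(y)
            result[0] = SubsetScore((), 0, criterion.value(ll, n, 0), ll)
            continue
        idx = _combination_indices(pp, p)
        ll, flags = _batch_fit_loglik(X, y, idx, sd, options)
        crit = -2.0 * ll + a_n * p
        best = int(np.flatnonzero(crit <= crit.min() + TIE_TOL)[0])
        subset = tuple(names[j] for j in idx[best])
        score = SubsetScore(
            subset, p, float(crit[best]), float(ll[best]), flagged=bool(flags[best])
        )
        if refit_winners:
            model = fit_logit(panel, subset, options)
            score.model = model
            score.flagged = score.flagged or model.separation_flag or not model.converged
        result[p] = score
    return result


def _combination_indices(pp: int, p: int) -> np.ndarray:
    """All C(pp, p) index combinations as a (B, p) array, lexicographic."""
    count = math.comb(pp, p)
    flat = np.fromiter(
        chain.from_iterable(combinations(range(pp), p)), dtype=np.intp, count=count * p
    )
    return flat.reshape(count, p)


# ----------------------------------------------------------------------
# batched Newton engine


def _batch_fit_loglik(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    sd: np.ndarray,
    options: FitOptions,
    chunk: int = 8192,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum log-likelihood for every subset in ``idx`` (B × p index rows).

    Returns (log_likelihoods, flags) where flags marks separation or
    non-convergence.  Work proceeds in chunks to bound memory.
    """
    if _newton_scan is not None:
        ll, flags = _newton_scan(
            np.ascontiguousarray(X),
            y.astype(np.float64),
            np.ascontiguousarray(idx),
            sd.astype(np.float64),
            options.ridge,
            options.tol,
            options.max_iter,
            options.guard,
        )
        return ll, flags.astype(bool)
    B = idx.shape[0]
    ll = np.empty(B)
    flags = np.zeros(B, dtype=bool)
    for start in range(0, B, chunk):
        sl = slice(start, min(start + chunk, B))
        ll[sl], flags[sl] = _batch_newton_chunk(X, y, idx[sl], sd, options)
    return ll, flags


def _batch_newton_chunk(X, y, idx, sd, options):
    b, p = idx.shape
    n = X.shape[0]
    # stacked designs: (b, n, p+1), intercept first
    Xd = np.empty((b, n, p + 1))
    Xd[:, :, 0] = 1.0
    Xd[:, :, 1:] = X[:, idx].transpose(1, 0, 2)
    yf = y.astype(float)
    sd_sub = sd[idx]  # (b, p)

    beta = np.zeros((b, p + 1))
    ll = np.full(b, _ll_from_eta(np.zeros(n), yf))
    converged = np.zeros(b, dtype=bool)
    separated = np.zeros(b, dtype=bool)
    active = np.arange(b)
    eye = options.ridge * np.eye(p + 1)

    for _ in range(options.max_iter):
        if active.size == 0:
            break
        Xa = Xd[active]
        XaT = Xa.transpose(0, 2, 1)
        ba = beta[active]
        lla = ll[active]
        eta = np.clip((Xa @ ba[..., None])[..., 0], -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = (XaT @ (yf[None, :] - mu)[..., None])[..., 0]
        hess = XaT @ (Xa * w[..., None]) + eye
        delta = np.linalg.solve(hess, grad[..., None])[..., 0]

        new_beta = ba + delta
        new_ll = _batch_ll(Xa, new_beta, yf)
        step = np.ones(active.size)
        for _h in range(30):
            worse = new_ll < lla - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta[worse] = ba[worse] + step[worse, None] * delta[worse]
            new_ll[worse] = _batch_ll(Xa[worse], new_beta[worse], yf)

        rel = np.abs(new_ll - lla) / np.maximum(1.0, np.abs(new_ll))
        beta[active] = new_beta
        ll[active] = new_ll
        done = rel < options.tol
        # separation: once the guard trips, the likelihood is already at its
        # clamped plateau — stop iterating and keep the flag
        sep = np.any(np.abs(new_beta[:, 1:]) * sd_sub[active] > options.guard, axis=1)
        separated[active[sep]] = True
        converged[active[done & ~sep]] = True
        active = active[~(done | sep)]

    flags = separated | ~converged
    return ll, flags


def _batch_ll(Xd, beta, yf):
    # softplus form of the Bernoulli log-likelihood: sum(y*eta - log(1+e^eta))
    eta = (Xd @ beta[..., None])[..., 0]
    return np.sum(yf[None, :] * eta - np.logaddexp(0.0, eta), axis=1)


def _ll_from_eta(eta, yf):
    return bernoulli_log_likelihood(yf, eta)
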