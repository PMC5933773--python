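"""Standard errors via numerical differentiation and person scoring.

Standard errors of the item (and free density) parameters come from finite
second differences of the observed-data log-likelihood at the MML estimates:
the covariance is the inverse of the negative Hessian, and the SE the square
root of its diagonal.  Central differencing is the default for
unidimensional models and forward differencing for multidimensional ones
(each Hessian entry then costs far fewer likelihood evaluations); Richardson
extrapolation of the central differences is available as a high-accuracy
option.

Person scoring supports EAP (posterior mean over the quadrature grid), MAP
(posterior mode) and MLE (likelihood mode with the prior removed), with
posterior-SD or curvature-based standard errors, plus the empirical
reliability coefficient var(theta_hat) / (var(theta_hat) + mean(SE^2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from .estimate import (
    ModelSpec,
    ParamSet,
    ResponseData,
    item_logprob_matrix,
    marginal_loglik,
    _log_weights,
    LOG_TINY,
)
from .exceptions import NumericalError
from .latent import QuadratureGrid

__all__ = [
    "SEResult",
    "PersonScores",
    "finite_difference_hessian",
    "observed_hessian",
    "param_se",
    "score_persons",
    "empirical_reliability",
]


@dataclass
class SEResult:
    """Standard errors per free parameter with a solvability flag."""

    se: np.ndarray
    hessian_ok: bool
    method: str = "central"


@dataclass
class PersonScores:
    """Point estimates and SEs of the latent traits, persons x dimensions."""

    theta: np.ndarray         # (N, D)
    se: np.ndarray            # (N, D)
    method: str
    valid: np.ndarray         # (N,) False when the score is undefined


# ---------------------------------------------------------------------------
# numerical Hessians
# ---------------------------------------------------------------------------

def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(1.0, np.abs(x))


def _central_hessian(f: Callable, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for j in range(p):
        e = np.zeros(p); e[j] = h[j]
        fp[j] = f(x + e)
        fm[j] = f(x - e)
        H[j, j] = (fp[j] + fm[j] - 2.0 * f0) / h[j] ** 2
    for j in range(p):
        ej = np.zeros(p); ej[j] = h[j]
        for k in range(j + 1, p):
            ek = np.zeros(p); ek[k] = h[k]
            v = (f(x + ej + ek) - f(x + ej - ek)
                 - f(x - ej + ek) + f(x - ej - ek)) / (4.0 * h[j] * h[k])
            H[j, k] = H[k, j] = v
    return H


def _forward_hessian(f: Callable, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    p = x.size
    f0 = f(x)
    f1 = np.empty(p)
    for j in range(p):
        e = np.zeros(p); e[j] = h[j]
        f1[j] = f(x + e)
    H = np.empty((p, p))
    for j in range(p):
        ej = np.zeros(p); ej[j] = h[j]
        for k in range(j, p):
            ek = np.zeros(p); ek[k] = h[k]
            v = (f(x + ej + ek) - f1[j] - f1[k] + f0) / (h[j] * h[k])
            H[j, k] = H[k, j] = v
    return H


def finite_difference_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    method: str = "central",
    rel_step: float = 1e-4,
    richardson_levels: int = 4,
) -> np.ndarray:
    """Symmetric finite-difference Hessian of a scalar function.

    Steps are relative, ``h_j = rel_step * max(1, |x_j|)``.  ``richardson``
    applies Romberg-style extrapolation to central differences with
    successively halved steps (exact for quartics and beyond as the level
    grows).
    """
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    if method == "central":
        H = _central_hessian(f, x, h)
    elif method == "forward":
        H = _forward_hessian(f, x, h)
    elif method == "richardson":
        levels = max(2, int(richardson_levels))
        tab = [_central_hessian(f, x, h / (2.0**m)) for m in range(levels)]
        for m in range(1, levels):
            fac = 4.0**m
            tab = [
                (fac * tab[i + 1] - tab[i]) / (fac - 1.0)
                for i in range(len(tab) - 1)
            ]
        H = tab[0]
    else:
        raise NumericalError(f"unknown differencing method {method!r}")
    if not np.all(np.isfinite(H)):
        raise NumericalError("non-finite entries in the numerical Hessian")
    return 0.5 * (H + H.T)


def observed_hessian(
    data: ResponseData,
    spec: ModelSpec,
    params: ParamSet,
    grid: QuadratureGrid,
    method: Optional[str] = None,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Hessian of the observed-data log-likelihood at the estimates.

    The default method is central differencing for unidimensional models and
    the cheaper forward differencing for multidimensional ones.
    """
    if method is None:
        method = "central" if spec.n_dims == 1 else "forward"
    x0 = params.pack(spec, include_density=True)

    def f(v):
        p = ParamSet.unpack(v, spec, template=params, include_density=True)
        return marginal_loglik(data, spec, p, grid)

    return finite_difference_hessian(f, x0, method=method, rel_step=rel_step)


def param_se(hessian: np.ndarray, method: str = "central") -> SEResult:
    """SEs as sqrt(diag((-H)^-1)); pseudo-inverse fallback is flagged."""
    negH = -np.asarray(hessian, dtype=float)
    ok = True
    try:
        np.linalg.cholesky(negH)
        cov = np.linalg.inv(negH)
    except np.linalg.LinAlgError:
        ok = False
        cov = np.linalg.pinv(negH)
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        ok = False
        diag = np.abs(diag)
    return SEResult(se=np.sqrt(diag), hessian_ok=ok, method=method)


# ---------------------------------------------------------------------------
# person scoring
# ---------------------------------------------------------------------------

def _person_logliks(data, spec, params, grid):
    """Log-likelihood of each person's responses at each node (collapsed)."""
    patterns, _ = data.collapse()
    logP = item_logprob_matrix(spec, params, grid.nodes)
    lp = np.maximum(logP, LOG_TINY)
    S = patterns.shape[0]
    acc = np.zeros((S, grid.n_nodes))
    for i in range(patterns.shape[1]):
        idx = patterns[:, i]
        valid = idx >= 0
        if np.all(valid):
            acc += lp[i].T[idx]
        elif np.any(valid):
            acc[valid] += lp[i].T[idx[valid]]
    # map collapsed patterns back to persons
    _, inverse = np.unique(data.codes, axis=0, return_inverse=True)
    return acc, inverse, patterns


def score_persons(
    data: ResponseData,
    spec: ModelSpec,
    params: ParamSet,
    grid: QuadratureGrid,
    method: str = "EAP",
) -> PersonScores:
    """Score persons by EAP, MAP or MLE given fitted item parameters.

    EAP is the posterior mean over the grid with the posterior SD as SE
    (persons with no observed responses get the prior mean).  MAP and MLE
    locate the mode by continuous optimization started from the grid
    maximizer; their SE is curvature-based.  MLE is undefined for persons
    with no responses, flagged via ``valid``.
    """
    acc, inverse, patterns = _person_logliks(data, spec, params, grid)
    logw = _log_weights(spec, params, grid)
    D = spec.n_dims
    any_obs = (patterns >= 0).any(axis=1)
    if method == "EAP":
        post = acc + logw
        post = np.exp(post - post.max(axis=1, keepdims=True))
        post /= post.sum(axis=1, keepdims=True)
        mean = post @ grid.nodes                     # (S, D)
        ex2 = post @ (grid.nodes**2)
        sd = np.sqrt(np.maximum(ex2 - mean**2, 0.0))
        return PersonScores(
            theta=mean[inverse], se=sd[inverse], method="EAP",
            valid=np.ones(data.n_persons, dtype=bool),
        )
    if method not in ("MAP", "MLE"):
        raise NumericalError(f"unknown scoring method {method!r}")
    objective_grid = acc + logw if method == "MAP" else acc
    S = acc.shape[0]
    theta = np.zeros((S, D))
    se = np.full((S, D), np.nan)
    valid = np.ones(S, dtype=bool)
    lo, hi = grid.range
    dens = params.density(spec)
    pats = patterns

    def negobj(th, s):
        lp = item_logprob_matrix(spec, params, th[None, :] if D > 1 else th[:1])
        tot = 0.0
        for i in range(pats.shape[1]):
            z = pats[s, i]
            if z >= 0:
                tot += max(lp[i, 0, z], LOG_TINY)
        if method == "MAP":
            tot += float(dens.logpdf(th[None, :] if D > 1 else th[:1])[0])
        return -tot

    for s in range(S):
        if method == "MLE" and not any_obs[s]:
            valid[s] = False
            continue
        q0 = int(np.argmax(objective_grid[s]))
        x0 = grid.nodes[q0].astype(float)
        res = optimize.minimize(
            lambda th: negobj(np.atleast_1d(th), s), x0,
            method="L-BFGS-B", bounds=[(lo, hi)] * D,
        )
        theta[s] = np.atleast_1d(res.x)
        # curvature-based SE from a central second difference per coordinate
        h = 1e-3
        for d in range(D):
            e = np.zeros(D); e[d] = h
            curv = (
                negobj(theta[s] + e, s) + negobj(theta[s] - e, s)
                - 2.0 * negobj(theta[s], s)
            ) / h**2
            se[s, d] = 1.0 / np.sqrt(curv) if curv > 0 else np.nan
    return PersonScores(
        theta=theta[inverse], se=se[inverse], method=method,
        valid=valid[inverse] & any_obs[inverse],
    )


def empirical_reliability(scores: PersonScores):
    """Empirical reliability: var(theta_hat) / (var(theta_hat) + mean(SE^2)).

    Returns a scalar for unidimensional scores, one value per dimension
    otherwise; 0 (with all mass in the error term) when the score variance
    vanishes.
    """
    th = scores.theta[scores.valid]
    se = scores.se[scores.valid]
    var = th.var(axis=0, ddof=1) if th.shape[0] > 1 else np.zeros(th.shape[1])
    mse = np.nanmean(se**2, axis=0)
    with np.errstate(invalid="ignore"):
        rxx = np.where(var + mse > 0, var / (var + mse), 0.0)
    return float(rxx[0]) if rxx.size == 1 else rxx
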