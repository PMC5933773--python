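"""Category-probability kernels for unfolding (ideal-point) item response models.

Unfolding models describe Likert-type responses whose endorsement probability
peaks when a respondent's latent trait :math:`\\theta` coincides with the item
location :math:`\\delta`, and falls off with the distance
:math:`|\\theta-\\delta|` on either side.  Three kernel families are provided:

* the **GGUM family** (generalized graded unfolding model and its rating-scale
  and unit-discrimination reductions, UM3/UM4/UM7/UM8), built from the
  "agree from below / agree from above" decomposition with threshold
  parameters :math:`\\tau_{ik}`;
* the **unit-threshold family** (UM1/UM2/UM5/UM6), the same construction with
  a single unit threshold :math:`\\lambda_i` in place of the :math:`\\tau`
  vector;
* **Luo's general family**, in which the category probability is a normalized
  product of binary "sub-endorsement" probabilities driven by a symmetric
  operational function :math:`\\psi`.  Five operational functions are
  supported: ``ALM`` (:math:`e^{|x|}`), ``SSLM`` (:math:`e^{x^2}`),
  ``PARELLA`` (:math:`x^2`), ``HCM`` (:math:`\\cosh x`) and ``GUM``
  (a category-indexed ratio of hyperbolic cosines).

A multidimensional variant replaces :math:`\\theta-\\delta` by the weighted
Euclidean distance :math:`\\|\\theta-\\delta\\| =
\\sqrt{\\sum_d [\\alpha_d(\\theta_d-\\delta)]^2}`.

All probability evaluations are carried out in log space (log-sum-exp and
log-cosh identities) so that large :math:`|\\alpha(\\theta-\\delta)|` never
overflows.  The module also provides the Fisher information of
:math:`\\theta` for every kernel, computed from analytic derivatives of the
log category probabilities.

The scalar functions (:func:`ggum_probs`, :func:`luo_probs`, ...) are thin
wrappers over vectorized array cores that the estimation machinery reuses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, log_expit

from .exceptions import ConfigurationError, ParameterError


def _normalize_log(lognum: np.ndarray) -> np.ndarray:
    """lognum - logsumexp(lognum, axis=-1), written out for speed."""
    m = lognum.max(axis=-1, keepdims=True)
    return lognum - (m + np.log(np.exp(lognum - m).sum(axis=-1, keepdims=True)))

__all__ = [
    "OPERATIONAL_FUNCTIONS",
    "CategoryScale",
    "GgumItemParams",
    "LuoItemParams",
    "MumItemParams",
    "psi",
    "ggum_probs",
    "unit_probs",
    "luo_probs",
    "mum_probs",
    "fisher_information",
]

OPERATIONAL_FUNCTIONS = ("ALM", "SSLM", "PARELLA", "HCM", "GUM")

_LOG2 = float(np.log(2.0))
# guard for removable singularities (PARELLA derivative at theta = delta)
_XEPS = 1e-150


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryScale:
    """Number of response categories of an item.

    ``C`` is the number of categories minus one (codes run 0..C) and
    ``M = 2C + 1`` is the doubled latent-response range used by the
    GGUM-style kernels.
    """

    C: int

    def __post_init__(self) -> None:
        if int(self.C) < 1:
            raise ConfigurationError(f"C must be >= 1, got {self.C}")
        object.__setattr__(self, "C", int(self.C))

    @property
    def M(self) -> int:
        return 2 * self.C + 1


def _check_finite(name: str, value: np.ndarray) -> np.ndarray:
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class GgumItemParams:
    """Item parameters for the GGUM / unit-threshold families.

    ``tau`` is the full threshold vector of length C+1 whose leading entry is
    the anchoring zero (tau_0 = 0); ``lambda_`` is the unit threshold of the
    UM1/UM2/UM5/UM6 variants.  Exactly one of the two must be supplied.
    """

    alpha: float
    delta: float
    tau: Optional[np.ndarray] = None
    lambda_: Optional[float] = None

    def __post_init__(self) -> None:
        a = float(_check_finite("alpha", self.alpha))
        if a <= 0:
            raise ParameterError(f"alpha must be positive, got {a}")
        _check_finite("delta", self.delta)
        if (self.tau is None) == (self.lambda_ is None):
            raise ParameterError("exactly one of tau / lambda_ must be given")
        if self.tau is not None:
            tau = _check_finite("tau", np.atleast_1d(self.tau))
            if tau[0] != 0.0:
                raise ParameterError("tau[0] is the anchoring zero and must equal 0")
            object.__setattr__(self, "tau", tau)
        else:
            _check_finite("lambda_", self.lambda_)


@dataclass(frozen=True)
class LuoItemParams:
    """Item parameters for Luo's unidimensional family (thresholds rho_k > 0)."""

    alpha: float
    delta: float
    rho: np.ndarray
    operational_function: str = "HCM"

    def __post_init__(self) -> None:
        if self.operational_function not in OPERATIONAL_FUNCTIONS:
            raise ConfigurationError(
                f"unknown operational function {self.operational_function!r}; "
                f"expected one of {OPERATIONAL_FUNCTIONS}"
            )
        a = float(_check_finite("alpha", self.alpha))
        if a <= 0:
            raise ParameterError(f"alpha must be positive, got {a}")
        _check_finite("delta", self.delta)
        rho = _check_finite("rho", np.atleast_1d(self.rho))
        if np.any(rho <= 0):
            raise ParameterError(f"all rho must be positive, got {rho}")
        object.__setattr__(self, "rho", rho)


@dataclass(frozen=True)
class MumItemParams:
    """Item parameters for the multidimensional unfolding model.

    ``alpha`` holds one (nonnegative) discrimination per dimension; in the
    between-item design exactly one entry is nonzero and
    ``dimension_of_item`` records which (1-based).  ``delta`` is the single
    item location shared by all dimensions (confirmatory constraint).
    """

    alpha: np.ndarray
    delta: float
    rho: np.ndarray
    operational_function: str = "HCM"
    dimension_of_item: Optional[int] = None

    def __post_init__(self) -> None:
        if self.operational_function not in OPERATIONAL_FUNCTIONS:
            raise ConfigurationError(
                f"unknown operational function {self.operational_function!r}"
            )
        alpha = _check_finite("alpha", np.atleast_1d(self.alpha))
        if np.any(alpha < 0):
            raise ParameterError(f"alpha entries must be nonnegative, got {alpha}")
        object.__setattr__(self, "alpha", alpha)
        _check_finite("delta", self.delta)
        rho = _check_finite("rho", np.atleast_1d(self.rho))
        if np.any(rho <= 0):
            raise ParameterError(f"all rho must be positive, got {rho}")
        object.__setattr__(self, "rho", rho)
        if self.dimension_of_item is not None:
            d = int(self.dimension_of_item)
            if not 1 <= d <= alpha.size:
                raise ParameterError(
                    f"dimension_of_item must be in 1..{alpha.size}, got {d}"
                )


# ---------------------------------------------------------------------------
# operational functions
# ---------------------------------------------------------------------------

def _logcosh(x: np.ndarray) -> np.ndarray:
    # log cosh(x) = |x| + log1p(exp(-2|x|)) - log 2, overflow-free
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - _LOG2


def _gum_coeffs(C: int) -> tuple[np.ndarray, np.ndarray]:
    half = (2 * C + 1) / 2.0
    k = np.arange(1, C + 1, dtype=float)
    return half + 1.0 - k, half - k


def _log_psi_each(v: np.ndarray, kind: str, C: int) -> np.ndarray:
    """log psi_k(v_k) applied elementwise along a trailing axis of length C."""
    v = np.asarray(v, dtype=float)
    if kind == "ALM":
        return np.abs(v)
    if kind == "SSLM":
        return v * v
    if kind == "PARELLA":
        with np.errstate(divide="ignore"):
            return 2.0 * np.log(np.abs(v))
    if kind == "HCM":
        return _logcosh(v)
    if kind == "GUM":
        a, b = _gum_coeffs(C)
        return _logcosh(a * v) - _logcosh(b * v)
    raise ConfigurationError(f"unknown operational function {kind!r}")


def _log_psi_k(x: np.ndarray, kind: str, C: int) -> np.ndarray:
    """log psi_k(x) for k = 1..C; output shape = x.shape + (C,)."""
    x = np.asarray(x, dtype=float)
    if kind == "GUM":
        return _log_psi_each(x[..., None], kind, C)
    base = _log_psi_each(x, kind, C)
    return np.broadcast_to(base[..., None], base.shape + (C,))


def _dlog_psi_each(v: np.ndarray, kind: str, C: int) -> np.ndarray:
    """d/dv log psi_k(v), elementwise along a trailing axis of length C."""
    v = np.asarray(v, dtype=float)
    if kind == "ALM":
        return np.sign(v)
    if kind == "SSLM":
        return 2.0 * v
    if kind == "PARELLA":
        safe = np.where(np.abs(v) < _XEPS, _XEPS, v)
        return 2.0 / safe
    if kind == "HCM":
        return np.tanh(v)
    if kind == "GUM":
        a, b = _gum_coeffs(C)
        return a * np.tanh(a * v) - b * np.tanh(b * v)
    raise ConfigurationError(f"unknown operational function {kind!r}")


def _dlog_psi_k(x: np.ndarray, kind: str, C: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if kind == "GUM":
        return _dlog_psi_each(x[..., None], kind, C)
    base = _dlog_psi_each(x, kind, C)
    return np.broadcast_to(base[..., None], base.shape + (C,))


def psi(x, kind: str, k: Optional[int] = None, C: Optional[int] = None):
    """Operational function :math:`\\psi_k(x)` of Luo's unfolding family.

    For ``GUM`` the function depends on the category index ``k`` (1..C) and
    the scale ``C``; for the other four kinds ``k`` and ``C`` are ignored.
    Every kind is nonnegative, symmetric (``psi(x) == psi(-x)``) and
    nondecreasing in ``|x|``.
    """
    x = np.asarray(x, dtype=float)
    if kind not in OPERATIONAL_FUNCTIONS:
        raise ConfigurationError(f"unknown operational function {kind!r}")
    if kind == "GUM":
        if k is None or C is None:
            raise ConfigurationError("GUM requires the category index k and C")
        if not 1 <= int(k) <= int(C):
            raise ConfigurationError(f"k must lie in 1..{C}, got {k}")
        a, b = _gum_coeffs(int(C))
        return np.exp(_logcosh(a[k - 1] * x) - _logcosh(b[k - 1] * x))
    if kind == "ALM":
        return np.exp(np.abs(x))
    if kind == "SSLM":
        return np.exp(x * x)
    if kind == "PARELLA":
        return x * x
    return np.cosh(x)


# ---------------------------------------------------------------------------
# GGUM / unit-threshold family (vectorized cores)
# ---------------------------------------------------------------------------

def _center(dlognum: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Turn d log(numerator) into d log(probability): subtract E_P[d log num]."""
    return dlognum - (P * dlognum).sum(axis=-1, keepdims=True)


def ggum_logprob_array(t, alpha, delta, tau_free, C, grad=False):
    """Log category probabilities of the GGUM family on a node grid.

    Parameters
    ----------
    t : (Q,) latent-trait nodes
    alpha, delta : (I,) item discriminations and locations
    tau_free : (C,) or (I, C) thresholds tau_1..tau_C (tau_0 = 0 implied);
        a 1-D array means thresholds shared by all items
    grad : also return d log P with respect to delta, alpha and tau

    Returns
    -------
    logP : (I, Q, C+1) array; with ``grad=True`` also a dict with entries
    ``delta`` (I,Q,C+1), ``alpha`` (I,Q,C+1) and ``tau`` (I,Q,C+1,C).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    tau_free = np.asarray(tau_free, dtype=float)
    if tau_free.ndim == 1:
        tau_free = tau_free[None, :]
    M = 2 * C + 1
    z = np.arange(C + 1, dtype=float)
    # cumulative thresholds T_z = sum_{k=0}^{z} tau_k with tau_0 = 0
    Tz = np.concatenate(
        [np.zeros((tau_free.shape[0], 1)), np.cumsum(tau_free, axis=1)], axis=1
    )  # (1 or I, C+1)
    d = t[None, :] - delta[:, None]                     # (I, Q)
    al = alpha[:, None, None]
    u1 = al * (z * d[..., None] - Tz[:, None, :])       # (I, Q, C+1)
    u2 = al * ((M - z) * d[..., None] - Tz[:, None, :])
    lognum = np.logaddexp(u1, u2)
    logP = _normalize_log(lognum)
    if not grad:
        return logP
    P = np.exp(logP)
    w1 = expit(u1 - u2)
    w2 = 1.0 - w1
    ez = w1 * z + w2 * (M - z)                          # E[latent z-weight]
    g_delta = _center(-alpha[:, None, None] * ez, P)
    g_alpha = _center(w1 * u1 + w2 * u2, P) / alpha[:, None, None]
    # d lognum / d tau_m = -alpha * 1[z >= m], identical in both exponents
    ind = (z[:, None] >= np.arange(1, C + 1)[None, :]).astype(float)  # (C+1, C)
    surv = np.einsum("iqz,zm->iqm", P, ind)             # E_P 1[z >= m]
    g_tau = -alpha[:, None, None, None] * (ind[None, None] - surv[..., None, :])
    return logP, {"delta": g_delta, "alpha": g_alpha, "tau": g_tau}


def unit_logprob_array(t, alpha, delta, lam, C, grad=False):
    """Log category probabilities of the unit-threshold (lambda) family.

    ``lam`` is scalar-like of shape (1,) (common unit threshold) or (I,).
    Gradient dict keys: ``delta``, ``alpha``, ``lambda`` (I,Q,C+1).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    M = 2 * C + 1
    z = np.arange(C + 1, dtype=float)
    w = z * (M - z)                                     # z(M-z)
    d = t[None, :] - delta[:, None]
    al = alpha[:, None, None]
    shift = w * lam[:, None, None]
    u1 = al * (z * d[..., None] + shift)
    u2 = al * ((M - z) * d[..., None] + shift)
    lognum = np.logaddexp(u1, u2)
    logP = _normalize_log(lognum)
    if not grad:
        return logP
    P = np.exp(logP)
    w1 = expit(u1 - u2)
    w2 = 1.0 - w1
    ez = w1 * z + w2 * (M - z)
    g_delta = _center(-alpha[:, None, None] * ez, P)
    g_alpha = _center(w1 * u1 + w2 * u2, P) / alpha[:, None, None]
    g_lam = _center(al * np.broadcast_to(w, u1.shape), P)
    return logP, {"delta": g_delta, "alpha": g_alpha, "lambda": g_lam}


# ---------------------------------------------------------------------------
# Luo family (vectorized cores)
# ---------------------------------------------------------------------------

def _luo_core_from_a(a, C):
    """Log category probabilities from the binary log-odds a_k (..., C).

    a_k = log psi_k(rho_k) - log psi_k(x) so that P_k = expit(a_k); the
    category numerator is prod_{k<=z} P_k * prod_{k>z} Q_k.
    """
    logPk = log_expit(a)
    logQk = log_expit(-a)
    pref = np.zeros(a.shape[:-1] + (C + 1,))
    pref[..., 1:] = np.cumsum(logPk, axis=-1)           # sum_{k<=z} log P_k
    sfx = np.zeros(a.shape[:-1] + (C + 1,))
    # suffix[z] = sum_{k>z} log Q_k, built by reversed cumsum (no -inf - -inf)
    sfx[..., :-1] = np.cumsum(logQk[..., ::-1], axis=-1)[..., ::-1]
    lognum = pref + sfx
    logP = _normalize_log(lognum)
    return logP


def luo_logprob_array(t, alpha, delta, rho, kind, C, grad=False):
    """Log category probabilities of Luo's unidimensional family on a grid.

    ``rho`` has shape (C,) (thresholds common to all items) or (I, C).
    Gradient dict keys: ``delta``, ``alpha`` (I,Q,C+1) and ``rho``
    (I,Q,C+1,C).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ParameterError(f"all rho must be positive, got {rho}")
    if rho.ndim == 1:
        rho = rho[None, :]
    d = t[None, :] - delta[:, None]                     # (I, Q)
    x = alpha[:, None] * d
    lpx = _log_psi_k(x, kind, C)                        # (I, Q, C)
    lpr = _log_psi_each(rho, kind, C)[:, None, :]       # (1 or I, 1, C)
    a = lpr - lpx
    logP = _luo_core_from_a(a, C)
    if not grad:
        return logP
    P = np.exp(logP)
    Pk = expit(a)                                       # (I, Q, C)
    z = np.arange(C + 1)
    Uzk = (z[:, None] >= np.arange(1, C + 1)[None, :]).astype(float)  # (C+1, C)
    UmP = Uzk[None, None] - Pk[..., None, :]            # (I, Q, C+1, C)
    dlpx = _dlog_psi_k(x, kind, C)                      # (I, Q, C)
    # a_k = log psi_k(rho_k) - log psi_k(alpha (t - delta))
    da_ddelta = alpha[:, None, None] * dlpx
    da_dalpha = -d[..., None] * dlpx
    g_delta = _center((UmP * da_ddelta[..., None, :]).sum(axis=-1), P)
    g_alpha = _center((UmP * da_dalpha[..., None, :]).sum(axis=-1), P)
    dlpr = _dlog_psi_each(rho, kind, C)[:, None, None, :]
    g_rho = UmP * dlpr
    g_rho = g_rho - (P[..., None] * g_rho).sum(axis=-2, keepdims=True)
    return logP, {"delta": g_delta, "alpha": g_alpha, "rho": g_rho}


def mum_logprob_array(nodes, alpha, delta, dim_of_item, rho, kind, C, grad=False):
    """Log category probabilities of the between-item multidimensional model.

    Parameters
    ----------
    nodes : (Q, D) grid of latent coordinates
    alpha : (I,) discrimination of each item on its own dimension
    delta : (I,) item locations (shared across dimensions)
    dim_of_item : (I,) 0-based dimension index of each item
    rho : (D, C) thresholds, common within a dimension

    Gradient dict keys: ``delta``, ``alpha`` (I,Q,C+1) and ``rho``
    (I,Q,C+1,C) -- each item's gradient applies to its own dimension's rho.
    """
    nodes = np.asarray(nodes, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    dim_of_item = np.asarray(dim_of_item, dtype=int)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ParameterError(f"all rho must be positive, got {rho}")
    coord = nodes[:, dim_of_item].T                     # (I, Q)
    diff = coord - delta[:, None]
    # between-item Euclidean distance collapses to |alpha| * |coord - delta|
    x = np.sqrt((alpha[:, None] * diff) ** 2)
    lpx = _log_psi_k(x, kind, C)
    lpr = _log_psi_each(rho[dim_of_item], kind, C)[:, None, :]
    a = lpr - lpx
    logP = _luo_core_from_a(a, C)
    if not grad:
        return logP
    P = np.exp(logP)
    Pk = expit(a)
    z = np.arange(C + 1)
    Uzk = (z[:, None] >= np.arange(1, C + 1)[None, :]).astype(float)
    UmP = Uzk[None, None] - Pk[..., None, :]
    dlpx = _dlog_psi_k(x, kind, C)
    xsafe = np.where(x < _XEPS, _XEPS, x)
    dx_ddelta = -(alpha[:, None] ** 2) * diff / xsafe
    dx_dalpha = alpha[:, None] * diff**2 / xsafe
    g_delta = _center(
        (UmP * (-dlpx * dx_ddelta[..., None])[..., None, :]).sum(axis=-1), P
    )
    g_alpha = _center(
        (UmP * (-dlpx * dx_dalpha[..., None])[..., None, :]).sum(axis=-1), P
    )
    dlpr = _dlog_psi_each(rho[dim_of_item], kind, C)[:, None, None, :]
    g_rho = UmP * dlpr
    g_rho = g_rho - (P[..., None] * g_rho).sum(axis=-2, keepdims=True)
    return logP, {"delta": g_delta, "alpha": g_alpha, "rho": g_rho}


# ---------------------------------------------------------------------------
# public scalar operations
# ---------------------------------------------------------------------------

def _as_scale(scale) -> CategoryScale:
    if isinstance(scale, CategoryScale):
        return scale
    return CategoryScale(int(scale))


def ggum_probs(theta: float, params: GgumItemParams, scale) -> np.ndarray:
    """Category probabilities P(Z = z | theta), z = 0..C, for the GGUM (UM8 form)."""
    scale = _as_scale(scale)
    theta = float(_check_finite("theta", theta))
    if params.tau is None:
        raise ParameterError("ggum_probs requires tau thresholds (use unit_probs for lambda)")
    if params.tau.size != scale.C + 1:
        raise ParameterError(
            f"tau must have length C+1 = {scale.C + 1}, got {params.tau.size}"
        )
    logP = ggum_logprob_array(
        [theta], [params.alpha], [params.delta], params.tau[1:], scale.C
    )
    return np.exp(logP[0, 0])


def unit_probs(theta: float, params: GgumItemParams, scale) -> np.ndarray:
    """Category probabilities for the unit-threshold (lambda) family (UM6 form)."""
    scale = _as_scale(scale)
    theta = float(_check_finite("theta", theta))
    if params.lambda_ is None:
        raise ParameterError("unit_probs requires the unit threshold lambda_")
    logP = unit_logprob_array(
        [theta], [params.alpha], [params.delta], [params.lambda_], scale.C
    )
    return np.exp(logP[0, 0])


def luo_probs(theta: float, params: LuoItemParams, scale) -> np.ndarray:
    """Category probabilities for Luo's general unidimensional family."""
    scale = _as_scale(scale)
    theta = float(_check_finite("theta", theta))
    if params.rho.size != scale.C:
        raise ParameterError(f"rho must have length C = {scale.C}, got {params.rho.size}")
    logP = luo_logprob_array(
        [theta], [params.alpha], [params.delta], params.rho,
        params.operational_function, scale.C,
    )
    return np.exp(logP[0, 0])


def mum_probs(theta, params: MumItemParams, scale) -> np.ndarray:
    """Category probabilities for the multidimensional unfolding model.

    ``theta`` is a length-D coordinate vector; the distance is the weighted
    Euclidean norm of ``alpha * (theta - delta)`` across dimensions.
    """
    scale = _as_scale(scale)
    theta = _check_finite("theta", np.atleast_1d(theta))
    if theta.size != params.alpha.size:
        raise ParameterError(
            f"theta has {theta.size} coordinates but alpha has {params.alpha.size}"
        )
    if params.rho.size != scale.C:
        raise ParameterError(f"rho must have length C = {scale.C}, got {params.rho.size}")
    dist = float(np.sqrt(np.sum((params.alpha * (theta - params.delta)) ** 2)))
    lpx = _log_psi_k(np.array(dist), params.operational_function, scale.C)
    lpr = _log_psi_each(params.rho, params.operational_function, scale.C)
    a = lpr - lpx
    return np.exp(_luo_core_from_a(a[None, :], scale.C)[0])


def fisher_information(theta, params, scale):
    """Fisher information of theta: I = sum_z [d log P(z)/d theta]^2 P(z).

    For multidimensional items a per-coordinate information vector is
    returned.  The PARELLA kernel at theta = delta has a degenerate category
    distribution; ``+inf`` is returned there as a sentinel.
    """
    scale = _as_scale(scale)
    C = scale.C
    if isinstance(params, GgumItemParams):
        theta = float(_check_finite("theta", theta))
        if params.tau is not None:
            logP, g = ggum_logprob_array(
                [theta], [params.alpha], [params.delta], params.tau[1:], C, grad=True
            )
        else:
            logP, g = unit_logprob_array(
                [theta], [params.alpha], [params.delta], [params.lambda_], C, grad=True
            )
        P = np.exp(logP[0, 0])
        dtheta = -g["delta"][0, 0]          # kernels depend on theta - delta only
        return float(np.sum(P * dtheta**2))
    if isinstance(params, LuoItemParams):
        theta = float(_check_finite("theta", theta))
        if params.operational_function == "PARELLA" and theta == params.delta:
            return np.inf
        logP, g = luo_logprob_array(
            [theta], [params.alpha], [params.delta], params.rho,
            params.operational_function, C, grad=True,
        )
        P = np.exp(logP[0, 0])
        dtheta = -g["delta"][0, 0]
        return float(np.sum(P * dtheta**2))
    if isinstance(params, MumItemParams):
        theta = _check_finite("theta", np.atleast_1d(theta))
        dist2 = np.sum((params.alpha * (theta - params.delta)) ** 2)
        dist = float(np.sqrt(dist2))
        if params.operational_function == "PARELLA" and dist == 0.0:
            return np.full(theta.size, np.inf)
        lpx = _log_psi_k(np.array(dist), params.operational_function, C)
        lpr = _log_psi_each(params.rho, params.operational_function, C)
        a = (lpr - lpx)[None, :]
        logP = _luo_core_from_a(a, C)[0]
        P = np.exp(logP)
        Pk = expit(a[0])
        dlpx = _dlog_psi_each(
            np.full(C, dist), params.operational_function, C
        )
        dsafe = max(dist, _XEPS)
        info = np.empty(theta.size)
        z = np.arange(C + 1)
        Uzk = (z[:, None] >= np.arange(1, C + 1)[None, :]).astype(float)
        for d in range(theta.size):
            ddist = params.alpha[d] ** 2 * (theta[d] - params.delta) / dsafe
            da = -dlpx * ddist                  # (C,)
            gz = ((Uzk - Pk[None, :]) * da).sum(axis=1)
            gz = gz - np.sum(P * gz)
            info[d] = np.sum(P * gz**2)
        return info
    raise ConfigurationError(f"unsupported parameter type {type(params)!r}")
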