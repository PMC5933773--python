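"""Marginal maximum likelihood estimation by EM for unfolding models.

The observed-data log-likelihood marginalizes the latent trait over a fixed
quadrature grid,

.. math::

    \\log L(\\xi) = \\sum_s n_s \\log \\sum_q w_q
        \\prod_i \\Pr(Z_i = x_{si} \\mid V_q, \\xi_i)^{\\chi(x_{si})},

where patterns ``s`` are the unique response vectors with counts ``n_s`` and
``chi`` skips missing entries.  The E-step forms the expected response
frequencies ``r_izq`` from the node posterior of each pattern; the M-step
maximizes the complete-data log-likelihood
``sum_q sum_z r_izq log Pr(z | V_q, xi_i)`` with a bounded quasi-Newton
(L-BFGS-B) update using analytic gradients, treating all free item
parameters as one block (the blocks are separable across items except for
thresholds constrained equal across items, which couple them).  Free latent
density parameters (the variance for UM1-UM4, the pairwise correlations for
the multidimensional models) are updated by maximizing the expected prior
mass term ``sum_q R_q log w_q`` in the same cycle.

Constraint systems follow the standard model taxonomy: UM1/UM2/UM5/UM6 are
the unit-threshold (lambda) family, UM3/UM4/UM7/UM8 the tau-threshold GGUM
family, with discrimination fixed at one for UM1-UM4 and free otherwise, and
thresholds shared across items for UM1/UM3/UM5/UM7.  Luo's kernels (ALM,
SSLM, PARELLA, HCM, GUM) default to common rho thresholds; the
multidimensional variants ("MUM-HCM", ...) use a between-item loading
structure with unit latent variances and free correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (
    ConfigurationError,
    DataError,
    NumericalError,
    ParameterError,
)
from .kernels import (
    OPERATIONAL_FUNCTIONS,
    ggum_logprob_array,
    luo_logprob_array,
    mum_logprob_array,
    unit_logprob_array,
)
from .latent import LatentDensity, QuadratureGrid, build_grid, density_weights

__all__ = [
    "ResponseData",
    "ModelSpec",
    "ParamSet",
    "EStepTables",
    "FitResult",
    "marginal_loglik",
    "estep",
    "complete_data_gradient",
    "mstep",
    "fit_mml_em",
    "default_starts",
    "default_grid",
]

LOG_TINY = float(np.log(1e-300))

BOUNDS = {
    "alpha": (1e-3, 10.0),
    "delta": (-6.0, 6.0),
    "tau": (-6.0, 6.0),
    "lambda": (-6.0, 6.0),
    "rho": (1e-3, 6.0),
    "sigma2": (0.04, 9.0),
    "corr": (-0.95, 0.95),
}

_UM_TABLE = {
    # kernel: (family, alpha_free, threshold_mode, sigma2_free)
    "UM1": ("unit", False, "common", True),
    "UM2": ("unit", False, "item", True),
    "UM3": ("ggum", False, "common", True),
    "UM4": ("ggum", False, "item", True),
    "UM5": ("unit", True, "common", False),
    "UM6": ("unit", True, "item", False),
    "UM7": ("ggum", True, "common", False),
    "UM8": ("ggum", True, "item", False),
}


# ---------------------------------------------------------------------------
# response data
# ---------------------------------------------------------------------------

class ResponseData:
    """Persons x items integer category codes with missingness.

    Codes are 0-based (0..C); missing responses are stored as -1.  Response
    patterns are collapsed to unique rows with counts for the likelihood
    computations, which leaves results identical to the uncollapsed form.
    """

    def __init__(self, codes: np.ndarray, C: int):
        codes = np.asarray(codes)
        if codes.ndim != 2:
            raise DataError(f"codes must be 2-D (persons x items), got {codes.shape}")
        codes = codes.astype(np.int64)
        C = int(C)
        bad = (codes > C) | (codes < -1)
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise DataError(
                f"code {codes[r, c]} out of range 0..{C} at person {r}, item {c}"
            )
        self.codes = codes
        self.C = C
        self._patterns: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def n_persons(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean indicator of observed (non-missing) responses."""
        return self.codes >= 0

    def collapse(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique response patterns and their counts (sum of counts = persons)."""
        if self._patterns is None:
            pat, cnt = np.unique(self.codes, axis=0, return_counts=True)
            self._patterns = (pat, cnt.astype(float))
        return self._patterns


# ---------------------------------------------------------------------------
# model specification and parameter collection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Kernel choice plus the constraint map defining the free parameters."""

    kernel: str
    n_items: int
    n_categories: int                       # C
    family: str                             # "ggum" | "unit" | "luo" | "mum"
    op_kind: Optional[str] = None           # operational function for luo/mum
    alpha_free: bool = True
    threshold_mode: str = "item"            # "item" | "common"
    sigma2_free: bool = False
    corr_free: bool = False
    n_dims: int = 1
    item_dimension: Optional[np.ndarray] = None   # (I,) 0-based, mum only

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_categories < 1:
            raise ConfigurationError("need n_items >= 1 and n_categories >= 1")
        if self.threshold_mode not in ("item", "common"):
            raise ConfigurationError(f"bad threshold_mode {self.threshold_mode!r}")
        if self.family == "mum":
            if self.item_dimension is None:
                raise ConfigurationError("mum models need item_dimension")
            dims = np.asarray(self.item_dimension, dtype=int)
            if dims.size != self.n_items or dims.min() < 0 or dims.max() >= self.n_dims:
                raise ConfigurationError("item_dimension out of range")
            object.__setattr__(self, "item_dimension", dims)

    @property
    def C(self) -> int:
        return self.n_categories

    @property
    def n_thresholds(self) -> int:
        """Free thresholds per item/block: C for tau and rho, 1 for lambda."""
        return 1 if self.family == "unit" else self.n_categories

    @classmethod
    def from_kernel(
        cls,
        kernel: str,
        n_items: int,
        n_categories: int,
        n_dims: int = 1,
        item_dimension: Optional[Sequence[int]] = None,
        threshold_mode: Optional[str] = None,
        alpha_free: Optional[bool] = None,
        sigma2_free: Optional[bool] = None,
    ) -> "ModelSpec":
        """Build the standard constraint system for a named kernel.

        ``kernel`` is one of UM1..UM8, one of Luo's operational-function ids
        (ALM, SSLM, PARELLA, HCM, GUM), or ``"MUM-<id>"`` for the
        multidimensional between-item variant.
        """
        kernel = str(kernel).upper()
        if kernel in _UM_TABLE:
            family, afree, tmode, s2free = _UM_TABLE[kernel]
            return cls(
                kernel=kernel, n_items=n_items, n_categories=n_categories,
                family=family, op_kind=None,
                alpha_free=afree if alpha_free is None else alpha_free,
                threshold_mode=tmode if threshold_mode is None else threshold_mode,
                sigma2_free=s2free if sigma2_free is None else sigma2_free,
            )
        if kernel in OPERATIONAL_FUNCTIONS:
            return cls(
                kernel=kernel, n_items=n_items, n_categories=n_categories,
                family="luo", op_kind=kernel,
                alpha_free=True if alpha_free is None else alpha_free,
                threshold_mode="common" if threshold_mode is None else threshold_mode,
                sigma2_free=False if sigma2_free is None else sigma2_free,
            )
        if kernel.startswith("MUM-") and kernel[4:] in OPERATIONAL_FUNCTIONS:
            if item_dimension is None:
                raise ConfigurationError("MUM kernels need item_dimension")
            dims = np.asarray(item_dimension, dtype=int)
            return cls(
                kernel=kernel, n_items=n_items, n_categories=n_categories,
                family="mum", op_kind=kernel[4:],
                alpha_free=True, threshold_mode="common",
                sigma2_free=False, corr_free=True,
                n_dims=int(n_dims), item_dimension=dims,
            )
        raise ConfigurationError(f"unknown kernel {kernel!r}")

    # ---- free-parameter layout -------------------------------------------

    def param_names(self, include_density: bool = True) -> list[str]:
        """Names of the free parameters in canonical packing order."""
        I, C, K = self.n_items, self.n_categories, self.n_thresholds
        tname = {"ggum": "tau", "unit": "lambda", "luo": "rho", "mum": "rho"}[
            self.family
        ]
        names = [f"delta_{i + 1}" for i in range(I)]
        if self.alpha_free:
            names += [f"alpha_{i + 1}" for i in range(I)]
        if self.family == "mum":
            for d in range(self.n_dims):
                names += [f"rho_d{d + 1}_{k + 1}" for k in range(K)]
        elif self.threshold_mode == "item":
            for i in range(I):
                if K == 1:
                    names.append(f"lambda_{i + 1}")
                else:
                    names += [f"{tname}_{i + 1}_{k + 1}" for k in range(K)]
        else:
            if K == 1:
                names.append("lambda")
            else:
                names += [f"{tname}_{k + 1}" for k in range(K)]
        if include_density:
            if self.sigma2_free:
                names.append("sigma2")
            if self.corr_free:
                names += [
                    f"corr_{a + 1}{b + 1}"
                    for a, b in combinations(range(self.n_dims), 2)
                ]
        return names

    def param_families(self, include_density: bool = True) -> list[str]:
        """Parameter family label ("delta", "alpha", ...) per packed entry."""
        fams = []
        for n in self.param_names(include_density):
            fams.append(n.split("_")[0])
        return fams

    def bounds(self, include_density: bool = True) -> list[tuple[float, float]]:
        tkey = {"ggum": "tau", "unit": "lambda", "luo": "rho", "mum": "rho"}[
            self.family
        ]
        out = []
        for fam in self.param_families(include_density):
            key = fam if fam in ("delta", "alpha", "sigma2", "corr") else tkey
            out.append(BOUNDS[key])
        return out


def _default_thresh(spec: ModelSpec) -> np.ndarray:
    K = spec.n_thresholds
    if spec.family == "mum":
        return np.full((spec.n_dims, K), 1.0)
    if spec.threshold_mode == "item":
        return np.full((spec.n_items, K), -0.5 if spec.family == "ggum" else 1.0)
    return np.full(K, -0.5 if spec.family == "ggum" else 1.0)


@dataclass
class ParamSet:
    """Full parameter collection xi: item parameters plus density parameters.

    ``thresh`` is (I, K) in item mode, (K,) in common mode, (D, K) for the
    multidimensional models, where K = C for tau/rho and 1 for lambda.
    Fixed parameters keep their constrained values (alpha = 1, sigma2 = 1,
    corr = 0) and are simply excluded from the packed free vector.
    """

    delta: np.ndarray
    alpha: np.ndarray
    thresh: np.ndarray
    sigma2: float = 1.0
    corr: Optional[np.ndarray] = None

    def copy(self) -> "ParamSet":
        return ParamSet(
            self.delta.copy(), self.alpha.copy(), self.thresh.copy(),
            float(self.sigma2), None if self.corr is None else self.corr.copy(),
        )

    def density(self, spec: ModelSpec) -> LatentDensity:
        if spec.n_dims == 1:
            return LatentDensity(
                np.zeros(1), np.array([[self.sigma2]]),
                free_variance=spec.sigma2_free,
            )
        sigma = np.eye(spec.n_dims)
        if self.corr is not None:
            for (a, b), c in zip(combinations(range(spec.n_dims), 2), self.corr):
                sigma[a, b] = sigma[b, a] = c
        return LatentDensity(
            np.zeros(spec.n_dims), sigma, free_correlations=spec.corr_free
        )

    # ---- packing ---------------------------------------------------------

    def pack(self, spec: ModelSpec, include_density: bool = True) -> np.ndarray:
        parts = [self.delta]
        if spec.alpha_free:
            parts.append(self.alpha)
        parts.append(np.ravel(self.thresh))
        if include_density:
            if spec.sigma2_free:
                parts.append([self.sigma2])
            if spec.corr_free:
                parts.append(self.corr)
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    @classmethod
    def unpack(
        cls, vec: np.ndarray, spec: ModelSpec,
        template: Optional["ParamSet"] = None,
        include_density: bool = True,
    ) -> "ParamSet":
        vec = np.asarray(vec, dtype=float)
        I, K = spec.n_items, spec.n_thresholds
        pos = 0
        delta = vec[pos:pos + I].copy(); pos += I
        if spec.alpha_free:
            alpha = vec[pos:pos + I].copy(); pos += I
        else:
            alpha = np.ones(I)
        if spec.family == "mum":
            shape = (spec.n_dims, K)
        elif spec.threshold_mode == "item":
            shape = (I, K)
        else:
            shape = (K,)
        n_t = int(np.prod(shape))
        thresh = vec[pos:pos + n_t].reshape(shape).copy(); pos += n_t
        sigma2 = 1.0 if template is None else float(template.sigma2)
        corr = None
        if spec.n_dims > 1:
            n_pairs = spec.n_dims * (spec.n_dims - 1) // 2
            corr = (
                np.zeros(n_pairs) if template is None or template.corr is None
                else template.corr.copy()
            )
        if include_density:
            if spec.sigma2_free:
                sigma2 = float(vec[pos]); pos += 1
            if spec.corr_free:
                n_pairs = spec.n_dims * (spec.n_dims - 1) // 2
                corr = vec[pos:pos + n_pairs].copy(); pos += n_pairs
        if pos != vec.size:
            raise ConfigurationError(
                f"parameter vector has {vec.size} entries, expected {pos}"
            )
        return cls(delta, alpha, thresh, sigma2, corr)


# ---------------------------------------------------------------------------
# probability matrices and likelihood
# ---------------------------------------------------------------------------

def item_logprob_matrix(
    spec: ModelSpec, params: ParamSet, nodes: np.ndarray, grad: bool = False
):
    """Log category probabilities (I, Q, C+1) for every item at every node."""
    C = spec.n_categories
    if spec.family == "ggum":
        return ggum_logprob_array(
            np.ravel(nodes), params.alpha, params.delta, params.thresh, C, grad=grad
        )
    if spec.family == "unit":
        lam = params.thresh
        lam = lam[:, 0] if lam.ndim == 2 else np.broadcast_to(
            lam, (spec.n_items,)
        )
        return unit_logprob_array(
            np.ravel(nodes), params.alpha, params.delta, lam, C, grad=grad
        )
    if spec.family == "luo":
        return luo_logprob_array(
            np.ravel(nodes), params.alpha, params.delta, params.thresh,
            spec.op_kind, C, grad=grad,
        )
    if spec.family == "mum":
        return mum_logprob_array(
            np.atleast_2d(nodes), params.alpha, params.delta,
            spec.item_dimension, params.thresh, spec.op_kind, C, grad=grad,
        )
    raise ConfigurationError(f"unknown family {spec.family!r}")


def _log_weights(spec: ModelSpec, params: ParamSet, grid: QuadratureGrid) -> np.ndarray:
    return np.log(density_weights(grid, params.density(spec)))


def _pattern_posterior(patterns, counts, logP, logw):
    """Posterior over nodes per pattern plus the marginal log-likelihood."""
    S = patterns.shape[0]
    lp = np.maximum(logP, LOG_TINY)
    acc = np.broadcast_to(logw, (S, logw.size)).copy()
    for i in range(patterns.shape[1]):
        idx = patterns[:, i]
        valid = idx >= 0
        if np.all(valid):
            acc += lp[i].T[idx]
        elif np.any(valid):
            acc[valid] += lp[i].T[idx[valid]]
    m = acc.max(axis=1)
    un = np.exp(acc - m[:, None])
    tot = un.sum(axis=1)
    if np.any(~np.isfinite(m)) or np.any(tot <= 0):
        s = int(np.argmax(~np.isfinite(m) | (tot <= 0)))
        raise NumericalError(f"likelihood underflow for response pattern {s}")
    ll = float(np.sum(counts * (m + np.log(tot))))
    return un / tot[:, None], ll


def marginal_loglik(
    data: ResponseData, spec: ModelSpec, params: ParamSet, grid: QuadratureGrid
) -> float:
    """Observed-data (marginal) log-likelihood on the quadrature grid."""
    patterns, counts = data.collapse()
    logP = item_logprob_matrix(spec, params, grid.nodes)
    logw = _log_weights(spec, params, grid)
    _, ll = _pattern_posterior(patterns, counts, logP, logw)
    return ll


@dataclass
class EStepTables:
    """Expected response frequencies r_izq plus per-node posterior mass."""

    r: np.ndarray            # (I, C+1, Q)
    node_mass: np.ndarray    # (Q,) total posterior mass R_q
    loglik: float


def estep(
    data: ResponseData, spec: ModelSpec, params: ParamSet, grid: QuadratureGrid
) -> EStepTables:
    """E-step: expected frequency of response z for item i at node q."""
    patterns, counts = data.collapse()
    logP = item_logprob_matrix(spec, params, grid.nodes)
    logw = _log_weights(spec, params, grid)
    post, ll = _pattern_posterior(patterns, counts, logP, logw)
    wpost = counts[:, None] * post
    I, C = spec.n_items, spec.n_categories
    r = np.zeros((I, C + 1, grid.n_nodes))
    for i in range(I):
        idx = patterns[:, i]
        for z in range(C + 1):
            sel = idx == z
            if np.any(sel):
                r[i, z] = wpost[sel].sum(axis=0)
    return EStepTables(r=r, node_mass=wpost.sum(axis=0), loglik=ll)


def _estep_between_item(data, spec, params, grid, mum_axis):
    """E-step for between-item multidimensional models on the axis grid.

    Probabilities are evaluated once per axis value and expanded to the
    tensor grid for the pattern posterior; the expected counts are then
    collapsed back onto the axis of each item's dimension, which is all the
    M-step needs.
    """
    axis, idx, onehot, axis_nodes = mum_axis
    patterns, counts = data.collapse()
    logP_axis = item_logprob_matrix(spec, params, axis_nodes)  # (I, A, C+1)
    dims = spec.item_dimension
    logP = logP_axis[np.arange(spec.n_items)[:, None], idx[dims], :]
    logw = _log_weights(spec, params, grid)
    post, ll = _pattern_posterior(patterns, counts, logP, logw)
    wpost = counts[:, None] * post
    w_axis = [wpost @ oh for oh in onehot]                  # D x (S, A)
    I, C, A = spec.n_items, spec.n_categories, axis.size
    r = np.zeros((I, C + 1, A))
    for i in range(I):
        col = patterns[:, i]
        wa = w_axis[dims[i]]
        for z in range(C + 1):
            sel = col == z
            if np.any(sel):
                r[i, z] = wa[sel].sum(axis=0)
    tables = EStepTables(r=r, node_mass=wpost.sum(axis=0), loglik=ll)
    return tables, axis_nodes


# ---------------------------------------------------------------------------
# complete-data objective (M-step)
# ---------------------------------------------------------------------------

def _cd_value_grad(vec, spec, params, r, nodes):
    """Negative complete-data log-likelihood and gradient for the item block."""
    p = ParamSet.unpack(vec, spec, template=params, include_density=False)
    logP, g = item_logprob_matrix(spec, p, nodes, grad=True)
    lp = np.maximum(logP, LOG_TINY)
    # r is (I, C+1, Q); logP is (I, Q, C+1)
    f = -np.einsum("izq,iqz->", r, lp)
    parts = [-np.einsum("izq,iqz->i", r, g["delta"])]
    if spec.alpha_free:
        parts.append(-np.einsum("izq,iqz->i", r, g["alpha"]))
    tkey = "lambda" if spec.family == "unit" else (
        "tau" if spec.family == "ggum" else "rho"
    )
    gt = g[tkey]
    if spec.family == "unit":
        per_item = -np.einsum("izq,iqz->i", r, gt)       # (I,)
        if spec.threshold_mode == "item":
            parts.append(per_item)
        else:
            parts.append(per_item.sum(keepdims=True))
    else:
        per_item = -np.einsum("izq,iqzk->ik", r, gt)     # (I, K)
        if spec.family == "mum":
            acc = np.zeros((spec.n_dims, spec.n_thresholds))
            np.add.at(acc, spec.item_dimension, per_item)
            parts.append(acc.ravel())
        elif spec.threshold_mode == "item":
            parts.append(per_item.ravel())
        else:
            parts.append(per_item.sum(axis=0))
    grad = np.concatenate(parts)
    return f, grad


def complete_data_gradient(
    item: int, r: EStepTables, spec: ModelSpec, params: ParamSet,
    grid: QuadratureGrid,
) -> np.ndarray:
    """Gradient of the complete-data log-likelihood for one item's parameters.

    Order: delta_i, alpha_i (if free), then the thresholds that item i's
    probabilities depend on (its own row in item mode, the shared block in
    common mode).  Signs follow the log-likelihood (ascent direction).
    """
    logP, g = item_logprob_matrix(spec, params, grid.nodes, grad=True)
    ri = r.r[item]                                        # (C+1, Q)
    out = [np.einsum("zq,qz->", ri, g["delta"][item])]
    if spec.alpha_free:
        out.append(np.einsum("zq,qz->", ri, g["alpha"][item]))
    tkey = "lambda" if spec.family == "unit" else (
        "tau" if spec.family == "ggum" else "rho"
    )
    gt = g[tkey]
    if spec.family == "unit":
        out.append(np.einsum("zq,qz->", ri, gt[item]))
    else:
        out.extend(np.einsum("zq,qzk->k", ri, gt[item]))
    return np.asarray(out, dtype=float)


def _density_update(spec, params, grid, node_mass):
    """Exact discretized M-step for the free latent density parameters."""
    if spec.n_dims == 1 and spec.sigma2_free:
        V2 = grid.nodes[:, 0] ** 2

        def neg(s2):
            logw = -0.5 * V2 / s2
            logw -= np.log(np.sum(np.exp(logw - logw.max()))) + logw.max()
            return -float(np.dot(node_mass, logw))

        lo, hi = BOUNDS["sigma2"]
        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        if np.isfinite(res.x):
            params.sigma2 = float(res.x)
    elif spec.corr_free and spec.n_dims > 1:
        pairs = list(combinations(range(spec.n_dims), 2))

        def neg(c):
            sigma = np.eye(spec.n_dims)
            for (a, b), v in zip(pairs, c):
                sigma[a, b] = sigma[b, a] = v
            try:
                dens = LatentDensity(np.zeros(spec.n_dims), sigma)
            except ParameterError:
                return 1e12
            logw = dens.logpdf(grid.nodes)
            logw -= np.log(np.sum(np.exp(logw - logw.max()))) + logw.max()
            return -float(np.dot(node_mass, logw))

        res = optimize.minimize(
            neg, params.corr, method="L-BFGS-B",
            bounds=[BOUNDS["corr"]] * len(pairs),
            options={"maxiter": 25},
        )
        if np.all(np.isfinite(res.x)) and neg(res.x) <= neg(params.corr):
            params.corr = np.asarray(res.x, dtype=float)
    return params


def mstep(
    r: EStepTables, spec: ModelSpec, params: ParamSet, grid: QuadratureGrid,
    maxiter: int = 40, update_density: bool = True,
    nodes: Optional[np.ndarray] = None,
) -> ParamSet:
    """M-step: one bounded quasi-Newton pass on the complete-data objective.

    Returns an updated parameter collection; the complete-data objective
    never decreases (failed optimizer runs fall back to the previous
    values).  ``nodes`` overrides the evaluation nodes of the expected-count
    tables (used by the between-item fast path, where counts are collapsed
    onto the per-dimension axis).
    """
    nodes = grid.nodes if nodes is None else nodes
    x0 = params.pack(spec, include_density=False)
    res = optimize.minimize(
        _cd_value_grad, x0, args=(spec, params, r.r, nodes),
        jac=True, method="L-BFGS-B",
        bounds=spec.bounds(include_density=False),
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
    )
    x1 = res.x if np.all(np.isfinite(res.x)) else x0
    f0 = _cd_value_grad(x0, spec, params, r.r, nodes)[0]
    f1 = _cd_value_grad(x1, spec, params, r.r, nodes)[0]
    if not np.isfinite(f1) or f1 > f0:
        x1 = x0
    new = ParamSet.unpack(x1, spec, template=params, include_density=False)
    if update_density:
        new = _density_update(spec, new, grid, r.node_mass)
    return new


# ---------------------------------------------------------------------------
# starting values and the EM driver
# ---------------------------------------------------------------------------

def default_grid(spec: ModelSpec) -> QuadratureGrid:
    """50 equally spaced nodes on [-4, 4] (1-D) or 15 per dimension (D > 1)."""
    if spec.n_dims == 1:
        return build_grid((-4.0, 4.0), 50, 1)
    return build_grid((-4.0, 4.0), 15, spec.n_dims)


def default_starts(
    data: ResponseData, spec: ModelSpec,
    delta_signs: Optional[Sequence[float]] = None, seed: int = 0,
) -> ParamSet:
    """Deterministic starting values.

    Discriminations start at 1.  Locations start at +/-1 when the user
    supplies item polarity signs (recommended for unfolding models), else at
    a small seeded jitter.  Thresholds start from pooled category
    proportions: with q_k the pooled share of responses in category k or
    above, rho_k starts at 2 q_k (the half-point distance shrinks for rarer
    high categories) and tau_k at a damped logit of q_k.  The latent
    variance starts at 1 and correlations at 0.
    """
    I, C = spec.n_items, spec.n_categories
    obs = data.codes[data.codes >= 0]
    if obs.size == 0:
        q = np.linspace(0.7, 0.3, C)
    else:
        q = np.array([np.mean(obs >= k) for k in range(1, C + 1)])
    q = np.clip(q, 0.01, 0.99)
    if delta_signs is not None:
        signs = np.sign(np.asarray(delta_signs, dtype=float))
        signs[signs == 0] = 1.0
        if signs.size != I:
            raise ConfigurationError("delta_signs must have one entry per item")
        delta = signs * 1.0
    else:
        rng = np.random.default_rng(seed)
        delta = rng.uniform(-1.0, 1.0, I)
    alpha = np.ones(I)
    if spec.family == "ggum":
        tvals = np.clip(0.5 * np.log(q / (1 - q)) - 0.5, -2.0, 1.0)
    elif spec.family == "unit":
        tvals = np.array([0.3])
    else:
        tvals = np.clip(2.0 * q, 0.2, 2.5)
    K = spec.n_thresholds
    if spec.family == "mum":
        thresh = np.tile(tvals, (spec.n_dims, 1))
    elif spec.threshold_mode == "item":
        thresh = np.tile(tvals[:K], (I, 1))
    else:
        thresh = tvals[:K].copy()
    corr = None
    if spec.n_dims > 1:
        corr = np.zeros(spec.n_dims * (spec.n_dims - 1) // 2)
    return ParamSet(delta, alpha, thresh, 1.0, corr)


@dataclass
class FitResult:
    """MML-EM fit: estimates, log-likelihood and convergence trace."""

    spec: ModelSpec
    grid: QuadratureGrid
    estimates: ParamSet
    loglik: float
    n_iterations: int
    converged: bool
    trace: pd.DataFrame            # columns: loglik, max_change
    boundary: bool = False         # some estimate sits on a parameter bound

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names()

    def packed(self) -> np.ndarray:
        return self.estimates.pack(self.spec)


def fit_mml_em(
    data: ResponseData,
    spec: ModelSpec,
    grid: Optional[QuadratureGrid] = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    starts: Optional[ParamSet] = None,
    delta_signs: Optional[Sequence[float]] = None,
    seed: int = 0,
    mstep_maxiter: int = 15,
    verbose: bool = False,
) -> FitResult:
    """Fit an unfolding model by marginal maximum likelihood EM.

    Iterates E- and M-steps until the largest absolute parameter change
    falls below ``tol`` (default 1e-4) or ``max_iter`` cycles (default 500)
    elapse; ``converged`` reports which happened.  The observed-data
    log-likelihood is nondecreasing along the trace.
    """
    if data.n_items != spec.n_items:
        raise ConfigurationError(
            f"data has {data.n_items} items but spec expects {spec.n_items}"
        )
    if data.C != spec.n_categories:
        raise ConfigurationError("data and spec disagree on the category scale")
    if grid is None:
        grid = default_grid(spec)
    params = (starts or default_starts(data, spec, delta_signs, seed)).copy()
    # between-item fast path: item probabilities depend on a node only
    # through its coordinate on the item's dimension, so probabilities are
    # evaluated on the per-dimension axis and expected counts collapsed
    # onto it before the M-step.
    mum_axis = None
    if spec.family == "mum" and grid.rule == "rectangular" and spec.n_dims > 1:
        axis = np.unique(grid.nodes[:, 0])
        if axis.size == grid.points_per_dim:
            idx = np.stack(
                [np.searchsorted(axis, grid.nodes[:, d])
                 for d in range(spec.n_dims)]
            )                                               # (D, Q)
            onehot = [
                (idx[d][:, None] == np.arange(axis.size)[None, :]).astype(float)
                for d in range(spec.n_dims)
            ]                                               # D x (Q, A)
            mum_axis = (axis, idx, onehot,
                        np.tile(axis[:, None], (1, spec.n_dims)))
    vec_prev = params.pack(spec)
    ll_rows = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if mum_axis is not None:
            tables, axis_nodes = _estep_between_item(
                data, spec, params, grid, mum_axis
            )
            params = mstep(tables, spec, params, grid, maxiter=mstep_maxiter,
                           nodes=axis_nodes)
        else:
            tables = estep(data, spec, params, grid)
            params = mstep(tables, spec, params, grid, maxiter=mstep_maxiter)
        vec = params.pack(spec)
        change = float(np.max(np.abs(vec - vec_prev))) if vec.size else 0.0
        ll_rows.append((tables.loglik, change))
        if verbose:
            print(f"EM iter {n_iter:4d}  loglik {tables.loglik:.6f}  "
                  f"max change {change:.2e}")
        vec_prev = vec
        if change < tol:
            converged = True
            break
    loglik = marginal_loglik(data, spec, params, grid)
    trace = pd.DataFrame(ll_rows, columns=["loglik", "max_change"])
    vec = params.pack(spec)
    lo = np.array([b[0] for b in spec.bounds()])
    hi = np.array([b[1] for b in spec.bounds()])
    boundary = bool(np.any((vec - lo < 1e-6) | (hi - vec < 1e-6)))
    return FitResult(
        spec=spec, grid=grid, estimates=params, loglik=loglik,
        n_iterations=n_iter, converged=converged, trace=trace,
        boundary=boundary,
    )
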