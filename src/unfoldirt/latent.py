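"""Latent-trait density and fixed quadrature grids.

The marginal likelihood integrates the latent trait over a fixed rectangular
grid of equally spaced nodes (default 50 on [-4, 4] per dimension, tensorized
across dimensions) with weights proportional to a multivariate normal density
and renormalized to sum to one.  The renormalization makes the discretized
density a proper probability mass function, so posterior expectations and
expected-count tables are well scaled.  Gauss-Hermite nodes are available as
an alternative rule, but the rectangular rule is the default because it is
the convention of the estimation programs this package mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, ParameterError, ResourceError

__all__ = ["LatentDensity", "QuadratureGrid", "build_grid", "density_weights"]

_MAX_NODES = 10_000_000


@dataclass(frozen=True)
class LatentDensity:
    """Multivariate normal latent density N(mu, Sigma).

    ``mu`` is fixed at zero for identification in all supported models;
    ``free_variance`` / ``free_correlations`` record which density parameters
    the estimation routine may update.
    """

    mu: np.ndarray
    sigma: np.ndarray
    free_variance: bool = False
    free_correlations: bool = False

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if sigma.shape != (mu.size, mu.size):
            raise ParameterError(
                f"sigma must be {mu.size}x{mu.size}, got {sigma.shape}"
            )
        if not np.allclose(sigma, sigma.T):
            raise ParameterError("sigma must be symmetric")
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("sigma must be positive definite") from exc
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_dims(self) -> int:
        return self.mu.size

    @classmethod
    def standard(cls, n_dims: int = 1, **kw) -> "LatentDensity":
        return cls(np.zeros(n_dims), np.eye(n_dims), **kw)

    @classmethod
    def equicorrelated(cls, n_dims: int, corr: float, **kw) -> "LatentDensity":
        """Unit-variance density with all pairwise correlations equal."""
        sigma = np.full((n_dims, n_dims), float(corr))
        np.fill_diagonal(sigma, 1.0)
        return cls(np.zeros(n_dims), sigma, **kw)

    def logpdf(self, nodes: np.ndarray) -> np.ndarray:
        nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
        dev = nodes - self.mu
        try:
            chol = np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("sigma must be positive definite") from exc
        sol = np.linalg.solve(chol, dev.T)
        quad = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        k = self.n_dims
        return -0.5 * (quad + logdet + k * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed tensor-product node grid with normalized density weights."""

    nodes: np.ndarray          # (Q, D)
    weights: np.ndarray        # (Q,), sums to 1
    range: tuple[float, float]
    points_per_dim: int
    rule: str = "rectangular"

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_dims(self) -> int:
        return self.nodes.shape[1]


def build_grid(
    range: Sequence[float] = (-4.0, 4.0),
    points_per_dim: int = 50,
    n_dims: int = 1,
    density: Optional[LatentDensity] = None,
    rule: str = "rectangular",
) -> QuadratureGrid:
    """Build a quadrature grid of ``points_per_dim ** n_dims`` nodes.

    The rectangular rule places equally spaced nodes spanning ``range`` in
    each dimension; Gauss-Hermite uses probabilists' Hermite nodes scaled to
    the standard normal.  Weights come from ``density`` (standard normal by
    default) and are renormalized to sum to one.
    """
    lo, hi = float(range[0]), float(range[1])
    points_per_dim = int(points_per_dim)
    n_dims = int(n_dims)
    if points_per_dim < 2:
        raise ConfigurationError("points_per_dim must be >= 2")
    if n_dims < 1:
        raise ConfigurationError("n_dims must be >= 1")
    if hi <= lo:
        raise ConfigurationError(f"empty range ({lo}, {hi})")
    if float(points_per_dim) ** n_dims > _MAX_NODES:
        raise ResourceError(
            f"grid of {points_per_dim}^{n_dims} nodes exceeds {_MAX_NODES:g}"
        )
    if rule == "rectangular":
        axis = np.linspace(lo, hi, points_per_dim)
        base_logw = None
    elif rule == "gauss-hermite":
        # probabilists' nodes: x_i of He_n, weights already include exp(-x^2/2)
        x, w = np.polynomial.hermite_e.hermegauss(points_per_dim)
        axis = x
        base_logw = np.log(w)
    else:
        raise ConfigurationError(f"unknown quadrature rule {rule!r}")
    if n_dims == 1:
        nodes = axis[:, None]
    else:
        mesh = np.meshgrid(*([axis] * n_dims), indexing="ij")
        nodes = np.stack([m.ravel() for m in mesh], axis=1)
    grid = QuadratureGrid(
        nodes=nodes,
        weights=np.full(nodes.shape[0], 1.0 / nodes.shape[0]),
        range=(lo, hi),
        points_per_dim=points_per_dim,
        rule=rule,
    )
    if rule == "gauss-hermite":
        # GH weights replace the density factor for the standard normal only;
        # for a general density reweight by the density ratio.
        dens = density if density is not None else LatentDensity.standard(n_dims)
        logw = np.zeros(nodes.shape[0])
        for col in nodes.T:          # note: `range` is shadowed by the kwarg
            logw += base_logw[np.searchsorted(axis, col)]
        logw += dens.logpdf(nodes) + 0.5 * np.sum(nodes**2, axis=1)
        w = np.exp(logw - logw.max())
        weights = w / w.sum()
        return QuadratureGrid(nodes, weights, (lo, hi), points_per_dim, rule)
    dens = density if density is not None else LatentDensity.standard(n_dims)
    return QuadratureGrid(
        nodes, density_weights(grid, dens), (lo, hi), points_per_dim, rule
    )


def density_weights(grid: QuadratureGrid, density: LatentDensity) -> np.ndarray:
    """Normalized density mass at each node: w_q = f(V_q) / sum_q f(V_q)."""
    if density.n_dims != grid.n_dims:
        raise ParameterError(
            f"density has {density.n_dims} dims but grid has {grid.n_dims}"
        )
    logw = density.logpdf(grid.nodes)
    w = np.exp(logw - logw.max())
    return w / w.sum()
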