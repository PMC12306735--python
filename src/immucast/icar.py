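"""Intrinsic CAR (Besag) precision matrices, BYM2 scaling and PC priors.

The structured spatial effect uses the intrinsic conditional
autoregressive precision ``Q`` with ``Q_ii = degree(i)`` and
``Q_ij = -1`` for neighbours.  ``Q`` is rank deficient (one null vector
per connected component), so the effect is defined under per-component
sum-to-zero constraints.  The BYM2 parameterisation requires the
structured component to have unit *typical* marginal variance, achieved
by rescaling ``Q`` so that the geometric mean of the constrained
marginal variances equals one.

Penalized-complexity (PC) priors: an exponential prior on an effect
standard deviation calibrated by ``P(sigma > U) = alpha``, and the
distance-based prior on the BYM2 mixing proportion ``phi`` derived from
the Kullback–Leibler divergence between the BYM2 covariance and its
unstructured base model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gmean

from .graphs import RegionGraph

__all__ = [
    "IcarPrecision",
    "build_icar_precision",
    "scale_icar",
    "sample_icar",
    "bym2_effect",
    "pc_prior_scale_density",
    "pc_prior_scale_logpdf",
    "pc_prior_scale_rate",
    "PCPriorMixing",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class IcarPrecision:
    """ICAR precision with optional BYM2 scaling.

    ``Q`` is ordered like ``regions``; ``isolated`` flags degree-zero
    regions (zero row/column, excluded from scaling and from the
    structured effect).  After :func:`scale_icar`, ``scale_factor`` holds
    the geometric mean of the constrained marginal variances of ``Q`` and
    ``Q_star = scale_factor * Q`` has geometric-mean marginal variance 1.
    """

    Q: np.ndarray
    regions: tuple[str, ...]
    isolated: tuple[str, ...]
    components: tuple[tuple[str, ...], ...]
    scale_factor: float | None = None

    @property
    def Q_star(self) -> np.ndarray:
        if self.scale_factor is None:
            raise ValueError("precision not scaled yet; call scale_icar first")
        return self.scale_factor * self.Q

    def index_of(self, region_ids) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.regions)}
        return np.array([lookup[r] for r in region_ids], dtype=int)


def build_icar_precision(graph: RegionGraph) -> IcarPrecision:
    """Unscaled ICAR precision from adjacency (degree on the diagonal)."""
    if graph.n_regions == 0:
        raise ValueError("graph has no regions")
    regions = tuple(graph.region_ids)
    idx = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    Q = np.zeros((n, n))
    for e in graph.edges:
        a, b = tuple(e)
        Q[idx[a], idx[b]] -= 1.0
        Q[idx[b], idx[a]] -= 1.0
    deg = -Q.sum(axis=1)
    Q[np.diag_indices(n)] = deg
    isolated = tuple(r for r in regions if deg[idx[r]] == 0)
    comps = tuple(
        tuple(sorted(c, key=idx.get)) for c in graph.components() if len(c) > 1
    )
    return IcarPrecision(Q=Q, regions=regions, isolated=isolated, components=comps)


def _component_variances(prec: IcarPrecision) -> dict[str, float]:
    """Marginal variances of the sum-to-zero constrained ICAR, per component.

    For a connected component the null space of its precision block is the
    constant vector, so the Moore–Penrose pseudo-inverse *is* the covariance
    under the sum-to-zero constraint; its diagonal gives the variances.
    """
    out: dict[str, float] = {}
    for comp in prec.components:
        sel = prec.index_of(comp)
        block = prec.Q[np.ix_(sel, sel)]
        cov = np.linalg.pinv(block, hermitian=True)
        for r, v in zip(comp, np.diag(cov)):
            out[r] = float(v)
    return out


def scale_icar(prec: IcarPrecision) -> IcarPrecision:
    """Scale so the geometric-mean constrained marginal variance is one."""
    variances = _component_variances(prec)
    if not variances:
        raise ValueError(
            "scaling undefined: graph has no connected component with >= 2 regions"
        )
    factor = float(gmean(list(variances.values())))
    return replace(prec, scale_factor=factor)


def _component_eigens(prec: IcarPrecision, scaled: bool = True):
    """(indices, eigvals, eigvecs) per component of Q (or Q_star)."""
    Q = prec.Q_star if scaled else prec.Q
    out = []
    for comp in prec.components:
        sel = prec.index_of(comp)
        w, V = np.linalg.eigh(Q[np.ix_(sel, sel)])
        out.append((sel, w, V))
    return out


def sample_icar(prec: IcarPrecision, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw from the scaled ICAR under per-component sum-to-zero constraints.

    Returns an array of shape ``(size, n_regions)``; isolated regions get 0.
    """
    x = np.zeros((size, len(prec.regions)))
    for sel, w, V in _component_eigens(prec, scaled=True):
        pos = w > _EIG_TOL * w.max()
        z = rng.standard_normal((size, int(pos.sum())))
        x[:, sel] = z / np.sqrt(w[pos]) @ V[:, pos].T
    return x


def structured_covariance_eigenvalues(prec: IcarPrecision) -> np.ndarray:
    """Eigenvalues of the scaled, constrained structured covariance.

    These live on the sum-to-zero subspace (dimension n - #components) and
    feed the PC prior on the BYM2 mixing proportion.
    """
    vals = []
    for _sel, w, _V in _component_eigens(prec, scaled=True):
        pos = w > _EIG_TOL * w.max()
        vals.append(1.0 / w[pos])
    return np.concatenate(vals) if vals else np.array([])


def bym2_effect(u_star: np.ndarray, v: np.ndarray, phi: float, sigma: float) -> np.ndarray:
    """Combine scaled structured and iid components on the BYM2 scale.

    ``b = sigma * (sqrt(phi) * u_star + sqrt(1 - phi) * v)`` — ``sigma`` is
    the marginal standard deviation, ``phi`` the structured fraction.
    """
    u_star = np.asarray(u_star, dtype=float)
    v = np.asarray(v, dtype=float)
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if u_star.shape != v.shape:
        raise ValueError("u_star and v must have matching shapes")
    return sigma * (np.sqrt(phi) * u_star + np.sqrt(1.0 - phi) * v)


# -- PC prior on a standard deviation -----------------------------------------

def pc_prior_scale_rate(U: float, alpha: float) -> float:
    """Exponential rate lambda with ``P(sigma > U) = alpha``."""
    if U <= 0:
        raise ValueError("U must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return -np.log(alpha) / U


def pc_prior_scale_density(sigma, U: float, alpha: float):
    """PC prior density for an effect scale: Exp(rate = -ln(alpha)/U)."""
    lam = pc_prior_scale_rate(U, alpha)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return lam * np.exp(-lam * sigma)


def pc_prior_scale_logpdf(sigma, U: float, alpha: float):
    lam = pc_prior_scale_rate(U, alpha)
    return np.log(lam) - lam * np.asarray(sigma, dtype=float)


# -- PC prior on the BYM2 mixing proportion -----------------------------------

class PCPriorMixing:
    """Distance-based PC prior for the BYM2 mixing proportion ``phi``.

    The base model is the pure unstructured effect (``phi = 0``).  With
    ``gamma_j`` the eigenvalues of the scaled constrained structured
    covariance, the Kullback–Leibler distance is

    ``d(phi) = sqrt(sum_j [(1 - phi + phi*gamma_j) - 1 - log(1 - phi + phi*gamma_j)])``

    and the prior is exponential in ``d`` truncated to ``d([0, 1])``,
    with the rate solved so that ``P(phi < U) = alpha``.
    """

    def __init__(self, gamma: np.ndarray, U: float = 0.5, alpha: float = 2.0 / 3.0):
        gamma = np.asarray(gamma, dtype=float)
        if gamma.size == 0:
            raise ValueError("no structured eigenvalues: mixing prior undefined")
        if not 0.0 < U < 1.0 or not 0.0 < alpha < 1.0:
            raise ValueError("need U in (0,1) and alpha in (0,1)")
        self.gamma = gamma
        self.U = float(U)
        self.alpha = float(alpha)
        self._d_max = self.distance(1.0)
        self._lam = self._solve_rate()

    def distance(self, phi) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        s = 1.0 - phi[..., None] + phi[..., None] * self.gamma
        kld2 = np.sum(s - 1.0 - np.log(s), axis=-1)
        return np.sqrt(np.maximum(kld2, 0.0))

    def _d_slope_at_zero(self) -> float:
        return float(np.sqrt(np.sum((self.gamma - 1.0) ** 2) / 2.0))

    def _d_prime(self, phi: float) -> float:
        d = float(self.distance(phi))
        if d < 1e-8:
            return self._d_slope_at_zero()
        s = 1.0 - phi + phi * self.gamma
        return float(np.sum((self.gamma - 1.0) * (1.0 - 1.0 / s)) / (2.0 * d))

    def _solve_rate(self) -> float:
        dU, dmax = float(self.distance(self.U)), float(self._d_max)

        def cdf_gap(lam):
            return -np.expm1(-lam * dU) / -np.expm1(-lam * dmax) - self.alpha

        # cdf at lam -> 0 tends to dU/dmax; increases towards 1 with lam
        if dU / dmax >= self.alpha:
            return 1e-8  # effectively uniform in distance
        return float(brentq(cdf_gap, 1e-8, 1e4))

    def logpdf(self, phi) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        scalar = phi.ndim == 0
        phi = np.atleast_1d(phi)
        if np.any((phi < 0) | (phi > 1)):
            raise ValueError("phi must lie in [0, 1]")
        d = self.distance(phi)
        dp = np.array([self._d_prime(float(p)) for p in phi])
        norm = -np.expm1(-self._lam * self._d_max)
        out = np.log(self._lam) - self._lam * d + np.log(np.maximum(dp, 1e-300)) - np.log(norm)
        return float(out[0]) if scalar else out

    def pdf(self, phi) -> np.ndarray:
        return np.exp(self.logpdf(phi))
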