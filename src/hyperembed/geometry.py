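"""Closed-form quantities and sampling primitives of the S^D geometric model.

The S^D model places ``N`` nodes on a D-sphere of radius ``R`` chosen so the
node density is one, assigns each node a hidden degree ``kappa``, and connects
pairs with the gravity-law probability

    p_ij = 1 / (1 + chi_ij**beta),   chi_ij = R * dtheta_ij / (mu*k_i*k_j)**(1/D)

where ``dtheta_ij`` is the angular separation of the two nodes, ``beta > D``
is the inverse temperature coupling topology to geometry, and ``mu`` fixes the
mean degree.  Everything downstream (generation, inference, evaluation) builds
on the primitives collected here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln


def sphere_radius(N: int, D: int) -> float:
    """Radius of the D-sphere holding ``N`` nodes at unit density.

    R = [N * Gamma((D+1)/2) / (2 * pi**((D+1)/2))]**(1/D), i.e. the radius at
    which the surface measure of the D-sphere equals ``N``.
    """
    if int(N) != N or int(D) != D or N < 2 or D < 1:
        raise ValueError(f"need integer N >= 2 and D >= 1, got N={N}, D={D}")
    N, D = int(N), int(D)
    log_r = (np.log(N) + gammaln((D + 1) / 2) - np.log(2.0) - (D + 1) / 2 * np.log(np.pi)) / D
    return float(np.exp(log_r))


def compute_mu(beta: float, D: int, mean_degree: float) -> float:
    """Density parameter mu fixing the expected mean degree.

    mu = beta * Gamma(D/2) * sin(D*pi/beta) / (2 * pi**(1 + D/2) * <k>).
    Only defined in the geometric regime ``beta > D``.
    """
    if beta <= D:
        raise ValueError(f"geometric regime requires beta > D (beta={beta}, D={D})")
    if mean_degree <= 0:
        raise ValueError("mean_degree must be positive")
    if np.isinf(beta):
        num = D * np.pi * np.exp(gammaln(D / 2))  # beta*sin(D*pi/beta) -> D*pi
    else:
        num = beta * np.exp(gammaln(D / 2)) * np.sin(D * np.pi / beta)
    den = 2.0 * np.pi ** (1.0 + D / 2.0) * mean_degree
    return float(num / den)


@dataclass(frozen=True)
class ModelParams:
    """Global S^D parameters: size, dimension, temperature, density, radius."""

    N: int
    D: int
    beta: float
    mu: float
    R: float
    mean_degree: float

    @classmethod
    def from_mean_degree(cls, N: int, D: int, beta: float, mean_degree: float) -> "ModelParams":
        """Derive ``R`` and ``mu`` from their closed forms."""
        return cls(
            N=int(N),
            D=int(D),
            beta=float(beta),
            mu=compute_mu(beta, D, mean_degree),
            R=sphere_radius(N, D),
            mean_degree=float(mean_degree),
        )

    def with_beta(self, beta: float) -> "ModelParams":
        """Copy with a new ``beta`` and the matching ``mu``."""
        return replace(self, beta=float(beta), mu=compute_mu(beta, self.D, self.mean_degree))


@dataclass
class HiddenDegreeSet:
    """Per-node hidden degrees with the generator's power-law metadata.

    ``kappa0`` and ``kappa_c`` are the lower cutoff and natural cutoff of the
    truncated power law; they are ``nan`` for inferred (non-generated) sets.
    """

    kappa: np.ndarray
    kappa0: float = float("nan")
    kappa_c: float = float("nan")
    gamma: float = float("nan")


def angular_distance(v1: np.ndarray, v2: np.ndarray) -> np.ndarray | float:
    """Angular separation arccos(v1.v2 / (|v1||v2|)) in [0, pi].

    Accepts single vectors or broadcastable ``(..., D+1)`` stacks.  The
    normalized dot product is clipped to [-1, 1] to absorb round-off.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero vector has no direction")
    cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    out = np.arccos(np.clip(cosang, -1.0, 1.0))
    return float(out) if out.ndim == 0 else out


def pairwise_angular_distances(vectors: np.ndarray) -> np.ndarray:
    """Full (n, n) matrix of angular separations between unit row vectors."""
    g = np.clip(vectors @ vectors.T, -1.0, 1.0)
    np.fill_diagonal(g, 1.0)
    return np.arccos(g)


def connection_probability(kappa_i, kappa_j, dtheta, params: ModelParams):
    """Gravity-law connection probability; returns ``(p, chi)``.

    chi = R*dtheta / (mu*kappa_i*kappa_j)**(1/D) and p = 1/(1+chi**beta).
    Vectorized over broadcastable inputs; dtheta = 0 gives p = 1 exactly.
    """
    kappa_i = np.asarray(kappa_i, dtype=float)
    kappa_j = np.asarray(kappa_j, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    if np.any(kappa_i <= 0) or np.any(kappa_j <= 0):
        raise ValueError("hidden degrees must be positive")
    chi = params.R * dtheta / (params.mu * kappa_i * kappa_j) ** (1.0 / params.D)
    p = 1.0 / (1.0 + chi**params.beta)
    if p.ndim == 0:
        return float(p), float(chi)
    return p, chi


def sample_uniform_sphere(n: int, D: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` points uniform on the unit D-sphere (rows of shape D+1).

    Standard-normal entries normalized to unit length; rotation invariant.
    """
    g = rng.standard_normal((n, D + 1))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    # a numerically-zero Gaussian vector is virtually impossible; guard anyway
    bad = norms[:, 0] < 1e-300
    if np.any(bad):
        g[bad] = rng.standard_normal((int(bad.sum()), D + 1))
        norms = np.linalg.norm(g, axis=1, keepdims=True)
    return g / norms


def sample_at_separation(v: np.ndarray, dtheta, rng: np.random.Generator) -> np.ndarray:
    """Unit vector(s) at exact angular separation ``dtheta`` from ``v``.

    The azimuthal orientation is uniform in the hyperplane orthogonal to
    ``v``.  ``dtheta`` may be a scalar or a length-m array (then m vectors
    are returned).
    """
    v = np.asarray(v, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero vector has no direction")
    e = v / nv
    scalar = np.ndim(dtheta) == 0
    dtheta = np.atleast_1d(np.asarray(dtheta, dtype=float))
    m = dtheta.shape[0]
    g = rng.standard_normal((m, e.shape[0]))
    g -= np.outer(g @ e, e)
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = g / norms
    out = np.cos(dtheta)[:, None] * e + np.sin(dtheta)[:, None] * u
    # renormalize to kill second-order round-off
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if scalar else out


def angular_distance_pdf(dtheta, D: int):
    """Density of the angular separation of two uniform points on the D-sphere.

    rho(dtheta) = Gamma((D+1)/2) * sin(dtheta)**(D-1) / (Gamma(D/2) * sqrt(pi))
    on [0, pi]; for D = 1 this is the constant 1/pi.
    """
    dtheta = np.asarray(dtheta, dtype=float)
    norm = np.exp(gammaln((D + 1) / 2) - gammaln(D / 2)) / np.sqrt(np.pi)
    out = norm * np.sin(dtheta) ** (D - 1)
    return float(out) if out.ndim == 0 else out
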