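"""Synthetic S^D networks with known ground truth.

Generates hidden degrees from a truncated power law, node positions either
uniform on the D-sphere or clustered into spherical-cap communities, and
edges as independent Bernoulli draws from the gravity-law connection
probability.  The generated object retains all latent variables, so it serves
as ground truth for validating the embedding pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import (
    HiddenDegreeSet,
    ModelParams,
    sample_at_separation,
    sample_uniform_sphere,
)

__all__ = [
    "GeneratedNetwork",
    "sample_hidden_degrees",
    "generate_network",
    "generate_community_positions",
    "sample_in_cap",
]


@dataclass
class GeneratedNetwork:
    """A sampled S^D network plus the latent variables that produced it."""

    adjacency: sp.csr_matrix
    positions: np.ndarray
    hidden_degrees: HiddenDegreeSet
    params: ModelParams
    community_labels: np.ndarray | None = None
    cap_angle: float | None = None

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


def sample_hidden_degrees(
    N: int, gamma: float, mean_degree: float, rng: np.random.Generator
) -> HiddenDegreeSet:
    """Draw N hidden degrees from rho(kappa) ~ kappa**(-gamma) on [k0, kc].

    The lower cutoff kappa0 = (gamma-2)/(gamma-1) * <k> fixes the mean of the
    untruncated law to <k>; the natural cutoff kappa_c = kappa0 * N**(1/(gamma-1))
    suppresses hidden degrees whose expected degree would exceed N.
    """
    if gamma <= 2:
        raise ValueError("gamma must exceed 2 (kappa0 would be non-positive)")
    if not 2 < gamma < 3:
        warnings.warn(f"gamma={gamma} outside the scale-free range (2, 3)", stacklevel=2)
    kappa0 = (gamma - 2.0) / (gamma - 1.0) * mean_degree
    kappa_c = kappa0 * N ** (1.0 / (gamma - 1.0))
    u = rng.uniform(size=N)
    # inverse transform for the truncated Pareto
    a = kappa0 ** (1.0 - gamma)
    b = kappa_c ** (1.0 - gamma)
    kappa = (a + u * (b - a)) ** (1.0 / (1.0 - gamma))
    return HiddenDegreeSet(kappa=kappa, kappa0=kappa0, kappa_c=kappa_c, gamma=gamma)


def generate_network(
    hidden_degrees: HiddenDegreeSet,
    positions: np.ndarray,
    beta: float,
    D: int,
    mean_degree: float,
    rng: np.random.Generator,
    community_labels: np.ndarray | None = None,
    cap_angle: float | None = None,
) -> GeneratedNetwork:
    """Bernoulli-sample every pair with the gravity-law probability.

    ``positions`` are unit vectors of shape (N, D+1); ``mu`` is derived from
    (beta, D, mean_degree) so the expected mean degree is calibrated.
    """
    kappa = np.asarray(hidden_degrees.kappa, dtype=float)
    N = kappa.shape[0]
    if positions.shape != (N, D + 1):
        raise ValueError(
            f"positions shape {positions.shape} does not match N={N}, D={D}"
        )
    params = ModelParams.from_mean_degree(N, D, beta, mean_degree)

    iu, ju = np.triu_indices(N, k=1)
    cosang = np.clip(np.einsum("ij,ij->i", positions[iu], positions[ju]), -1.0, 1.0)
    dtheta = np.arccos(cosang)
    chi = params.R * dtheta / (params.mu * kappa[iu] * kappa[ju]) ** (1.0 / D)
    if np.isinf(beta):
        p = (chi < 1.0).astype(float)
    else:
        p = 1.0 / (1.0 + chi**beta)
    edge = rng.uniform(size=p.shape[0]) < p
    rows = np.concatenate([iu[edge], ju[edge]])
    cols = np.concatenate([ju[edge], iu[edge]])
    adjacency = sp.csr_matrix(
        (np.ones(rows.shape[0], dtype=np.int8), (rows, cols)), shape=(N, N)
    )
    return GeneratedNetwork(
        adjacency=adjacency,
        positions=positions,
        hidden_degrees=hidden_degrees,
        params=params,
        community_labels=community_labels,
        cap_angle=cap_angle,
    )


def _octahedron() -> np.ndarray:
    return np.vstack([np.eye(3), -np.eye(3)])


def _tetrahedron() -> np.ndarray:
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return v / np.sqrt(3.0)


def _cube() -> np.ndarray:
    v = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    return v / np.sqrt(3.0)


def _icosahedron() -> np.ndarray:
    phi = (1 + np.sqrt(5.0)) / 2
    v = []
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            v += [[0, s1, s2 * phi], [s1, s2 * phi, 0], [s2 * phi, 0, s1]]
    v = np.array(v, dtype=float)
    return v / np.linalg.norm(v[0])


def _dodecahedron() -> np.ndarray:
    phi = (1 + np.sqrt(5.0)) / 2
    v = list(_cube() * np.sqrt(3.0))
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            v += [[0, s1 / phi, s2 * phi], [s1 / phi, s2 * phi, 0], [s2 * phi, 0, s1 / phi]]
    v = np.array(v, dtype=float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


_PLATONIC = {4: _tetrahedron, 6: _octahedron, 8: _cube, 12: _icosahedron, 20: _dodecahedron}


def community_apices(D: int, n_communities: int, rng: np.random.Generator) -> np.ndarray:
    """Evenly spread apex directions on the unit D-sphere.

    D = 1 uses equally spaced angles; D = 2 uses exact symmetric layouts where
    one exists (antipodal pair, equatorial triangle, platonic solids); any
    other case falls back to a maximin-repulsion optimization seeded by
    ``rng``.
    """
    n = int(n_communities)
    if n < 2:
        raise ValueError("need at least 2 communities")
    if D == 1:
        ang = 2 * np.pi * np.arange(n) / n
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if D == 2:
        if n == 2:
            return np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        if n == 3:
            ang = 2 * np.pi * np.arange(3) / 3
            return np.column_stack([np.cos(ang), np.sin(ang), np.zeros(3)])
        if n in _PLATONIC:
            return _PLATONIC[n]()
    return _repulsion_layout(D, n, rng)


def _repulsion_layout(D: int, n: int, rng: np.random.Generator, n_iter: int = 2000) -> np.ndarray:
    """Maximize the minimum pairwise separation by projected gradient ascent
    on an inverse-distance energy (Thomson-style)."""
    v = sample_uniform_sphere(n, D, rng)
    step = 0.1
    for _ in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        force = np.sum(diff / d2[..., None] ** 1.5, axis=1)
        v = v + step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.999
    return v


def sample_in_cap(
    apex: np.ndarray, cap_angle: float, D: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` points uniform (by surface measure) in the cap of polar angle
    ``cap_angle`` around ``apex``: polar angle from the sin**(D-1) density
    truncated to [0, cap_angle] by tabulated inverse transform, azimuth
    uniform."""
    grid = np.linspace(0.0, cap_angle, 4096)
    pdf = np.sin(grid) ** (D - 1)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    theta = np.interp(rng.uniform(size=n), cdf, grid)
    return np.atleast_2d(sample_at_separation(apex, theta, rng))


def generate_community_positions(
    N: int,
    D: int,
    n_communities: int,
    cap_angle: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions clustered into spherical-cap communities.

    Apices are spread evenly on the sphere; nodes are assigned round-robin to
    communities (sizes differ by at most one) and placed uniformly inside the
    cap of polar angle ``cap_angle`` around their apex.  Returns
    ``(positions, labels)``.
    """
    if not 0 < cap_angle <= np.pi:
        raise ValueError("cap_angle must lie in (0, pi]")
    apices = community_apices(D, n_communities, rng)
    labels = np.arange(N) % n_communities
    positions = np.empty((N, D + 1))
    for c in range(n_communities):
        idx = np.flatnonzero(labels == c)
        positions[idx] = sample_in_cap(apices[c], cap_angle, D, idx.size, rng)
    return positions, labels
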