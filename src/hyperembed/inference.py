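"""Stage 1 of the embedding: hidden degrees and inverse temperature.

Hidden degrees are adjusted, one value per observed-degree class, until the
model's expected degree matches every observed degree within a tolerance.
The inverse temperature ``beta`` is then found by matching the model's
expected mean local clustering (a Monte-Carlo estimate over degree classes)
to the empirical one; since expected clustering increases with ``beta``, a
geometric ramp followed by bisection suffices.  Every candidate ``beta``
re-derives ``mu`` from the closed form and refits the hidden degrees before
clustering is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._quadrature import (
    angular_pdf_prefactor,
    connected_distance_cdf_tables,
    gravity_moments,
    sample_from_tables,
)
from .geometry import HiddenDegreeSet, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "largest_component",
    "NetworkData",
    "InferenceConfig",
    "expected_degree_model",
    "expected_degrees_by_class",
    "fit_hidden_degrees",
    "estimate_mean_clustering",
    "infer_beta",
]


def largest_component(adjacency: sp.spmatrix) -> tuple[sp.csr_matrix, np.ndarray]:
    """Largest connected component; returns ``(sub_adjacency, kept_indices)``."""
    A = sp.csr_matrix(adjacency)
    n_comp, comp = sp.csgraph.connected_components(A, directed=False)
    if n_comp == 1:
        return A, np.arange(A.shape[0])
    keep = np.flatnonzero(comp == int(np.argmax(np.bincount(comp))))
    return A[keep][:, keep], keep


@dataclass
class NetworkData:
    """A simple undirected graph in the form the inference stages consume."""

    adjacency: sp.csr_matrix
    degrees: np.ndarray
    mean_local_clustering: float
    degree_values: np.ndarray       # distinct observed degrees, ascending
    degree_counts: np.ndarray       # multiplicity of each degree class
    class_of_node: np.ndarray       # index into degree_values per node
    node_labels: list | None = None

    @classmethod
    def from_adjacency(cls, adjacency: sp.spmatrix, node_labels: list | None = None) -> "NetworkData":
        A = sp.csr_matrix(adjacency)
        A.setdiag(0)
        A.eliminate_zeros()
        A.data[:] = 1
        if (A != A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        degrees = np.asarray(A.sum(axis=1)).ravel().astype(int)
        cbar = mean_local_clustering(A, degrees)
        values, class_of_node, counts = np.unique(degrees, return_inverse=True, return_counts=True)
        return cls(
            adjacency=A,
            degrees=degrees,
            mean_local_clustering=cbar,
            degree_values=values,
            degree_counts=counts,
            class_of_node=class_of_node,
            node_labels=node_labels,
        )

    @property
    def n_nodes(self) -> int:
        return self.degrees.shape[0]

    @property
    def observed_mean_degree(self) -> float:
        return float(self.degrees.mean())


def mean_local_clustering(adjacency: sp.csr_matrix, degrees: np.ndarray) -> float:
    """Mean local clustering over nodes with degree >= 2.

    Nodes of degree 0 or 1 have no defined local clustering and are excluded
    from both this empirical average and its model counterpart, keeping the
    two comparable during the ``beta`` fit.
    """
    mask = degrees >= 2
    if not np.any(mask):
        return 0.0
    A = adjacency
    triangles = np.asarray((A @ A).multiply(A).sum(axis=1)).ravel() / 2.0
    k = degrees[mask].astype(float)
    c = 2.0 * triangles[mask] / (k * (k - 1.0))
    return float(c.mean())


@dataclass
class InferenceConfig:
    """Tolerances and Monte-Carlo settings for stage-1 inference."""

    epsilon: float = 0.01            # max |expected - observed| degree
    epsilon_clust: float = 0.01      # tolerance on mean local clustering
    m: int = 600                     # MC samples per degree class
    max_iter: int = 5000             # cap on hidden-degree sweeps
    max_ramp: int = 40               # cap on beta *= 1.5 ramp steps
    max_bisect: int = 40             # cap on bisection steps
    seed: int | None = None          # used by the CLI to build the generator

    def __post_init__(self):
        if self.epsilon <= 0 or self.epsilon_clust <= 0 or self.m < 1:
            raise ValueError("tolerances must be positive and m >= 1")


def expected_degree_model(kappa_i: float, other_kappas: np.ndarray, params: ModelParams) -> float:
    """Expected degree of a node with hidden degree ``kappa_i``.

    Sums the model connection probability, integrated over the angular
    separation density, against every entry of ``other_kappas`` (the hidden
    degrees of the *other* nodes).
    """
    other_kappas = np.asarray(other_kappas, dtype=float)
    if kappa_i <= 0 or np.any(other_kappas <= 0):
        raise ValueError("hidden degrees must be positive")
    ts = (params.mu * kappa_i * other_kappas) ** (1.0 / params.D) / params.R
    (integral,) = gravity_moments(ts, params.beta, params.D, moments=(0,))
    return float(angular_pdf_prefactor(params.D) * integral.sum())


def expected_degrees_by_class(
    kappa_cls: np.ndarray, counts: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Expected degree for one representative node of each degree class.

    ``kappa_cls[a]`` is the shared hidden degree of class ``a`` with
    ``counts[a]`` members; the node's own contribution is excluded.
    """
    kappa_cls = np.asarray(kappa_cls, dtype=float)
    ts = (params.mu * np.outer(kappa_cls, kappa_cls)) ** (1.0 / params.D) / params.R
    (integral,) = gravity_moments(ts, params.beta, params.D, moments=(0,))
    P = angular_pdf_prefactor(params.D) * integral
    return P @ counts.astype(float) - np.diag(P)


def fit_hidden_degrees(
    network: NetworkData,
    beta: float,
    params: ModelParams,
    config: InferenceConfig,
    rng: np.random.Generator,
) -> HiddenDegreeSet:
    """Adjust hidden degrees until expected degrees match observed ones.

    One kappa per observed-degree class, initialized at the degree itself and
    nudged by ``|kappa + (k - kbar)*u|`` with ``u ~ U(0,1)`` until the largest
    deviation drops below ``config.epsilon``.
    """
    params = params.with_beta(beta)
    k_obs = network.degree_values.astype(float)
    counts = network.degree_counts
    kappa = k_obs.copy()
    kappa[kappa < 1e-10] = 1e-10
    for it in range(config.max_iter):
        kbar = expected_degrees_by_class(kappa, counts, params)
        resid = k_obs - kbar
        eps_max = float(np.abs(resid).max())
        if eps_max <= config.epsilon:
            logger.debug("hidden degrees converged in %d iterations (eps=%.3g)", it, eps_max)
            return HiddenDegreeSet(kappa=kappa[network.class_of_node].copy())
        u = rng.uniform(size=kappa.shape[0])
        kappa = np.abs(kappa + resid * u)
        kappa[kappa < 1e-10] = 1e-10
    raise RuntimeError(
        f"hidden-degree fit did not reach epsilon={config.epsilon} in "
        f"{config.max_iter} iterations (residual {eps_max:.4g})"
    )


def class_kappas(network: NetworkData, hidden_degrees: HiddenDegreeSet) -> np.ndarray:
    """Representative kappa per degree class (all class members share one)."""
    kappa_cls = np.empty(network.degree_values.shape[0])
    kappa_cls[network.class_of_node] = hidden_degrees.kappa
    return kappa_cls


def estimate_mean_clustering(
    network: NetworkData,
    kappa_cls: np.ndarray,
    params: ModelParams,
    config: InferenceConfig,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo estimate of the model's expected mean local clustering.

    For each degree class k >= 2: draw ``m`` neighbor pairs from the
    degree-biased distribution P(k') ~ k'*N_k', place the two neighbors at
    separations drawn from the connected-pair distance density, and average
    the probability that they are themselves connected.  The class values are
    then averaged with weights N_k over classes k >= 2, mirroring the
    empirical mean local clustering.
    """
    D = params.D
    values = network.degree_values
    counts = network.degree_counts.astype(float)
    # degree-biased neighbor class distribution P(k'|k) = k' P(k') / <k>
    w = values * counts
    p_neighbor = w / w.sum()

    ts_matrix = (params.mu * np.outer(kappa_cls, kappa_cls)) ** (1.0 / D) / params.R
    K = values.shape[0]
    _, tables = connected_distance_cdf_tables(ts_matrix.ravel(), params.beta, D)

    mask = values >= 2
    if not np.any(mask):
        return 0.0
    m = config.m
    cbar_k = np.zeros(K)
    for a in np.flatnonzero(mask):
        j1 = rng.choice(K, size=m, p=p_neighbor)
        j2 = rng.choice(K, size=m, p=p_neighbor)
        t1 = sample_from_tables(tables, a * K + j1, rng.uniform(size=m))
        t2 = sample_from_tables(tables, a * K + j2, rng.uniform(size=m))
        # the two neighbors sit at polar angles t1, t2 from the class-k node;
        # their own separation depends on the uniform azimuths via the dot
        # product of two independent uniform directions in the orthogonal
        # D-dimensional hyperplane
        g1 = rng.standard_normal((m, D))
        g2 = rng.standard_normal((m, D))
        dot = np.einsum("ij,ij->i", g1, g2) / (
            np.linalg.norm(g1, axis=1) * np.linalg.norm(g2, axis=1)
        )
        cos12 = np.clip(np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * dot, -1.0, 1.0)
        t12 = np.arccos(cos12)
        chi = params.R * t12 / (params.mu * kappa_cls[j1] * kappa_cls[j2]) ** (1.0 / D)
        with np.errstate(over="ignore"):
            p12 = 1.0 / (1.0 + chi**params.beta)
        cbar_k[a] = p12.mean()
    return float((cbar_k[mask] * counts[mask]).sum() / counts[mask].sum())


def infer_beta(
    network: NetworkData,
    params_template: ModelParams,
    config: InferenceConfig,
    rng: np.random.Generator,
) -> tuple[float, HiddenDegreeSet, float]:
    """Find beta matching the empirical mean local clustering.

    Starts uniform in (D, D+1), ramps by factors of 1.5 while the model
    clustering is below the empirical one, then bisects.  Every evaluation
    refits the hidden degrees and rederives ``mu``.  Returns
    ``(beta, hidden_degrees, mu)``.
    """
    c_emp = network.mean_local_clustering
    if c_emp <= 0:
        raise ValueError("network has no clustering to match (mean local clustering is 0)")
    D = params_template.D

    def evaluate(beta: float):
        params = params_template.with_beta(beta)
        hidden = fit_hidden_degrees(network, beta, params, config, rng)
        kappa_cls = class_kappas(network, hidden)
        cbar = estimate_mean_clustering(network, kappa_cls, params, config, rng)
        logger.info("beta=%.4f -> expected clustering %.4f (target %.4f)", beta, cbar, c_emp)
        return cbar, hidden, params

    beta = float(rng.uniform(D, D + 1))
    cbar, hidden, params = evaluate(beta)
    if abs(cbar - c_emp) < config.epsilon_clust:
        return beta, hidden, params.mu

    if cbar < c_emp:
        lo, c_lo = beta, cbar
        hi = None
        for _ in range(config.max_ramp):
            beta *= 1.5
            cbar, hidden, params = evaluate(beta)
            if abs(cbar - c_emp) < config.epsilon_clust:
                return beta, hidden, params.mu
            if cbar >= c_emp:
                hi = beta
                break
            lo = beta
        if hi is None:
            raise RuntimeError(
                f"could not bracket beta: clustering still {cbar:.4f} < {c_emp:.4f} "
                f"after {config.max_ramp} ramp steps"
            )
    else:
        # the initial draw already overshoots: bracket from just above D
        hi = beta
        lo = D + 1e-3
    for _ in range(config.max_bisect):
        beta = 0.5 * (lo + hi)
        cbar, hidden, params = evaluate(beta)
        if abs(cbar - c_emp) < config.epsilon_clust:
            return beta, hidden, params.mu
        if cbar < c_emp:
            lo = beta
        else:
            hi = beta
        if hi - lo < 1e-6 * max(1.0, hi):
            logger.warning("beta bracket collapsed before clustering tolerance was met")
            return beta, hidden, params.mu
    raise RuntimeError("beta bisection did not converge within the step cap")
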