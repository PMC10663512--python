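"""Stages 3-4: likelihood maximization of positions and final degree tune-up.

Nodes are visited in onion-decomposition order; for each node a cloud of
candidate positions is drawn around the hidden-degree-weighted mean of its
neighbors and the candidate with the highest local log-likelihood under the
gravity law is kept (the incumbent position competes too, so the global
log-likelihood never decreases).  Sweeps repeat until the log-likelihood
plateaus.  Finally the hidden degrees are re-adjusted per node so that the
position-conditional expected degrees match the observed ones.

Candidate scoring is the hot loop (candidates x nodes per node visited); it
runs vectorized in single precision, which changes scores by parts in 1e6 --
far below the sampling noise of the candidate cloud -- while the reported
global log-likelihood is always computed in double precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .geometry import HiddenDegreeSet, ModelParams, pairwise_angular_distances
from .inference import InferenceConfig, NetworkData

logger = logging.getLogger(__name__)

__all__ = [
    "MLEConfig",
    "EmbeddingResult",
    "onion_ordering",
    "onion_layers",
    "local_log_likelihood",
    "global_log_likelihood",
    "refine_positions",
    "final_degree_adjustment",
]

_LOG_CLAMP = math.log(1e-15)  # probabilities clamped to [1e-15, 1 - 1e-15]


@dataclass
class MLEConfig:
    """Knobs of the likelihood sweep."""

    sigma_mode: str = "max"       # 'max': literal max(pi/2, dtheta_max/2); 'min': min(...)
    plateau_tol: float = 1e-4     # relative log-likelihood change ending the sweeps
    max_sweeps: int = 8           # candidate sweeps locate the basin; the gradient polish finishes
    candidates_factor: int = 100  # candidates per node = factor * max(ln N, 1)
    gradient_sweeps: int = 20     # guarded gradient-ascent polish after the candidate sweeps
    gradient_steps: tuple = (0.3, 0.1, 0.03, 0.01)  # backtracking step sizes (chord units)

    def __post_init__(self):
        if self.sigma_mode not in ("max", "min"):
            raise ValueError("sigma_mode must be 'max' or 'min'")


@dataclass
class EmbeddingResult:
    """Output of the embedding pipeline."""

    hidden_degrees: HiddenDegreeSet
    positions: np.ndarray
    params: ModelParams
    loglik_trace: list = field(default_factory=list)
    eps_max: float = float("nan")


def onion_layers(adjacency: sp.csr_matrix) -> np.ndarray:
    """Onion-decomposition layer of every node.

    Peel repeatedly: all nodes at the current minimum remaining degree form
    one layer and are removed together; removal can lower other nodes'
    degrees, refining the k-core decomposition into layers.
    """
    A = sp.csr_matrix(adjacency)
    n = A.shape[0]
    deg = np.asarray(A.sum(axis=1)).ravel().astype(int)
    alive = np.ones(n, dtype=bool)
    layer = np.zeros(n, dtype=int)
    indptr, indices = A.indptr, A.indices
    current = 0
    while alive.any():
        current += 1
        dmin = deg[alive].min()
        batch = np.flatnonzero(alive & (deg <= dmin))
        layer[batch] = current
        alive[batch] = False
        for v in batch:
            for u in indices[indptr[v] : indptr[v + 1]]:
                if alive[u]:
                    deg[u] -= 1
    return layer


def onion_ordering(network: NetworkData, rng: np.random.Generator) -> np.ndarray:
    """Node visitation sequence: innermost onion layer first, shuffled within
    layers."""
    layers = onion_layers(network.adjacency)
    order = []
    for lay in np.unique(layers)[::-1]:
        members = np.flatnonzero(layers == lay)
        order.append(rng.permutation(members))
    return np.concatenate(order)


def _pair_log_terms(z: np.ndarray, is_edge) -> np.ndarray:
    """Clamped log-probability terms from the log-odds z = beta*ln(chi).

    ln p = -ln(1 + e^z) for edges, ln(1-p) = -ln(1 + e^-z) otherwise.
    """
    with np.errstate(over="ignore"):
        out = np.where(is_edge, -np.log1p(np.exp(z)), -np.log1p(np.exp(-z)))
    return np.maximum(out, _LOG_CLAMP, out=out)


def _candidate_scores(
    cands: np.ndarray,
    pos32_T: np.ndarray,
    offset32: np.ndarray,
    nbrs: np.ndarray,
    node: int,
    beta: float,
) -> np.ndarray:
    """Local log-likelihood of every candidate row, single precision.

    ``offset32[j] = beta * (ln R - ln s_ij)`` so the log-odds against node j
    are z = beta*ln(dtheta) + offset32[j].
    """
    beta32 = np.float32(beta)
    dots = np.clip(cands.astype(np.float32) @ pos32_T, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        z = beta32 * np.log(np.arccos(dots))
        z += offset32[None, :]
        tn = -np.log1p(np.exp(-z))                 # ln(1-p), the non-edge term
        np.maximum(tn, np.float32(_LOG_CLAMP), out=tn)
        te = -np.log1p(np.exp(z[:, nbrs]))         # ln p on the edge columns
        np.maximum(te, np.float32(_LOG_CLAMP), out=te)
    total = tn.sum(axis=1, dtype=np.float64)
    total -= tn[:, nbrs].sum(axis=1, dtype=np.float64)
    total += te.sum(axis=1, dtype=np.float64)
    total -= tn[:, node].astype(np.float64)        # self term excluded
    return total


def local_log_likelihood(
    node: int,
    positions: np.ndarray,
    hidden_degrees: HiddenDegreeSet,
    params: ModelParams,
    adjacency: sp.csr_matrix,
) -> float:
    """ln L_i = sum_{j != i} a_ij ln p_ij + (1 - a_ij) ln(1 - p_ij).

    Double precision (used for verification and small problems; the sweep
    itself scores candidates through the single-precision fast path).
    """
    A = sp.csr_matrix(adjacency)
    kappa = hidden_degrees.kappa
    dtheta = np.asarray(
        np.arccos(np.clip(positions @ positions[node], -1.0, 1.0)), dtype=float
    )
    with np.errstate(divide="ignore"):
        z = params.beta * (
            np.log(params.R * dtheta)
            - (math.log(params.mu) + np.log(kappa[node]) + np.log(kappa)) / params.D
        )
    is_edge = np.zeros(positions.shape[0], dtype=bool)
    is_edge[A.indices[A.indptr[node] : A.indptr[node + 1]]] = True
    terms = _pair_log_terms(z, is_edge)
    terms[node] = 0.0
    return float(terms.sum())


def global_log_likelihood(
    positions: np.ndarray,
    hidden_degrees: HiddenDegreeSet,
    params: ModelParams,
    adjacency: sp.csr_matrix,
) -> float:
    """Gravity-law log-likelihood of the graph over unordered pairs (double
    precision)."""
    A = sp.csr_matrix(adjacency)
    dtheta = pairwise_angular_distances(positions)
    lnk = np.log(hidden_degrees.kappa)
    with np.errstate(divide="ignore"):
        z = params.beta * (
            np.log(params.R * dtheta)
            - (math.log(params.mu) + lnk[:, None] + lnk[None, :]) / params.D
        )
    is_edge = A.toarray().astype(bool)
    terms = _pair_log_terms(z, is_edge)
    iu = np.triu_indices(positions.shape[0], k=1)
    return float(terms[iu].sum())


def refine_positions(
    network: NetworkData,
    hidden_degrees: HiddenDegreeSet,
    positions: np.ndarray,
    params: ModelParams,
    config: MLEConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list]:
    """Likelihood sweeps over all nodes; returns positions and the per-sweep
    global log-likelihood trace."""
    A = network.adjacency
    N = network.n_nodes
    D1 = params.D + 1
    kappa = hidden_degrees.kappa
    lnk = np.log(kappa)
    log_r = math.log(params.R)
    base_offset = params.beta * (
        log_r - (math.log(params.mu) + lnk) / params.D
    )  # still missing the -beta*ln(kappa_i)/D part, added per node
    inv_k2 = 1.0 / kappa**2
    n_cand = int(config.candidates_factor * max(math.log(N), 1.0))
    pos = np.ascontiguousarray(positions.copy())

    trace = [global_log_likelihood(pos, hidden_degrees, params, A)]
    for sweep in range(config.max_sweeps):
        pos32_T = np.ascontiguousarray(pos.T, dtype=np.float32)
        order = onion_ordering(network, rng)
        for i in order:
            nbrs = A.indices[A.indptr[i] : A.indptr[i + 1]]
            if nbrs.size == 0:
                continue
            vbar = inv_k2[nbrs] @ pos[nbrs]
            norm = np.linalg.norm(vbar)
            if norm < 1e-12:
                vbar = pos[i].copy()
                norm = 1.0
            cosang = np.clip(pos[nbrs] @ (vbar / norm), -1.0, 1.0)
            dtheta_max = float(np.arccos(cosang).max())
            if config.sigma_mode == "max":
                sigma = max(np.pi / 2.0, dtheta_max / 2.0)
            else:
                sigma = min(np.pi / 2.0, dtheta_max / 2.0)
            cands = vbar[None, :] + sigma * rng.standard_normal((n_cand, D1))
            norms = np.linalg.norm(cands, axis=1, keepdims=True)
            norms[norms < 1e-12] = 1.0
            cands /= norms
            cands = np.vstack([cands, pos[i][None, :]])
            offset32 = (base_offset - params.beta * lnk[i] / params.D).astype(np.float32)
            scores = _candidate_scores(cands, pos32_T, offset32, nbrs, i, params.beta)
            best = int(np.argmax(scores))
            if best != n_cand:  # a candidate beat the incumbent
                pos[i] = cands[best]
                pos32_T[:, i] = cands[best].astype(np.float32)
        trace.append(global_log_likelihood(pos, hidden_degrees, params, A))
        rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0)
        logger.info("sweep %d: log-likelihood %.2f (rel change %.2e)", sweep + 1, trace[-1], rel)
        if rel < config.plateau_tol:
            break
    else:
        logger.info("candidate sweeps hit the cap (%d) before the plateau", config.max_sweeps)
    if config.gradient_sweeps > 0:
        pos = _gradient_polish(network, hidden_degrees, pos, params, config, rng)
        trace.append(global_log_likelihood(pos, hidden_degrees, params, A))
        logger.info("after gradient polish: log-likelihood %.2f", trace[-1])
    return pos, trace


def _gradient_polish(
    network: NetworkData,
    hidden_degrees: HiddenDegreeSet,
    positions: np.ndarray,
    params: ModelParams,
    config: MLEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-node projected gradient ascent of the local log-likelihood.

    The candidate sweeps locate the right basin; this pass polishes within
    it.  Each node takes one backtracking step per sweep along the tangent
    gradient of its local log-likelihood, accepted only if the local
    log-likelihood improves (so the global log-likelihood stays monotone).
    Cost is O(N) per node versus O(candidates x N) for a candidate sweep.
    """
    A = network.adjacency
    n = network.n_nodes
    beta = params.beta
    lnk = np.log(hidden_degrees.kappa)
    log_r = math.log(params.R)
    log_mu = math.log(params.mu)
    pos = positions.copy()
    edge_mark = np.zeros(n, dtype=bool)

    def ll_and_grad(i, with_grad=True):
        v = pos[i]
        th = np.arccos(np.clip(pos @ v, -1.0, 1.0))
        with np.errstate(divide="ignore"):
            z = beta * (log_r + np.log(th) - (log_mu + lnk[i] + lnk) / params.D)
        nbrs = A.indices[A.indptr[i] : A.indptr[i + 1]]
        edge_mark[nbrs] = True
        terms = _pair_log_terms(z, edge_mark)
        terms[i] = 0.0
        ll = float(terms.sum())
        if not with_grad:
            edge_mark[nbrs] = False
            return ll, None
        p = expit(-z)
        a = edge_mark.astype(float)
        edge_mark[nbrs] = False
        w = (a - p) * beta / np.maximum(th * np.sin(th), 1e-9)
        w[i] = 0.0
        g = w @ pos
        g -= (g @ v) * v
        return ll, g

    for sweep in range(config.gradient_sweeps):
        moved = 0
        for i in onion_ordering(network, rng):
            ll0, g = ll_and_grad(i)
            norm = np.linalg.norm(g)
            if norm < 1e-12:
                continue
            ghat = g / norm
            old = pos[i].copy()
            for eta in config.gradient_steps:
                vnew = old + eta * ghat
                vnew /= np.linalg.norm(vnew)
                pos[i] = vnew
                ll_new, _ = ll_and_grad(i, with_grad=False)
                if ll_new > ll0:
                    moved += 1
                    break
                pos[i] = old
        if moved == 0:
            break
    return pos


def expected_degrees_at_positions(
    positions: np.ndarray, kappa: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Position-conditional expected degree: kbar_i = sum_{j != i} p_ij."""
    dtheta = pairwise_angular_distances(positions)
    with np.errstate(divide="ignore"):
        ln_rd = np.log(params.R * dtheta)
    lnk = np.log(kappa)
    z = params.beta * (ln_rd - (math.log(params.mu) + lnk[:, None] + lnk[None, :]) / params.D)
    p = expit(-z)
    np.fill_diagonal(p, 0.0)
    return p.sum(axis=1)


def final_degree_adjustment(
    network: NetworkData,
    hidden_degrees: HiddenDegreeSet,
    positions: np.ndarray,
    params: ModelParams,
    config: InferenceConfig,
    rng: np.random.Generator,
) -> tuple[HiddenDegreeSet, float]:
    """Per-node hidden-degree correction with positions held fixed.

    Iterates the noisy update kappa_i <- |kappa_i + (k_i - kbar_i) u| until
    max_i |kbar_i - k_i| <= epsilon.  The update direction contracts the
    residual, matching the initial-inference step.  Returns the adjusted set
    and the final residual.
    """
    k_obs = network.degrees.astype(float)
    kappa = hidden_degrees.kappa.copy()
    dtheta = pairwise_angular_distances(positions)
    with np.errstate(divide="ignore"):
        ln_rd = params.beta * np.log(params.R * dtheta)
    log_mu = math.log(params.mu)
    bod = params.beta / params.D
    for it in range(config.max_iter):
        lnk = np.log(kappa)
        z = ln_rd - bod * (log_mu + lnk[:, None] + lnk[None, :])
        p = expit(-z)
        np.fill_diagonal(p, 0.0)
        kbar = p.sum(axis=1)
        resid = k_obs - kbar
        eps_max = float(np.abs(resid).max())
        if eps_max <= config.epsilon:
            logger.debug("final degree adjustment converged in %d iterations", it)
            return HiddenDegreeSet(kappa=kappa), eps_max
        u = rng.uniform(size=kappa.shape[0])
        kappa = np.abs(kappa + resid * u)
        kappa[kappa < 1e-10] = 1e-10
    raise RuntimeError(
        f"final degree adjustment did not reach epsilon={config.epsilon} "
        f"within {config.max_iter} iterations (residual {eps_max:.4g})"
    )
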