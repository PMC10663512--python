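"""Model-corrected Laplacian Eigenmaps: initial positions on the D-sphere.

Standard Laplacian Eigenmaps needs known distances between neighboring
points.  Here the "known" distance between two connected nodes is the
model-expected angular separation conditioned on the edge, converted to a
chord length; the Gaussian edge weights built from those chords define a
weighted Laplacian whose lowest non-trivial eigenvectors give the initial
coordinates.  Degree-one nodes carry no geometric information, so they are
peeled off first and reattached afterwards at separations drawn from the
connected-pair distance density.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from ._quadrature import connected_distance_cdf_tables, gravity_moments, sample_from_tables
from .geometry import HiddenDegreeSet, ModelParams, sample_at_separation, sample_uniform_sphere
from .inference import NetworkData

logger = logging.getLogger(__name__)

__all__ = [
    "expected_connected_distance",
    "laplacian_positions_core",
    "peel_degree_one",
    "initial_positions",
    "le_loss",
]


def expected_connected_distance(kappa_i, kappa_j, params: ModelParams):
    """Expected angular separation of two *connected* nodes.

    Ratio of the first to the zeroth moment of the connected-pair separation
    density; vectorized over broadcastable hidden-degree arrays.
    """
    kappa_i = np.asarray(kappa_i, dtype=float)
    kappa_j = np.asarray(kappa_j, dtype=float)
    ts = (params.mu * kappa_i * kappa_j) ** (1.0 / params.D) / params.R
    i0, i1 = gravity_moments(ts, params.beta, params.D, moments=(0, 1))
    out = i1 / i0
    return float(out) if out.ndim == 0 else out


def _edge_expected_distances(
    rows: np.ndarray, cols: np.ndarray, kappa: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Expected separation per edge, computed once per distinct kappa pair."""
    uniq, inv = np.unique(kappa, return_inverse=True)
    U = uniq.shape[0]
    theta_pairs = expected_connected_distance(
        np.repeat(uniq, U), np.tile(uniq, U), params
    ).reshape(U, U)
    return theta_pairs[inv[rows], inv[cols]]


def le_loss(coords: np.ndarray, weights: sp.spmatrix) -> float:
    """Laplacian Eigenmaps loss sum_ij |v_i - v_j|^2 w_ij over edges."""
    W = sp.coo_matrix(weights)
    diff = coords[W.row] - coords[W.col]
    return float(np.sum(W.data * np.sum(diff**2, axis=1)))


def laplacian_positions_core(
    adjacency: sp.csr_matrix,
    kappa: np.ndarray,
    params: ModelParams,
    dense_cutoff: int = 500,
    scale: str = "mean_sq_chord",
    n_extra: int = 3,
    ipr_threshold: float = 5.0,
) -> np.ndarray:
    """Unit positions for a connected core with all degrees >= 2.

    Edge weights are w_ij = exp(-chord_ij^2 / t) with
    chord_ij = 2 sin(<dtheta_ij>/2) and ``t`` a bandwidth set from the
    contributing chord lengths: the default is the mean squared chord (the
    classic heat-kernel bandwidth; ``scale`` also accepts 'var_sq_chord' and
    'var_chord').  Coordinates come from D+1 low-lying eigenvectors of the
    generalized problem L y = lambda I y (L = I - w, I_ii = sum_j w_ij), the
    weight-normalized eigenmap of classic Laplacian Eigenmaps, normalized per
    node onto the unit sphere.

    Heavy-tailed graphs at weak coupling can grow spurious *localized* modes
    below the geometric ones, so rather than taking the D+1 smallest
    non-null eigenvectors blindly, the ``n_extra`` next eigenvectors are also
    computed, strongly localized modes (inverse participation ratio more
    than ``ipr_threshold`` times the delocalized Gaussian reference 3/n) are
    discarded, and the lowest D+1 survivors are kept (``n_extra=0`` recovers
    the blind choice).
    """
    n = adjacency.shape[0]
    D = params.D
    if n < D + 2:
        raise ValueError(f"core of {n} nodes cannot support a D={D} eigenmap")
    coo = sp.triu(adjacency, k=1).tocoo()
    theta = _edge_expected_distances(coo.row, coo.col, np.asarray(kappa, float), params)
    chord = 2.0 * np.sin(theta / 2.0)
    try:
        t = {
            "mean_sq_chord": float(np.mean(chord**2)),
            "var_sq_chord": float(np.var(chord**2)),
            "var_chord": float(np.var(chord)),
        }[scale]
    except KeyError:
        raise ValueError(f"unknown scale {scale!r}") from None
    if t <= 0:
        t = 1.0  # all chords identical (e.g. regular graph): weights uniform
    w = np.exp(-(chord**2) / t)
    rows = np.concatenate([coo.row, coo.col])
    cols = np.concatenate([coo.col, coo.row])
    W = sp.csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))
    L = sp.csgraph.laplacian(W)
    strength = np.asarray(W.sum(axis=1)).ravel()

    k = min(D + 2 + max(n_extra, 0), n - 1)
    if n <= dense_cutoff or k >= n - 2:
        from scipy.linalg import eigh

        vals, vecs = eigh(L.toarray(), np.diag(strength))
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        # shift-invert about a small negative value: L + |sigma| M is SPD
        M = sp.diags(strength).tocsc()
        vals, vecs = eigsh(L.tocsc(), k=k, M=M, sigma=-1e-3, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    nontrivial = vals > 1e-10
    if nontrivial.sum() < D + 1:
        raise RuntimeError(
            "Laplacian has multiple (near-)null eigenvalues; is the core connected?"
        )
    basis = vecs[:, nontrivial]
    if basis.shape[1] > D + 1:
        unit = basis / np.linalg.norm(basis, axis=0, keepdims=True)
        ipr_rel = np.sum(unit**4, axis=0) * n / 3.0
        delocalized = np.flatnonzero(ipr_rel <= ipr_threshold)
        if delocalized.size >= D + 1:
            basis = basis[:, delocalized]
    return _spherize(basis[:, : D + 1])


def _spherize(raw: np.ndarray) -> np.ndarray:
    """Row-normalize eigenvector components onto the unit sphere."""
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    zero = norms[:, 0] < 1e-12
    if np.any(zero):
        raw = raw.copy()
        raw[zero, 0] = 1.0
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
    return raw / norms


def peel_degree_one(adjacency: sp.csr_matrix):
    """Recursively strip degree-one nodes.

    Returns ``(core_mask, removal_order)`` where ``removal_order`` is a list
    of ``(node, anchor)`` pairs in removal order; reattachment must run in
    reverse so each node's anchor is already placed.  Removing a node can
    create new degree-one nodes (chains), hence the recursion.
    """
    A = sp.csr_matrix(adjacency)
    n = A.shape[0]
    deg = np.asarray(A.sum(axis=1)).ravel().astype(int)
    alive = np.ones(n, dtype=bool)
    indptr, indices = A.indptr, A.indices
    stack = sorted(np.flatnonzero(deg == 1).tolist(), reverse=True)
    order: list[tuple[int, int]] = []
    while stack:
        v = stack.pop()
        if not alive[v] or deg[v] != 1:
            continue
        nbrs = [u for u in indices[indptr[v] : indptr[v + 1]] if alive[u]]
        if len(nbrs) != 1:
            continue
        anchor = int(nbrs[0])
        alive[v] = False
        order.append((int(v), anchor))
        deg[anchor] -= 1
        deg[v] = 0
        if deg[anchor] == 1:
            stack.append(anchor)
    return alive, order


def initial_positions(
    network: NetworkData,
    hidden_degrees: HiddenDegreeSet,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """LE positions for all nodes: peel leaves, embed the core, reattach.

    Reattached nodes are placed at a separation from their anchor drawn from
    the connected-pair distance density for their hidden-degree pair, with
    uniform azimuth.
    """
    kappa = np.asarray(hidden_degrees.kappa, dtype=float)
    core_mask, order = peel_degree_one(network.adjacency)
    core_idx = np.flatnonzero(core_mask)
    n = network.n_nodes
    positions = np.empty((n, params.D + 1))
    if core_idx.size >= params.D + 2:
        sub = network.adjacency[core_idx][:, core_idx]
        positions[core_idx] = laplacian_positions_core(sub, kappa[core_idx], params)
    else:
        # degenerate core (trees, tiny graphs): no spectral information to use
        logger.warning("core too small for eigenmaps (%d nodes); placing uniformly", core_idx.size)
        if core_idx.size:
            positions[core_idx] = sample_uniform_sphere(core_idx.size, params.D, rng)

    table_cache: dict[tuple[float, float], np.ndarray] = {}
    for v, anchor in reversed(order):
        key = (float(min(kappa[v], kappa[anchor])), float(max(kappa[v], kappa[anchor])))
        if key not in table_cache:
            ts = (params.mu * key[0] * key[1]) ** (1.0 / params.D) / params.R
            _, table = connected_distance_cdf_tables(np.array([ts]), params.beta, params.D)
            table_cache[key] = table
        dtheta = sample_from_tables(table_cache[key], np.array([0]), rng.uniform(size=1))[0]
        positions[v] = sample_at_separation(positions[anchor], dtheta, rng)
    return positions
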