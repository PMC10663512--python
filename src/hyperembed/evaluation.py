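"""Embedding quality metrics and dimension selection.

Greedy routing (navigability), geometric community concentration,
Procrustes alignment against ground truth, empirical connection curves,
geometric community detection and partition scores — and the consensus rule
that picks a network's intrinsic dimension as the embedding dimension at
which these metrics jointly peak.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import shortest_path
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import normalized_mutual_info_score

from .geometry import ModelParams, pairwise_angular_distances
from .hyperbolic import HyperbolicCoordinates

__all__ = [
    "GreedyRoutingResult",
    "ConcentrationResult",
    "greedy_routing",
    "community_concentration",
    "align_to_reference",
    "empirical_connection_curve",
    "detect_geometric_communities",
    "partition_quality",
    "consensus_dimension",
    "ConsensusResult",
]


@dataclass
class GreedyRoutingResult:
    """Success rate and stretch of greedy forwarding on the hyperbolic map."""

    success_rate: float
    mean_stretch: float
    n_pairs: int


def greedy_routing(
    adjacency: sp.csr_matrix,
    coords: HyperbolicCoordinates,
    n_pairs: int = 10_000,
    rng: np.random.Generator | None = None,
) -> GreedyRoutingResult:
    """Greedy routing over sampled ordered source-target pairs.

    Each hop forwards to the neighbor with the smallest effective hyperbolic
    distance to the target (ties to the smallest node index).  Revisiting a
    node, or exceeding N hops, is a failure.  Stretch is the ratio of greedy
    hops to shortest-path hops, averaged over successful pairs only.
    """
    A = sp.csr_matrix(adjacency)
    A.sort_indices()
    N = A.shape[0]
    if rng is None:
        rng = np.random.default_rng()
    if N * (N - 1) <= n_pairs:
        src, dst = map(np.ravel, np.meshgrid(np.arange(N), np.arange(N), indexing="ij"))
        keep = src != dst
        src, dst = src[keep], dst[keep]
    else:
        src = rng.integers(0, N, size=n_pairs)
        dst = rng.integers(0, N, size=n_pairs)
        bad = src == dst
        while bad.any():
            dst[bad] = rng.integers(0, N, size=int(bad.sum()))
            bad = src == dst

    r = coords.radial
    U = coords.unit_directions
    indptr, indices = A.indptr, A.indices
    successes = 0
    hops_ratio_sum = 0.0
    uniq_src, inv_src = np.unique(src, return_inverse=True)
    sp_dist = shortest_path(A, method="D", unweighted=True, indices=uniq_src)

    succ_hops = []
    for p in range(src.shape[0]):
        s, t = int(src[p]), int(dst[p])
        ut = U[t]
        visited = {s}
        current = s
        hops = 0
        reached = False
        while hops < N:
            nbrs = indices[indptr[current] : indptr[current + 1]]
            if nbrs.size == 0:
                break
            hops += 1
            if t in nbrs:
                reached = True
                break
            dots = np.clip(U[nbrs] @ ut, -1.0, 1.0)
            with np.errstate(divide="ignore"):
                score = r[nbrs] + 2.0 * np.log(np.arccos(dots) / 2.0)
            current = int(nbrs[int(np.argmin(score))])
            if current in visited:
                break
            visited.add(current)
        if reached:
            d = sp_dist[inv_src[p], t]
            if np.isfinite(d) and d > 0:
                successes += 1
                hops_ratio_sum += hops / d
    n_total = src.shape[0]
    return GreedyRoutingResult(
        success_rate=successes / n_total,
        mean_stretch=hops_ratio_sum / successes if successes else float("nan"),
        n_pairs=n_total,
    )


@dataclass
class ConcentrationResult:
    """Geometric concentration of each node's own community."""

    rho_node_comm: np.ndarray
    c_C: float
    n_top: int
    rho_random: float


def community_concentration(
    positions: np.ndarray, labels: np.ndarray, fraction: float = 0.1
) -> ConcentrationResult:
    """Enrichment of a node's community among its geometrically nearest nodes.

    rho_{i,l} = (n_{i,l} / n_g) * (N / N_l) over the ``n_g = ceil(fraction*N)``
    angularly closest other nodes; ``c_C`` is the mean over nodes (the scalar
    concentration uses fraction = 0.1).  When labels carry no geometric
    signal the enrichment averages to 1 -- equivalently, the raw
    co-membership fraction n_{i,l}/n_g sits at its 1/N_C baseline, which is
    what ``rho_random`` reports.
    """
    labels = np.asarray(labels)
    N = positions.shape[0]
    if labels.shape[0] != N:
        raise ValueError("every node needs a label")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    uniq, counts = np.unique(labels, return_counts=True)
    sizes = dict(zip(uniq.tolist(), counts.tolist()))
    n_g = min(int(np.ceil(fraction * N)), N - 1)
    dtheta = pairwise_angular_distances(positions)
    np.fill_diagonal(dtheta, np.inf)
    rho = np.full(N, np.nan)
    for i in range(N):
        if sizes[labels[i]] < 2:
            warnings.warn(f"community {labels[i]} has a single node; node {i} skipped", stacklevel=2)
            continue
        nearest = np.argpartition(dtheta[i], n_g)[:n_g]
        # exact top-n_g with index tie-break
        nearest = nearest[np.lexsort((nearest, dtheta[i][nearest]))]
        n_il = int(np.sum(labels[nearest] == labels[i]))
        rho[i] = (n_il / n_g) * (N / sizes[labels[i]])
    return ConcentrationResult(
        rho_node_comm=rho,
        c_C=float(np.nanmean(rho)),
        n_top=n_g,
        rho_random=1.0 / uniq.shape[0],
    )


def align_to_reference(
    inferred: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal orthogonal alignment of inferred onto reference positions.

    Solves the orthogonal Procrustes problem (rotations and reflections) for
    the unit-vector stacks, returns ``(aligned, per_axis_pearson_r,
    mean_angular_displacement)``.
    """
    inferred = np.asarray(inferred, float)
    reference = np.asarray(reference, float)
    if inferred.shape != reference.shape:
        raise ValueError("position stacks must share shape")
    Q, _ = orthogonal_procrustes(inferred, reference)
    aligned = inferred @ Q
    r = np.array(
        [np.corrcoef(aligned[:, d], reference[:, d])[0, 1] for d in range(aligned.shape[1])]
    )
    cosang = np.clip(np.einsum("ij,ij->i", aligned, reference), -1.0, 1.0)
    return aligned, r, float(np.arccos(cosang).mean())


def empirical_connection_curve(
    adjacency: sp.spmatrix,
    positions: np.ndarray,
    kappa: np.ndarray,
    params: ModelParams,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Connection fraction binned by the rescaled distance chi.

    All node pairs are binned by chi on a log scale; each bin reports the
    fraction of connected pairs next to the gravity-law prediction at the
    bin's geometric center.  Empty bins are dropped.
    """
    A = sp.csr_matrix(adjacency)
    N = A.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    cosang = np.clip(np.einsum("ij,ij->i", positions[iu], positions[ju]), -1.0, 1.0)
    dtheta = np.arccos(cosang)
    kappa = np.asarray(kappa, float)
    chi = params.R * dtheta / (params.mu * kappa[iu] * kappa[ju]) ** (1.0 / params.D)
    connected = np.asarray(A[iu, ju]).ravel() > 0
    positive = chi > 0
    chi, connected = chi[positive], connected[positive]
    edges = np.geomspace(chi.min(), chi.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(chi, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        center = float(np.sqrt(edges[b] * edges[b + 1]))
        rows.append(
            {
                "chi": center,
                "fraction": float(connected[mask].mean()),
                "n_pairs": n,
                "p_theory": 1.0 / (1.0 + center**params.beta),
            }
        )
    return pd.DataFrame(rows)


def detect_geometric_communities(positions: np.ndarray, n_clusters: int) -> np.ndarray:
    """Average-linkage agglomerative clustering on angular distances."""
    N = positions.shape[0]
    if n_clusters > N:
        raise ValueError("cannot ask for more clusters than nodes")
    if n_clusters == N:
        return np.arange(N)
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="average"
    )
    return model.fit_predict(pairwise_angular_distances(positions))


def partition_quality(
    adjacency: sp.spmatrix, labels: np.ndarray, reference_labels: np.ndarray
) -> tuple[float, float]:
    """Newman-Girvan modularity of ``labels`` and NMI against the reference.

    NMI uses arithmetic-mean normalization; a constant reference makes it
    undefined and is reported as 0 with a warning.
    """
    A = sp.csr_matrix(adjacency)
    labels = np.asarray(labels)
    reference_labels = np.asarray(reference_labels)
    degrees = np.asarray(A.sum(axis=1)).ravel()
    two_m = degrees.sum()
    Q = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        e_c = A[members][:, members].sum() / 2.0
        d_c = degrees[members].sum()
        Q += e_c / (two_m / 2.0) - (d_c / two_m) ** 2
    if np.unique(reference_labels).shape[0] < 2 or np.unique(labels).shape[0] < 2:
        warnings.warn("NMI undefined against a constant partition; reporting 0", stacklevel=2)
        nmi = 0.0
    else:
        nmi = float(
            normalized_mutual_info_score(reference_labels, labels, average_method="arithmetic")
        )
    return float(Q), nmi


# metrics where smaller is better when voting for a dimension
_LOWER_IS_BETTER = {"stretch", "mean_stretch"}


@dataclass
class ConsensusResult:
    """Outcome of the per-metric vote over candidate dimensions."""

    dimension: int | None
    votes: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None
    unresolved: bool = False


def consensus_dimension(metrics_by_dim: dict[int, dict[str, float]]) -> ConsensusResult:
    """Vote each metric for the dimension where it peaks; return the mode.

    ``metrics_by_dim`` maps a candidate dimension to metric values; metrics
    named in ``_LOWER_IS_BETTER`` vote for their minimum.  A tie in the vote
    leaves the consensus unresolved (dimension ``None``) with the full table
    attached.
    """
    if len(metrics_by_dim) < 2:
        raise ValueError("need at least two candidate dimensions")
    table = pd.DataFrame(metrics_by_dim).T.sort_index()
    votes = {}
    for metric in table.columns:
        col = table[metric].dropna()
        if col.empty:
            continue
        votes[metric] = int(col.idxmin() if metric in _LOWER_IS_BETTER else col.idxmax())
    counts = Counter(votes.values())
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return ConsensusResult(dimension=None, votes=votes, table=table, unresolved=True)
    return ConsensusResult(dimension=top[0][0], votes=votes, table=table)
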