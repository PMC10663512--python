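"""Plain-text formats: edge lists, coordinate tables, label files.

Edge lists are two whitespace-separated node labels per line with '#'
comments.  Coordinate tables are TSV with a '# key=value' comment header
carrying the fitted global parameters; numeric fields are written with 17
significant digits so a write-read round trip is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .hyperbolic import to_hyperbolic
from .inference import NetworkData
from .likelihood import EmbeddingResult

logger = logging.getLogger(__name__)

__all__ = ["read_edgelist", "write_coordinates", "read_coordinates", "CoordinateTable", "write_edgelist"]


def read_edgelist(path) -> NetworkData:
    """Parse an edge list into a simple undirected graph.

    Self-loops and duplicate edges are dropped (with counts logged); labels
    are mapped to dense indices with the original labels retained.  If the
    graph is disconnected, the largest connected component is kept and a
    warning reports how many nodes were discarded.
    """
    label_to_idx: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    self_loops = 0
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two node labels, got {body!r}")
            a, b = parts
            ia = label_to_idx.setdefault(a, len(label_to_idx))
            ib = label_to_idx.setdefault(b, len(label_to_idx))
            if ia == ib:
                self_loops += 1
                continue
            key = (min(ia, ib), max(ia, ib))
            if key in edges:
                duplicates += 1
            else:
                edges.add(key)
    if not edges:
        raise ValueError(f"{path}: no edges found")
    if self_loops or duplicates:
        logger.info("dropped %d self-loops and %d duplicate edges", self_loops, duplicates)
    n = len(label_to_idx)
    rows, cols = np.array(sorted(edges)).T
    A = sp.csr_matrix(
        (np.ones(rows.shape[0] * 2, dtype=np.int8), (np.r_[rows, cols], np.r_[cols, rows])),
        shape=(n, n),
    )
    labels = list(label_to_idx)
    n_comp, comp = connected_components(A, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        keep = np.flatnonzero(comp == int(np.argmax(sizes)))
        logger.warning(
            "graph has %d components; keeping the largest (%d nodes, discarding %d)",
            n_comp, keep.size, n - keep.size,
        )
        A = A[keep][:, keep]
        labels = [labels[i] for i in keep]
    return NetworkData.from_adjacency(A, node_labels=labels)


def write_edgelist(adjacency: sp.spmatrix, path, labels=None) -> None:
    """Write an undirected edge list (each edge once), TSV."""
    coo = sp.triu(sp.csr_matrix(adjacency), k=1).tocoo()
    with open(path, "w") as fh:
        for i, j in zip(coo.row, coo.col):
            a = labels[i] if labels is not None else i
            b = labels[j] if labels is not None else j
            fh.write(f"{a}\t{b}\n")


@dataclass
class CoordinateTable:
    """Per-node embedding record plus the fitted global parameters."""

    labels: list
    kappa: np.ndarray
    positions: np.ndarray
    radial: np.ndarray
    meta: dict

    @property
    def D(self) -> int:
        return int(self.meta["D"])


def write_coordinates(result: EmbeddingResult, path, labels=None) -> None:
    """Serialize an embedding: label, kappa, D+1 unit components, radius r."""
    params = result.params
    coords = to_hyperbolic(result.positions, result.hidden_degrees.kappa, params)
    n, d1 = result.positions.shape
    if labels is None:
        labels = list(range(n))
    meta = {
        "N": n,
        "D": params.D,
        "beta": params.beta,
        "mu": params.mu,
        "R": params.R,
        "R_hat": coords.R_hat,
        "mean_degree": params.mean_degree,
    }
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val!r}\n")
        cols = ["label", "kappa"] + [f"x{d}" for d in range(d1)] + ["r"]
        fh.write("# " + "\t".join(cols) + "\n")
        for i in range(n):
            fields = [str(labels[i]), f"{result.hidden_degrees.kappa[i]:.17g}"]
            fields += [f"{v:.17g}" for v in result.positions[i]]
            fields.append(f"{coords.radial[i]:.17g}")
            fh.write("\t".join(fields) + "\n")


def read_coordinates(path) -> CoordinateTable:
    """Read a coordinate table back; validates header/column consistency."""
    meta: dict = {}
    labels: list = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    val = val.strip()
                    for cast in (int, float):
                        try:
                            val = cast(val)
                            break
                        except ValueError:
                            continue
                    meta[key.strip()] = val
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if "D" not in meta:
        raise ValueError(f"{path}: missing 'D' in header")
    D = int(meta["D"])
    data = np.array(rows)
    expected = 1 + (D + 1) + 1  # kappa, D+1 components, r
    if data.shape[1] != expected:
        raise ValueError(
            f"{path}: header D={D} implies {expected} numeric columns, found {data.shape[1]}"
        )
    kappa = data[:, 0]
    positions = data[:, 1 : D + 2]
    norms = np.linalg.norm(positions, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError(f"{path}: stored vectors are not unit norm")
    return CoordinateTable(
        labels=labels, kappa=kappa, positions=positions, radial=data[:, -1], meta=meta
    )
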