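"""Pearson connectivity matrices and sparsity-sweep binarization.

Sparsity is the fraction of retained edges out of the N(N-1)/2 possible
undirected edges.  Thresholding keeps the K = floor(s * N(N-1)/2) strongest
edges, so the realised sparsity never exceeds the requested one and edge
sets nest across the sweep.  Edges are ranked by signed correlation by
default (positive correlations fill the graph first); ranking by absolute
value is available via ``rank="absolute"``.  Ties at the cutoff are broken
by lexicographic (i, j) node order so results are identical across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SubjectRecord

#: The standard threshold sweep: 0.05 to 0.50 in steps of 0.05.
DEFAULT_SPARSITIES = tuple(np.round(np.arange(1, 11) * 0.05, 2))

RANK_SIGNED = "signed"
RANK_ABSOLUTE = "absolute"


@dataclass
class ConnectivityMatrix:
    """A subject's N x N Pearson correlation matrix (unit diagonal)."""

    subject_id: str
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {r.shape}")
        if not np.isfinite(r).all():
            raise ValueError("correlation matrix contains non-finite values")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        self.r = (r + r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class GraphStack:
    """Binary adjacency matrices of one subject across the sparsity sweep."""

    subject_id: str
    sparsities: tuple[float, ...]
    adjacency: np.ndarray  # (S, N, N) uint8
    edge_counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 3 or adj.shape[1] != adj.shape[2]:
            raise ValueError("adjacency must be (S, N, N)")
        if adj.shape[0] != len(self.sparsities):
            raise ValueError("one adjacency per sparsity level required")
        self.adjacency = adj.astype(np.uint8)
        self.edge_counts = tuple(
            int(a.sum() // 2) for a in self.adjacency
        )

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[2]

    def graph(self, level: int) -> np.ndarray:
        return self.adjacency[level]


def pearson_matrix(record: SubjectRecord) -> ConnectivityMatrix:
    """Sample Pearson correlation between all pairs of regional series."""
    ts = record.timeseries
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"subject {record.subject_id!r}: zero-variance region(s) "
            f"{dead.tolist()}"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(subject_id=record.subject_id, r=r)


def _edge_order(r: np.ndarray, rank: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted strongest-first under the rank policy."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    key = np.abs(vals) if rank == RANK_ABSOLUTE else vals
    # np.lexsort: last key is primary. Descending strength, then (i, j).
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order]


def threshold_by_sparsity(conn: ConnectivityMatrix, sparsity: float,
                          rank: str = RANK_SIGNED) -> np.ndarray:
    """Binarize a correlation matrix at one sparsity level.

    Keeps exactly ``floor(sparsity * N(N-1)/2)`` edges with the largest
    correlation under the ranking policy; returns a symmetric 0/1 matrix
    with zero diagonal.
    """
    if not (0 < sparsity <= 1):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    if rank not in (RANK_SIGNED, RANK_ABSOLUTE):
        raise ValueError(f"unknown rank policy {rank!r}")
    n = conn.n_regions
    k = int(np.floor(sparsity * n * (n - 1) / 2 + 1e-9))
    if k == 0:
        raise ValueError(
            f"sparsity {sparsity} keeps zero edges for N={n}; increase it"
        )
    iu, ju = _edge_order(conn.r, rank)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return adj


def build_graph_stack(conn: ConnectivityMatrix,
                      sparsities: tuple[float, ...] = DEFAULT_SPARSITIES,
                      rank: str = RANK_SIGNED) -> GraphStack:
    """Threshold one correlation matrix over the whole sparsity sweep."""
    sparsities = tuple(float(s) for s in sparsities)
    if any(s2 <= s1 for s1, s2 in zip(sparsities, sparsities[1:])):
        raise ValueError("sparsities must be strictly increasing")
    n = conn.n_regions
    iu, ju = _edge_order(conn.r, rank)
    adj = np.zeros((len(sparsities), n, n), dtype=np.uint8)
    for lvl, s in enumerate(sparsities):
        if not (0 < s <= 1):
            raise ValueError(f"sparsity must be in (0, 1], got {s}")
        k = int(np.floor(s * n * (n - 1) / 2 + 1e-9))
        if k == 0:
            raise ValueError(
                f"sparsity {s} keeps zero edges for N={n}; increase it"
            )
        a = adj[lvl]
        a[iu[:k], ju[:k]] = 1
        a |= a.T
    return GraphStack(subject_id=conn.subject_id, sparsities=sparsities,
                      adjacency=adj)
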