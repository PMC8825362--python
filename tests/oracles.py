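"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — exhaustive simple-path enumeration,
explicit triangle counting, textbook formula evaluation — so it shares no
code path with the package and can serve as an oracle on small graphs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_simple_paths(adj: np.ndarray, src: int, dst: int) -> list[list[int]]:
    """All simple paths from src to dst by depth-first search."""
    n = adj.shape[0]
    paths: list[list[int]] = []

    def walk(node: int, seen: list[int]) -> None:
        if node == dst:
            paths.append(list(seen))
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in seen:
                seen.append(nxt)
                walk(nxt, seen)
                seen.pop()

    walk(src, [src])
    return paths


def brute_path_stats(adj: np.ndarray):
    """(distances, counts, through) by exhaustive path enumeration.

    ``through[i][h, j]`` counts shortest h->j paths with i as an interior
    node.
    """
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.eye(n)
    through = np.zeros((n, n, n))
    for h in range(n):
        for j in range(n):
            if h == j:
                continue
            paths = enumerate_simple_paths(adj, h, j)
            if not paths:
                continue
            d = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == d]
            dist[h, j] = d
            counts[h, j] = len(shortest)
            for p in shortest:
                for i in p[1:-1]:
                    through[i][h, j] += 1
    return dist, counts, through


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    if n < 3:
        return np.zeros(n)
    dist, counts, through = brute_path_stats(adj)
    out = np.zeros(n)
    for i in range(n):
        for h in range(n):
            for j in range(n):
                if h == j or h == i or j == i:
                    continue
                if counts[h, j] > 0 and np.isfinite(dist[h, j]):
                    out[i] += through[i][h, j] / counts[h, j]
    return out / ((n - 1) * (n - 2))


def brute_clustering(adj: np.ndarray):
    n = adj.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2) if adj[a, b]
        )
        per[i] = 2.0 * links / (k * (k - 1))
    return per, per.mean()


def brute_lp(adj: np.ndarray) -> float:
    dist, _, _ = brute_path_stats(adj)
    n = adj.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n)
            if i != j and math.isfinite(dist[i, j])]
    if not vals:
        raise ValueError("no finite pairs")
    return float(np.mean(vals))


def brute_eg(adj: np.ndarray) -> float:
    dist, _, _ = brute_path_stats(adj)
    n = adj.shape[0]
    total = sum(
        1.0 / dist[i, j]
        for i in range(n) for j in range(n)
        if i != j and math.isfinite(dist[i, j])
    )
    return total / (n * (n - 1))


def brute_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    dist, _, _ = brute_path_stats(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / dist[i, j] for j in range(n)
            if j != i and math.isfinite(dist[i, j])
        ) / (n - 1)
    return out


def brute_eloc(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        total += brute_eg(sub)
    return total / n


def brute_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sum-of-products evaluation of the Pearson formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Erdos-Renyi adjacency matrix."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(np.uint8)
    return adj | adj.T


def random_tree(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform-ish random tree via random attachment."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for v in range(1, n):
        u = int(rng.integers(0, v))
        adj[u, v] = adj[v, u] = 1
    return adj
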