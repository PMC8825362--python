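"""Small-world and nodal metrics of binary undirected graphs.

All routines operate on dense 0/1 adjacency matrices with zero diagonal,
the form produced by :mod:`roinet.connectivity`.  The heavy pieces —
all-pairs shortest-path lengths and counts, and betweenness — are computed
with a level-synchronous breadth-first search expressed as boolean matrix
products over all sources at once, which keeps per-graph cost low enough
to sweep thousands of subject-by-sparsity graphs.

Conventions for disconnected graphs (these occur at the sparsest
thresholds): characteristic path length averages over connected (finite)
pairs only, while efficiency-type metrics score a disconnected pair as
zero (1/infinity).  Nodes with fewer than two neighbors contribute zero to
clustering and local efficiency.

Small-world reference values (Cr, Lr) come from an ensemble of
degree-preserving randomized graphs built by Maslov-Sneppen double-edge
swaps: gamma = Cp/Cr, lambda = Lp/Lr, sigma = gamma/lambda.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRIC_NAMES = ("NDi", "NEi", "NBi")


@dataclass
class PathStatistics:
    """All-pairs shortest-path structure of one graph.

    ``distances[h, j]`` is the hop count of a shortest path (``inf`` when
    disconnected); ``counts[h, j]`` the number of distinct shortest paths.
    """

    distances: np.ndarray
    counts: np.ndarray

    def through(self, i: int) -> np.ndarray:
        """Number of shortest h-j paths passing through interior node i.

        Uses the combination identity: paths through i exist iff
        d(h,i) + d(i,j) = d(h,j), and then number sigma_hi * sigma_ij.
        Entries with h = i or j = i or h = j are zero.
        """
        d, s = self.distances, self.counts
        via = d[:, i][:, None] + d[i, :][None, :]
        on_path = np.isfinite(d) & (via == d)
        out = np.where(on_path, np.outer(s[:, i], s[i, :]), 0.0)
        out[i, :] = 0.0
        out[:, i] = 0.0
        np.fill_diagonal(out, 0.0)
        return out


def _as_float_adj(graph: np.ndarray) -> np.ndarray:
    a = np.asarray(graph, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got {a.shape}")
    return a


def shortest_paths(graph: np.ndarray) -> PathStatistics:
    """BFS distances and shortest-path counts for every ordered pair."""
    a = _as_float_adj(graph)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.eye(n)
    frontier = np.eye(n, dtype=bool)
    level = 0
    while frontier.any():
        reach = np.where(frontier, counts, 0.0) @ a
        newly = (reach > 0) & np.isinf(dist)
        if not newly.any():
            break
        level += 1
        dist[newly] = level
        counts[newly] = reach[newly]
        frontier = newly
    return PathStatistics(distances=dist, counts=counts)


def clustering(graph: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering 2*Ei/(Ki*(Ki-1)) and its unweighted mean Cp.

    Ei is the number of edges among node i's neighbors; nodes with fewer
    than two neighbors get zero.
    """
    a = _as_float_adj(graph)
    k = a.sum(axis=1)
    # Ei = number of closed neighbor pairs = ((A @ A) * A).sum(row) / 2
    ei = (a @ a * a).sum(axis=1) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_node = np.where(denom > 0, 2.0 * ei / denom, 0.0)
    return per_node, float(per_node.mean())


def characteristic_path_length(paths: PathStatistics) -> float:
    """Mean shortest-path length over connected ordered pairs."""
    d = paths.distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("graph has no edges; path length undefined")
    return float(d[finite].mean())


def global_efficiency(paths: PathStatistics) -> float:
    """Mean inverse shortest-path length; disconnected pairs score zero."""
    d = paths.distances
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(graph: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    a = _as_float_adj(graph)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        total += global_efficiency(shortest_paths(sub))
    return total / n


def nodal_efficiency(paths: PathStatistics) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    d = paths.distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness(graph: np.ndarray,
                paths: PathStatistics | None = None) -> np.ndarray:
    """Normalized betweenness: fraction of shortest paths through each node.

    For node i, sums sigma_hj(i)/sigma_hj over ordered pairs h != j with
    both distinct from i, divided by (N-1)(N-2).  Values lie in [0, 1];
    degree-0 and degree-1 nodes score zero.
    """
    a = _as_float_adj(graph)
    n = a.shape[0]
    if n < 3:
        return np.zeros(n)
    if paths is None:
        paths = shortest_paths(a)
    d, s = paths.distances, paths.counts
    finite = np.isfinite(d)
    safe = np.where(s > 0, s, 1.0)
    out = np.empty(n)
    for i in range(n):
        via = d[:, i][:, None] + d[i, :][None, :]
        on_path = finite & (via == d)
        frac = np.where(on_path, np.outer(s[:, i], s[i, :]) / safe, 0.0)
        frac[i, :] = 0.0
        frac[:, i] = 0.0
        np.fill_diagonal(frac, 0.0)
        out[i] = frac.sum()
    return out / ((n - 1.0) * (n - 2.0))


@dataclass
class NodalMetrics:
    """Per-node degree, efficiency and normalized betweenness."""

    NDi: np.ndarray
    NEi: np.ndarray
    NBi: np.ndarray


def nodal_metrics(graph: np.ndarray) -> NodalMetrics:
    a = _as_float_adj(graph)
    paths = shortest_paths(a)
    return NodalMetrics(
        NDi=a.sum(axis=1),
        NEi=nodal_efficiency(paths),
        NBi=betweenness(a, paths),
    )


# ---------------------------------------------------------------------------
# degree-preserving randomization and small-world parameters
# ---------------------------------------------------------------------------

def double_edge_swap(graph: np.ndarray, n_swaps: int,
                     rng: np.random.Generator,
                     max_tries: int | None = None) -> np.ndarray:
    """Randomize a graph by Maslov-Sneppen double-edge swaps.

    Picks two edges (a, b), (c, d) and rewires them to (a, d), (c, b) when
    this creates neither self-loops nor multi-edges; every node keeps its
    exact degree.  Stops after ``n_swaps`` successful swaps or ``max_tries``
    attempts (default 100 per requested swap), whichever comes first.
    """
    a = np.asarray(graph, dtype=np.uint8).copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = iu.size
    if m < 2:
        return a
    if max_tries is None:
        max_tries = 100 * n_swaps
    n = a.shape[0]
    ei = iu.tolist()
    ej = ju.tolist()
    present = set(i * n + j for i, j in zip(ei, ej))
    done = 0
    tries = 0
    # draw candidate edge pairs and orientation flips in batches; the
    # per-attempt work is then pure python/set operations
    while done < n_swaps and tries < max_tries:
        batch = min(max_tries - tries, max(1024, 2 * (n_swaps - done)))
        cand = rng.integers(0, m, size=(batch, 2))
        flips = rng.random(batch) < 0.5
        for (e1, e2), flip in zip(cand.tolist(), flips.tolist()):
            if done >= n_swaps:
                break
            tries += 1
            if e1 == e2:
                continue
            x, y = ei[e1], ej[e1]
            u, v = ei[e2], ej[e2]
            if flip:
                u, v = v, u
            # propose (x, v) and (u, y)
            if x == v or u == y:
                continue
            k1 = x * n + v if x < v else v * n + x
            k2 = u * n + y if u < y else y * n + u
            if k1 in present or k2 in present:
                continue
            present.discard(ei[e1] * n + ej[e1])
            present.discard(ei[e2] * n + ej[e2])
            present.add(k1)
            present.add(k2)
            a[x, y] = a[y, x] = 0
            a[u, v] = a[v, u] = 0
            a[x, v] = a[v, x] = 1
            a[u, y] = a[y, u] = 1
            ei[e1], ej[e1] = (x, v) if x < v else (v, x)
            ei[e2], ej[e2] = (u, y) if u < y else (y, u)
            done += 1
    if done < n_swaps:
        logger.debug("double_edge_swap: %d/%d swaps after %d tries",
                     done, n_swaps, tries)
    return a


def random_reference_ensemble(
    graph: np.ndarray,
    n_random: int = 100,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> tuple[float, float]:
    """Ensemble means (Cr, Lr) over degree-preserving randomized graphs.

    Each of the ``n_random`` references is produced by at least
    ``swaps_per_edge`` times the edge count of attempted-successful double
    edge swaps.  If the graph admits no swap at all (complete or nearly
    empty), its own (Cp, Lp) are returned with a warning.
    """
    a = np.asarray(graph, dtype=np.uint8)
    n = a.shape[0]
    m = int(a.sum()) // 2
    if m < 2:
        raise ValueError("need at least 2 edges to build a random reference")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if m == n * (n - 1) // 2:
        warnings.warn("graph is complete; no degree-preserving swap exists, "
                      "returning its own clustering and path length")
        _, cp = clustering(a)
        return cp, characteristic_path_length(shortest_paths(a))
    cs = np.empty(n_random)
    ls = np.empty(n_random)
    for t in range(n_random):
        rnd = double_edge_swap(a, swaps_per_edge * m, rng)
        _, cs[t] = clustering(rnd)
        ls[t] = characteristic_path_length(shortest_paths(rnd))
    return float(cs.mean()), float(ls.mean())


@dataclass
class GlobalMetrics:
    """Global graph metrics and their small-world normalizations."""

    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    Cr: float
    Lr: float
    gamma: float
    lambda_: float
    sigma: float

    def as_dict(self) -> dict[str, float]:
        return {"Cp": self.Cp, "Lp": self.Lp, "Eg": self.Eg,
                "Eloc": self.Eloc, "gamma": self.gamma,
                "lambda": self.lambda_, "sigma": self.sigma}


def small_world(graph: np.ndarray, n_random: int = 100,
                seed: int | np.random.Generator | None = None) -> GlobalMetrics:
    """Assemble Cp, Lp, Eg, Eloc and gamma/lambda/sigma for one graph."""
    a = _as_float_adj(graph)
    paths = shortest_paths(a)
    _, cp = clustering(a)
    lp = characteristic_path_length(paths)
    eg = global_efficiency(paths)
    eloc = local_efficiency(a)
    cr, lr = random_reference_ensemble(a, n_random=n_random, seed=seed)
    if cr == 0 or lr == 0:
        raise ValueError("random reference has zero clustering or path "
                         "length; small-world ratios undefined")
    gamma = cp / cr
    lam = lp / lr
    return GlobalMetrics(Cp=cp, Lp=lp, Eg=eg, Eloc=eloc, Cr=cr, Lr=lr,
                         gamma=gamma, lambda_=lam, sigma=gamma / lam)


@dataclass
class HubSet:
    """Nodes whose metric exceeds the network mean by one SD."""

    metric_name: str
    hub_nodes: tuple[int, ...]
    threshold: float


def identify_hubs(values: np.ndarray, metric_name: str = "") -> HubSet:
    """Hubs: nodes with metric value > mean + 1 sample SD (ddof=1).

    With zero dispersion the hub set is empty.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 nodes to identify hubs")
    sd = values.std(ddof=1)
    threshold = float(values.mean() + sd)
    if sd == 0:
        hubs: tuple[int, ...] = ()
    else:
        hubs = tuple(int(i) for i in np.flatnonzero(values > threshold))
    return HubSet(metric_name=metric_name, hub_nodes=hubs,
                  threshold=threshold)


# ---------------------------------------------------------------------------
# per-cohort metric tables
# ---------------------------------------------------------------------------

def global_metric_table(stacks, n_random: int = 100,
                        seed: int | None = None) -> pd.DataFrame:
    """Long-format table of global metrics: one row per subject x sparsity.

    The random-reference ensemble of every graph is seeded from ``seed``,
    the subject's position and the sparsity level, so the table is
    reproducible and independent of evaluation order.
    """
    rows = []
    for s_idx, stack in enumerate(stacks):
        for lvl, s in enumerate(stack.sparsities):
            gm = small_world(
                stack.graph(lvl), n_random=n_random,
                seed=np.random.default_rng(
                    None if seed is None else (seed, s_idx, lvl)),
            )
            row = {"subject_id": stack.subject_id, "sparsity": s}
            row.update(gm.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def nodal_metric_table(stacks) -> pd.DataFrame:
    """Long-format nodal metrics: one row per subject x sparsity x node."""
    frames = []
    for stack in stacks:
        n = stack.n_regions
        for lvl, s in enumerate(stack.sparsities):
            nm = nodal_metrics(stack.graph(lvl))
            frames.append(pd.DataFrame({
                "subject_id": stack.subject_id,
                "sparsity": s,
                "node": np.arange(n),
                "NDi": nm.NDi,
                "NEi": nm.NEi,
                "NBi": nm.NBi,
            }))
    return pd.concat(frames, ignore_index=True)
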