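"""Jensen-Shannon kNN graph over cell-factor profiles and Leiden states.

Cells are compared on their normalized factor-score profiles using the
square root of the base-2 Jensen-Shannon divergence, a metric bounded in
[0, 1]. The kNN graph is pruned at an "information radius" — a percentile of
observed neighbor distances — and partitioned with the Leiden algorithm
(modularity objective, edge weights 1 - distance). Clusters below a minimum
size are dropped as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import REMOVED

__all__ = [
    "NeighborGraph",
    "StateAssignment",
    "jsd",
    "jsd_matrix",
    "build_knn",
    "prune_by_radius",
    "leiden_states",
]

_LOG2 = np.log(2.0)


def _entropy2(P: np.ndarray) -> np.ndarray:
    """Row-wise base-2 Shannon entropy with 0 log 0 = 0."""
    P = np.asarray(P, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(P > 0, P * np.log2(np.where(P > 0, P, 1.0)), 0.0)
    return -t.sum(axis=-1)


def jsd(p, q) -> float:
    """Jensen-Shannon distance between two probability vectors.

    Returns sqrt of the base-2 Jensen-Shannon divergence: symmetric, zero iff
    p == q, and at most 1 (disjoint supports).
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    for v, name in ((p, "p"), (q, "q")):
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1 (sum={v.sum():.8f})")
    m = 0.5 * (p + q)
    div = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    return float(np.sqrt(max(div, 0.0)))


def jsd_matrix(P: np.ndarray, Q: np.ndarray | None = None,
               chunk: int = 256) -> np.ndarray:
    """Pairwise Jensen-Shannon distances between profile rows (chunked)."""
    P = np.asarray(P, dtype=np.float64)
    Q = P if Q is None else np.asarray(Q, dtype=np.float64)
    hP = _entropy2(P)
    hQ = hP if Q is P else _entropy2(Q)
    out = np.empty((P.shape[0], Q.shape[0]))
    for lo in range(0, P.shape[0], chunk):
        hi = min(lo + chunk, P.shape[0])
        M = 0.5 * (P[lo:hi, None, :] + Q[None, :, :])
        div = _entropy2(M) - 0.5 * (hP[lo:hi, None] + hQ[None, :])
        out[lo:hi] = np.sqrt(np.clip(div, 0.0, None))
    return out


def _correlation_matrix(P: np.ndarray) -> np.ndarray:
    """1 - Pearson r between profile rows (alternative metric)."""
    C = np.corrcoef(P)
    return np.clip(1.0 - C, 0.0, None)


@dataclass
class NeighborGraph:
    """kNN graph with per-edge distances.

    ``edges`` is an (E, 2) int array of node positions with i < j after
    symmetrization; ``distances`` the matching edge lengths.
    """

    nodes: pd.Index
    edges: np.ndarray
    distances: np.ndarray
    k: int
    metric: str = "jsd"
    pruned: bool = False
    radius: float | None = None
    exact: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def isolated_nodes(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return np.flatnonzero(deg == 0)

    def to_igraph(self, weighted: bool = True):
        import igraph as ig

        g = ig.Graph(
            n=self.n_nodes,
            edges=[tuple(e) for e in self.edges.tolist()],
            directed=False,
        )
        if weighted:
            g.es["weight"] = np.clip(1.0 - self.distances, 1e-12, None).tolist()
        return g

    def to_edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_i": self.nodes[self.edges[:, 0]],
                "cell_j": self.nodes[self.edges[:, 1]],
                "distance": self.distances,
            }
        )


def build_knn(
    profiles: np.ndarray,
    k: int,
    cell_ids=None,
    metric: str = "jsd",
) -> NeighborGraph:
    """Exact kNN graph on cell profiles.

    Each node is linked to its ``k`` nearest neighbors (self excluded);
    the edge set is the symmetrized union, deduplicated. ``metric`` is
    ``"jsd"`` (default) or ``"correlation"`` (1 - Pearson r, used by the
    human EMX1+ re-clustering variant).
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    n = profiles.shape[0]
    if cell_ids is None:
        cell_ids = pd.RangeIndex(n)
    cell_ids = pd.Index(cell_ids)
    if cell_ids.has_duplicates:
        raise ValueError("duplicate cell identifiers")
    if not (1 <= k < n):
        raise ValueError(f"k={k} must satisfy 1 <= k < n_cells={n}")
    if metric == "jsd":
        D = jsd_matrix(profiles)
    elif metric == "correlation":
        D = _correlation_matrix(profiles)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, np.inf)
    # k nearest per row; stable order for determinism
    nbr = np.argpartition(D, k, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = nbr.ravel()
    dist = D[rows, cols]
    a = np.minimum(rows, cols)
    b = np.maximum(rows, cols)
    key = a.astype(np.int64) * n + b
    _, first = np.unique(key, return_index=True)
    order = np.sort(first)
    edges = np.stack([a[order], b[order]], axis=1)
    return NeighborGraph(
        nodes=cell_ids,
        edges=edges,
        distances=dist[order],
        k=k,
        metric=metric,
    )


def prune_by_radius(
    graph: NeighborGraph,
    percentile: float = 0.85,
    mode: str = "global",
) -> NeighborGraph:
    """Drop edges beyond the information radius.

    ``mode="global"`` (default): the radius is the given linear-interpolation
    percentile of *all* edge distances; edges strictly longer are removed
    (ties at the radius are retained). ``mode="per-cell"`` instead computes
    each cell's radius from its own incident-edge distances and keeps an edge
    only if it is within the radius of both endpoints.
    """
    if not (0.0 < percentile <= 1.0):
        raise ValueError("percentile must be in (0, 1]")
    if graph.pruned:
        raise ValueError("graph already pruned")
    if mode == "global":
        radius = float(np.quantile(graph.distances, percentile))
        keep = graph.distances <= radius
    elif mode == "per-cell":
        n = graph.n_nodes
        radius_per = np.full(n, np.inf)
        for node in range(n):
            mask = (graph.edges[:, 0] == node) | (graph.edges[:, 1] == node)
            if mask.any():
                radius_per[node] = np.quantile(graph.distances[mask], percentile)
        keep = (graph.distances <= radius_per[graph.edges[:, 0]]) & (
            graph.distances <= radius_per[graph.edges[:, 1]]
        )
        radius = float(np.median(radius_per[np.isfinite(radius_per)]))
    else:
        raise ValueError(f"unknown radius mode {mode!r}")
    out = replace(
        graph,
        edges=graph.edges[keep],
        distances=graph.distances[keep],
        pruned=True,
        radius=radius,
    )
    iso = out.isolated_nodes()
    if iso.size:
        warnings.warn(f"{iso.size} cells isolated after radius pruning")
    return out


@dataclass
class StateAssignment:
    """Per-cell state label (or the REMOVED sentinel) with provenance."""

    cell_ids: pd.Index
    labels: np.ndarray  # object array of state labels / REMOVED
    resolution: float
    seed: int
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("labels/cell_ids length mismatch")

    @property
    def active_mask(self) -> np.ndarray:
        return self.labels != REMOVED

    def states(self) -> list[str]:
        return sorted({l for l in self.labels if l != REMOVED})

    def state_sizes(self) -> pd.Series:
        active = self.labels[self.active_mask]
        return pd.Series(active).value_counts().sort_index()

    def copy_with(self, labels: np.ndarray, action: dict) -> "StateAssignment":
        return StateAssignment(
            cell_ids=self.cell_ids,
            labels=labels,
            resolution=self.resolution,
            seed=self.seed,
            provenance=self.provenance + [action],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.cell_ids, "state": self.labels})


def leiden_states(
    graph: NeighborGraph,
    resolution: float = 1.5,
    seed: int = 0,
    min_cluster_size: int = 20,
    weighted: bool = True,
) -> StateAssignment:
    """Leiden partition of the neighbor graph into states.

    Uses the modularity-with-resolution objective on edge weights
    1 - distance (or unweighted when ``weighted=False``). Clusters with fewer
    than ``min_cluster_size`` cells are relabelled REMOVED with provenance
    action "outlier-drop". Same seed implies identical labels.
    """
    import leidenalg

    if graph.edges.shape[0] == 0:
        raise ValueError("graph has no edges")
    g = graph.to_igraph(weighted=weighted)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if weighted else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # canonical label order: clusters numbered by decreasing size, ties by
    # smallest member position (stable across permutations of input order
    # once nodes are canonically sorted)
    sizes = np.bincount(membership)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    labels = np.array([str(rank[m]) for m in membership], dtype=object)

    assignment = StateAssignment(
        cell_ids=graph.nodes,
        labels=labels,
        resolution=resolution,
        seed=seed,
        provenance=[
            {
                "action": "leiden",
                "resolution": resolution,
                "seed": seed,
                "weighted": weighted,
                "n_clusters": int(sizes.size),
            }
        ],
    )
    # outlier removal
    counts = assignment.state_sizes()
    small = [s for s, c in counts.items() if c < min_cluster_size]
    if small:
        labels = assignment.labels.copy()
        dropped = 0
        for s in small:
            mask = labels == s
            dropped += int(mask.sum())
            labels[mask] = REMOVED
        assignment = assignment.copy_with(
            labels,
            {
                "action": "outlier-drop",
                "states": small,
                "n_cells": dropped,
                "min_cluster_size": min_cluster_size,
            },
        )
    return assignment
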