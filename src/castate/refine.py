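"""State refinement: cell-type purity removal and small-state merging.

Two rules stabilize the Leiden states:

1. **Purity removal** — for every (cell type, state) pair, the cells of that
   type inside the state are removed when they are fewer than
   ``min_type_cells`` OR make up less than ``min_type_fraction`` of the
   type's total. Evaluated in a single pass over the pre-refinement table.
2. **Small-state merging** — states below ``min_state_size`` cells merge,
   smallest first, into their nearest sibling on an average-linkage
   dendrogram of state centroids in a high-dimensional manifold embedding,
   iterated to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import REMOVED
from .state_graph import StateAssignment, jsd_matrix

__all__ = [
    "RefinementConfig",
    "purity_removal",
    "merge_small_states",
    "embed_profiles",
    "embed_for_visualization",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Thresholds for the two refinement rules.

    ``min_type_fraction``/``min_type_cells`` drive purity removal;
    ``min_state_size`` drives merging; ``embed_dims`` is the dimensionality
    of the manifold embedding the merge dendrogram is built on.
    ``purity_rule`` is "or" (either condition removes, the default reading)
    or "and".
    """

    min_type_fraction: float = 0.10
    min_type_cells: int = 15
    min_state_size: int = 250
    embed_dims: int = 10
    purity_rule: str = "or"

    def __post_init__(self) -> None:
        if min(self.min_type_fraction, self.min_type_cells,
               self.min_state_size, self.embed_dims) <= 0:
            raise ValueError("all refinement thresholds must be positive")
        if self.purity_rule not in ("or", "and"):
            raise ValueError("purity_rule must be 'or' or 'and'")


def purity_removal(
    assignment: StateAssignment,
    cell_types,
    config: RefinementConfig = RefinementConfig(),
) -> StateAssignment:
    """Remove low-purity (cell type, state) blocks in a single pass.

    ``cell_types`` is a per-cell label sequence aligned with the assignment.
    Totals per type are computed over non-removed cells before any removal,
    so evaluation is simultaneous, not cascading.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    if len(cell_types) != len(assignment.labels):
        raise ValueError("cell_types length mismatch")
    active = assignment.active_mask
    types = cell_types[active]
    states = assignment.labels[active]
    type_totals = pd.Series(types).value_counts()
    table = (
        pd.DataFrame({"type": types, "state": states})
        .groupby(["type", "state"])
        .size()
    )
    labels = assignment.labels.copy()
    removed_pairs: list[tuple[str, str, int]] = []
    for (t, s), n_ts in table.items():
        frac = n_ts / type_totals[t]
        below_cells = n_ts < config.min_type_cells
        below_frac = frac < config.min_type_fraction
        hit = (below_cells or below_frac) if config.purity_rule == "or" \
            else (below_cells and below_frac)
        if hit:
            mask = active & (cell_types == t) & (assignment.labels == s)
            labels[mask] = REMOVED
            removed_pairs.append((str(t), str(s), int(n_ts)))
    return assignment.copy_with(
        labels,
        {
            "action": "purity-removal",
            "pairs": removed_pairs,
            "n_cells": int(sum(n for _, _, n in removed_pairs)),
            "min_type_fraction": config.min_type_fraction,
            "min_type_cells": config.min_type_cells,
            "rule": config.purity_rule,
        },
    )


def embed_profiles(
    profiles: np.ndarray,
    dims: int = 10,
    seed: int = 0,
    n_neighbors: int = 15,
    metric: str = "jsd",
) -> np.ndarray:
    """UMAP embedding of cells from their factor profiles.

    The pairwise Jensen-Shannon distance matrix is handed to UMAP as a
    precomputed metric, so the embedding reflects the same geometry as the
    clustering graph. Deterministic for a fixed seed.
    """
    import umap

    profiles = np.asarray(profiles, dtype=np.float64)
    n = profiles.shape[0]
    if metric == "jsd":
        D = jsd_matrix(profiles)
        reducer = umap.UMAP(
            n_components=dims,
            n_neighbors=min(n_neighbors, n - 1),
            metric="precomputed",
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(D), dtype=np.float64)
    reducer = umap.UMAP(
        n_components=dims,
        n_neighbors=min(n_neighbors, n - 1),
        metric=metric,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(profiles), dtype=np.float64)


def embed_for_visualization(
    profiles: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_neighbors: int = 50,
) -> np.ndarray:
    """2-D visualization embedding (k=50 neighborhood, no radius pruning)."""
    return embed_profiles(profiles, dims=dims, seed=seed, n_neighbors=n_neighbors)


def _nearest_sibling(
    centroids: pd.DataFrame, sizes: pd.Series, small: str
) -> str:
    """Dendrogram sibling of ``small``: the state joining it at the lowest
    average-linkage merge height (== smallest cophenetic distance), ties
    broken by larger state size, then lexicographic label."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    states = list(centroids.index)
    if len(states) < 2:
        raise ValueError("need at least two states to merge")
    Z = linkage(centroids.to_numpy(), method="average")
    coph = squareform(cophenet(Z))
    i = states.index(small)
    heights = coph[i].copy()
    heights[i] = np.inf
    best = np.min(heights)
    cand = [states[j] for j in np.flatnonzero(heights == best)]
    cand.sort(key=lambda s: (-sizes[s], s))
    return cand[0]


def merge_small_states(
    assignment: StateAssignment,
    profiles: np.ndarray,
    config: RefinementConfig = RefinementConfig(),
    seed: int = 0,
    embedding: np.ndarray | None = None,
) -> StateAssignment:
    """Merge states below ``min_state_size`` into their dendrogram sibling.

    ``profiles`` are per-cell factor profiles aligned with the assignment;
    ``embedding`` may supply precomputed high-dimensional coordinates
    (otherwise a ``config.embed_dims``-dimensional UMAP is computed here).
    Merging proceeds smallest state first and repeats until every state has
    at least ``min_state_size`` cells (or a single state remains).
    """
    labels = assignment.labels.copy()
    sizes = assignment.state_sizes()
    if len(sizes) <= 1:
        warnings.warn("merge_small_states: single state, nothing to merge")
        return assignment
    if embedding is None:
        embedding = embed_profiles(profiles, dims=config.embed_dims, seed=seed)
    embedding = np.asarray(embedding, dtype=np.float64)
    if embedding.shape[0] != len(labels):
        raise ValueError("embedding/assignment length mismatch")

    actions: list[dict] = []
    while True:
        sizes = pd.Series(labels[labels != REMOVED]).value_counts().sort_index()
        too_small = sizes[sizes < config.min_state_size]
        if too_small.empty or len(sizes) < 2:
            break
        small = too_small.sort_values(kind="stable").index[0]
        centroids = pd.DataFrame(
            {
                s: embedding[labels == s].mean(axis=0)
                for s in sizes.index
            }
        ).T
        target = _nearest_sibling(centroids, sizes, small)
        labels[labels == small] = target
        actions.append(
            {
                "action": "merge",
                "from": str(small),
                "into": str(target),
                "n_cells": int(sizes[small]),
            }
        )
    if not actions:
        return assignment
    return StateAssignment(
        cell_ids=assignment.cell_ids,
        labels=labels,
        resolution=assignment.resolution,
        seed=assignment.seed,
        provenance=assignment.provenance + actions,
    )
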