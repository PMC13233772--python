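"""End-to-end pipeline driver: panel restriction through diagnostics.

Stages: restrict to panel -> select K (or fixed K) -> factorize ->
(optional) cell-cycle factor flagging -> Jensen-Shannon kNN graph -> radius
pruning -> Leiden states -> purity removal -> small-state merging ->
visualization embedding -> rate reconstruction + top state genes. Every
stage logs its parameters and duration; all randomness derives from the
config's master seed via named substreams.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import CountMatrix
from .factorize import (
    FactorModel,
    fit_hpf,
    flag_marker_correlated_factors,
    normalize_profiles,
    select_k,
)
from .gene_panel import GenePanel, intersect_with_matrix, load_panel
from .gene_scores import reconstruct_rates, top_state_genes
from .refine import (
    RefinementConfig,
    embed_for_visualization,
    embed_profiles,
    merge_small_states,
    purity_removal,
)
from .state_graph import (
    NeighborGraph,
    StateAssignment,
    build_knn,
    leiden_states,
    prune_by_radius,
)
from . import io as cio

__all__ = ["RunResult", "run_pipeline", "subset_and_rerun"]


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: RunConfig
    matrix: CountMatrix
    model: FactorModel
    profiles: np.ndarray
    graph: NeighborGraph
    assignment: StateAssignment
    embedding: np.ndarray
    top_genes: dict[str, list[str]]
    select_k_table: pd.DataFrame | None = None
    flagged_factors: list[int] = field(default_factory=list)
    unmatched_panel_genes: list[str] = field(default_factory=list)
    stage_log: list[dict] = field(default_factory=list)
    run_dir: Path | None = None


def _log(log: list[dict], stage: str, t0: float, **params) -> None:
    log.append(
        {
            "stage": stage,
            "seconds": round(time.time() - t0, 3),
            **params,
        }
    )


def run_pipeline(
    config: RunConfig,
    matrix: CountMatrix | None = None,
    panel: GenePanel | None = None,
    write: bool = True,
) -> RunResult:
    """Execute the full state-calling pipeline.

    ``matrix``/``panel`` may be passed in memory; otherwise they are read
    from the paths in the config. With ``write=True`` all artifacts land in
    ``config.output_dir`` together with a stage log and a content-hash
    manifest, so a rerun with the same config reproduces identical outputs.
    """
    log: list[dict] = []
    if matrix is None:
        if config.counts_path is None:
            raise ValueError("no matrix given and no counts_path configured")
        matrix = cio.read_counts(config.counts_path)
    if panel is None:
        if config.panel_path is None:
            raise ValueError("no panel given and no panel_path configured")
        panel = load_panel(config.panel_path)

    t0 = time.time()
    restricted, unmatched = intersect_with_matrix(panel, matrix)
    _log(log, "panel_restriction", t0,
         n_genes=restricted.n_genes, n_unmatched=len(unmatched))

    select_table = None
    K = config.K
    if K is None:
        t0 = time.time()
        res = select_k(
            restricted,
            config.candidate_ks,
            m=config.m,
            coverage=config.coverage,
            restarts=config.restarts,
            seed=config.seed_for("select_k"),
            max_iter=min(config.max_iter, 150),
            tol=max(config.tol, 1e-4),
            patience=5,
        )
        K = res.selected_k
        select_table = res.coverage_table
        _log(log, "select_k", t0, K=K, satisfied=res.satisfied)

    t0 = time.time()
    model = fit_hpf(
        restricted,
        K=K,
        seed=config.seed_for("fit"),
        max_iter=config.max_iter,
        tol=config.tol,
    )
    _log(log, "fit", t0, K=K, n_iter=model.n_iter, converged=model.converged)

    flagged: list[int] = []
    if config.flag_cycle_factors:
        t0 = time.time()
        flagged, _table = flag_marker_correlated_factors(
            model, matrix, config.cycle_markers, config.cycle_r_threshold
        )
        if flagged:
            model = model.drop_factors(flagged)
        _log(log, "flag_cycle_factors", t0, flagged=flagged)

    t0 = time.time()
    profiles = normalize_profiles(model)
    graph = build_knn(
        profiles, k=config.k_neighbors, cell_ids=restricted.cell_ids,
        metric=config.metric,
    )
    graph = prune_by_radius(
        graph, config.radius_percentile, mode=config.radius_mode
    )
    _log(log, "graph", t0, k=config.k_neighbors, radius=graph.radius)

    t0 = time.time()
    assignment = leiden_states(
        graph,
        resolution=config.resolution,
        seed=config.seed_for("leiden"),
        min_cluster_size=config.min_cluster_size,
    )
    _log(log, "leiden", t0, n_states=len(assignment.states()))

    refine_cfg = RefinementConfig(
        min_type_fraction=config.min_type_fraction,
        min_type_cells=config.min_type_cells,
        min_state_size=config.min_state_size,
        embed_dims=config.embed_dims,
    )
    t0 = time.time()
    if "cell_type" in restricted.cell_meta.columns:
        assignment = purity_removal(
            assignment, restricted.cell_meta["cell_type"].to_numpy(), refine_cfg
        )
    merge_embedding = embed_profiles(
        profiles, dims=refine_cfg.embed_dims,
        seed=config.seed_for("merge_embedding"),
    )
    assignment = merge_small_states(
        assignment, profiles, refine_cfg,
        seed=config.seed_for("merge"),
        embedding=merge_embedding,
    )
    _log(log, "refine", t0, n_states=len(assignment.states()))

    t0 = time.time()
    embedding = embed_for_visualization(
        profiles, dims=2, seed=config.seed_for("umap"),
        n_neighbors=config.viz_neighbors,
    )
    _log(log, "embed", t0)

    t0 = time.time()
    rates = reconstruct_rates(model, z_normalize=False)
    top = top_state_genes(
        rates, assignment, n=config.top_n_genes, gene_ids=restricted.gene_ids
    )
    _log(log, "scores", t0)

    result = RunResult(
        config=config,
        matrix=restricted,
        model=model,
        profiles=profiles,
        graph=graph,
        assignment=assignment,
        embedding=embedding,
        top_genes=top,
        select_k_table=select_table,
        flagged_factors=flagged,
        unmatched_panel_genes=unmatched,
        stage_log=log,
    )
    if write:
        result.run_dir = _write_run(result)
    return result


def _write_run(result: RunResult) -> Path:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    cio.save_model(result.model, out / "model.h5")
    cio.write_edge_list(result.graph, out / "graph_edges.tsv")
    result.assignment.to_frame().to_csv(out / "states.tsv", sep="\t", index=False)
    with open(out / "provenance.jsonl", "w") as f:
        for action in result.assignment.provenance:
            f.write(json.dumps(action) + "\n")
    emb = pd.DataFrame(
        result.embedding, columns=["umap_1", "umap_2"],
        index=result.matrix.cell_ids,
    )
    emb["state"] = result.assignment.labels
    emb.to_csv(out / "embedding.tsv", sep="\t")
    pd.DataFrame(
        {s: pd.Series(g) for s, g in result.top_genes.items()}
    ).to_csv(out / "top_genes.tsv", sep="\t", index=False)
    if result.select_k_table is not None:
        result.select_k_table.to_csv(out / "select_k.tsv", sep="\t")
    with open(out / "stages.jsonl", "w") as f:
        for rec in result.stage_log:
            f.write(json.dumps(rec) + "\n")
    cio.write_manifest(out)
    return out


def subset_and_rerun(
    parent: RunResult,
    cell_filter,
    overrides: dict | None = None,
) -> RunResult:
    """Re-run the pipeline on a cell subset of a finished run.

    ``cell_filter`` is a boolean mask over the parent's cells or a pandas
    query string evaluated on the parent's cell metadata (with the parent's
    state labels available as column ``state``). Overrides replace config
    fields (e.g. ``{"m": 3, "resolution": 0.6}``); the child writes to
    ``<parent_output>/subset`` unless overridden, and its provenance links
    the parent. The parent result is not modified.
    """
    meta = parent.matrix.cell_meta.copy()
    meta["state"] = parent.assignment.labels
    if isinstance(cell_filter, str):
        mask = meta.eval(cell_filter).to_numpy(dtype=bool)
    else:
        mask = np.asarray(cell_filter, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cell selection")
    overrides = dict(overrides or {})
    overrides.setdefault(
        "output_dir", str(Path(parent.config.output_dir) / "subset")
    )
    child_cfg = parent.config.with_overrides(**overrides)
    sub = parent.matrix.subset_cells(mask)
    panel_like = GenePanel(
        entries=pd.DataFrame(
            {
                "gene": sub.gene_ids,
                "group": "panel",
                "class": "panel",
            }
        )
    )
    child = run_pipeline(child_cfg, matrix=sub, panel=panel_like,
                         write=parent.run_dir is not None)
    child.stage_log.insert(
        0,
        {
            "stage": "subset",
            "parent": str(parent.run_dir),
            "n_cells": int(mask.sum()),
            "overrides": {k: str(v) for k, v in overrides.items()},
        },
    )
    return child
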