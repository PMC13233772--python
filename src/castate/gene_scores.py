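"""Cell-gene scores from the factor model, rankings, set scores, DE, programs.

The factorization's expected loadings reconstruct a denoised Poisson rate
matrix (cells x genes) whose per-state mean ranks state-defining genes.
Further operations: expression-matched gene-set scoring with binarization,
Wilcoxon rank-sum differential expression with Benjamini-Hochberg control,
and complete-linkage cosine clustering of pseudotemporal gene kinetics into
gene programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu

from .containers import CountMatrix, log_normalize
from .factorize import FactorModel
from .state_graph import StateAssignment

__all__ = [
    "RateMatrix",
    "GeneSetScore",
    "reconstruct_rates",
    "top_state_genes",
    "score_gene_set",
    "define_rgc_cells",
    "differential_expression",
    "cluster_gene_programs",
    "benjamini_hochberg",
]


@dataclass
class RateMatrix:
    """Poisson rate reconstruction ``cell_scores @ gene_scores.T``.

    ``z_values`` is the per-gene z-normalized copy (population SD; constant
    columns map to all-zero).
    """

    values: np.ndarray
    gene_ids: pd.Index | None = None
    cell_ids: pd.Index | None = None
    z_values: np.ndarray | None = None


def _z_normalize_columns(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)  # population SD (ddof=0)
    z = np.zeros_like(values, dtype=np.float64)
    ok = sd > 0
    z[:, ok] = (values[:, ok] - mu[ok]) / sd[ok]
    return z


def reconstruct_rates(model: FactorModel, z_normalize: bool = True) -> RateMatrix:
    """Dense cells x genes expected-count matrix from the fitted model."""
    if model.cell_scores.shape[1] != model.gene_scores.shape[1]:
        raise ValueError("cell/gene score factor dimensions differ")
    values = model.cell_scores @ model.gene_scores.T
    z = _z_normalize_columns(values) if z_normalize else None
    return RateMatrix(
        values=values,
        gene_ids=model.gene_ids,
        cell_ids=model.cell_ids,
        z_values=z,
    )


def top_state_genes(
    rates: RateMatrix,
    assignment: StateAssignment,
    n: int = 50,
    gene_ids=None,
) -> dict[str, list[str]]:
    """Per-state ranked gene lists by mean reconstructed rate.

    Genes are sorted by descending mean rate across the state's cells, ties
    broken lexicographically; the top ``n`` are returned. Empty states are
    skipped with a warning.
    """
    gene_ids = pd.Index(gene_ids if gene_ids is not None else rates.gene_ids)
    if gene_ids is None or len(gene_ids) != rates.values.shape[1]:
        raise ValueError("gene_ids must match the rate-matrix columns")
    if len(assignment.labels) != rates.values.shape[0]:
        raise ValueError("assignment does not cover the rate-matrix cells")
    out: dict[str, list[str]] = {}
    for state in assignment.states():
        mask = assignment.labels == state
        if not mask.any():
            warnings.warn(f"state {state!r} has no cells; skipped")
            continue
        means = rates.values[mask].mean(axis=0)
        order = np.lexsort((np.asarray(gene_ids), -means))
        out[state] = [gene_ids[i] for i in order[: min(n, len(gene_ids))]]
    return out


@dataclass
class GeneSetScore:
    """Per-cell gene-set score with its binarization."""

    raw: np.ndarray
    binarized: np.ndarray
    cutoff: float
    genes_used: list[str]

    def __post_init__(self) -> None:
        self.binarized = (self.raw >= self.cutoff).astype(int)


def score_gene_set(
    matrix: CountMatrix,
    gene_set,
    control_bins: int = 25,
    control_size: int = 50,
    seed: int = 0,
    cutoff: float = 1.0,
    log_values: np.ndarray | None = None,
) -> GeneSetScore:
    """Expression-matched gene-set score per cell, binarized at ``cutoff``.

    Score = mean log-normalized expression of the set genes minus the mean of
    a control set: all genes are binned by mean expression into
    ``control_bins`` bins and ``control_size`` control genes are sampled
    (without replacement within a bin when possible) from each set gene's
    bin, set genes excluded. Deterministic for a fixed seed.
    """
    present = [g for g in gene_set if g in matrix.gene_ids]
    if not present:
        raise ValueError(f"no gene of the set found in the matrix: {list(gene_set)}")
    absent = [g for g in gene_set if g not in matrix.gene_ids]
    if absent:
        warnings.warn(f"gene(s) absent from matrix, skipped: {absent}")
    X = log_normalize(matrix) if log_values is None else np.asarray(log_values)
    gene_ids = matrix.gene_ids
    means = X.mean(axis=0)
    # quantile bins on mean expression
    ranks = pd.Series(means).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (len(ranks) / control_bins)).astype(int)
    set_idx = matrix.gene_index(present)
    set_mask = np.zeros(len(gene_ids), dtype=bool)
    set_mask[set_idx] = True
    rng = np.random.default_rng(seed)
    control_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~set_mask)
        if pool.size == 0:
            pool = np.flatnonzero(~set_mask)
        take = min(control_size, pool.size)
        control_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
    control_idx = sorted(set(control_idx))
    raw = X[:, set_idx].mean(axis=1) - X[:, control_idx].mean(axis=1)
    return GeneSetScore(raw=raw, binarized=None, cutoff=cutoff, genes_used=present)


def define_rgc_cells(
    matrix: CountMatrix,
    positive_set=("HES1", "NES", "SOX2"),
    negative_set=("BCAN", "NHLH1"),
    seed: int = 0,
    cutoff: float = 1.0,
    mode: str = "and",
    **score_kwargs,
) -> np.ndarray:
    """Flag radial glial cells by marker-set scores.

    Default (``mode="and"``): positive-set score binarizes to 1 AND
    negative-set score binarizes to 0. ``mode="positive-only"`` uses only the
    positive set.
    """
    pos = score_gene_set(
        matrix, positive_set, seed=seed, cutoff=cutoff, **score_kwargs
    )
    if mode == "positive-only":
        return pos.binarized.astype(bool)
    if mode != "and":
        raise ValueError("mode must be 'and' or 'positive-only'")
    neg = score_gene_set(
        matrix, negative_set, seed=seed + 1, cutoff=cutoff, **score_kwargs
    )
    return (pos.binarized == 1) & (neg.binarized == 0)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=np.float64)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def differential_expression(
    values: np.ndarray,
    group_labels,
    groups: tuple[str, str],
    gene_ids,
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
    already_log: bool = True,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum DE on log-normalized values.

    Parameters
    ----------
    values
        cells x genes log-normalized expression (or raw; set
        ``already_log=False`` to log1p here).
    group_labels, groups
        Per-cell labels and the two labels to compare (A vs B; positive
        log2 fold change means higher in A).

    Returns a per-gene table with ``log2_fc``, the rank-sum ``statistic``,
    raw and BH-adjusted p-values, group means, and a ``significant`` flag
    (adjusted p < alpha and \\|log2 FC\\| >= threshold).
    """
    values = np.asarray(values, dtype=np.float64)
    if not already_log:
        values = np.log1p(values)
    group_labels = np.asarray(group_labels, dtype=object)
    a, b = groups
    ma, mb = group_labels == a, group_labels == b
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    A, B = values[ma], values[mb]
    res = mannwhitneyu(A, B, axis=0, alternative="two-sided", method="auto")
    stat, p = np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    eps = 1e-9
    log2_fc = np.log2((np.expm1(mean_a) + eps) / (np.expm1(mean_b) + eps))
    adj = benjamini_hochberg(p)
    df = pd.DataFrame(
        {
            "gene": pd.Index(gene_ids),
            "log2_fc": log2_fc,
            "statistic": stat,
            "pvalue": p,
            "adjusted_pvalue": adj,
            f"mean_{a}": mean_a,
            f"mean_{b}": mean_b,
        }
    )
    df["significant"] = (df["adjusted_pvalue"] < alpha) & (
        df["log2_fc"].abs() >= logfc_threshold
    )
    return df


def cluster_gene_programs(
    trends: np.ndarray,
    n_programs: int,
    gene_ids=None,
) -> pd.Series:
    """Cluster fitted gene kinetics into programs.

    Rows (genes x ordered trajectory points) are normalized to sum to 1, then
    agglomerated with complete linkage on pairwise cosine distances and the
    tree is cut at ``n_programs``. Scalar multiples of a trend land in the
    same program (cosine scale-invariance).
    """
    trends = np.asarray(trends, dtype=np.float64)
    if (trends < 0).any():
        raise ValueError("trend rows must be nonnegative")
    totals = trends.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = (
            list(pd.Index(gene_ids)[zero[:5]]) if gene_ids is not None
            else zero[:5].tolist()
        )
        raise ValueError(f"all-zero trend for gene(s): {names}")
    norm = trends / totals[:, None]
    if n_programs >= norm.shape[0]:
        labels = np.arange(1, norm.shape[0] + 1)
    else:
        Z = linkage(norm, method="complete", metric="cosine")
        labels = fcluster(Z, t=n_programs, criterion="maxclust")
    index = pd.Index(gene_ids) if gene_ids is not None else pd.RangeIndex(len(labels))
    return pd.Series(labels, index=index, name="program")
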