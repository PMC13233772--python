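"""Null models and quality metrics for the state analysis.

* mean-matched random-gene sampling (background null for the gene panel)
* LISI — local inverse Simpson index of label diversity in an embedding
* neighbor-voting AUROC of functional gene groups (MetaNeighbor-style)
* factor-redundancy normalized mutual information
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import normalized_mutual_info_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, log_normalize
from .factorize import FactorModel
from .gene_panel import MIN_GROUP_SIZE, GenePanel

__all__ = [
    "MatchedGeneSample",
    "EnrichmentResult",
    "sample_matched_genes",
    "lisi",
    "inverse_simpson",
    "auroc",
    "neighbor_voting_auroc",
    "enrichment_by_group",
    "factor_mutual_information",
]


@dataclass
class MatchedGeneSample:
    """One background gene per panel gene, matched on mean expression."""

    mapping: dict[str, str]
    deviation: float
    seed: int
    fallback_count: int = 0

    @property
    def sampled_genes(self) -> list[str]:
        return list(self.mapping.values())


def sample_matched_genes(
    matrix: CountMatrix,
    panel: GenePanel,
    deviation: float = 0.10,
    seed: int = 0,
    min_cells: int = 10,
) -> MatchedGeneSample:
    """Sample one non-panel background gene per panel gene.

    Eligible background genes are expressed in at least ``min_cells`` cells,
    are not panel members, and have a raw mean count within
    ``mean * (1 +/- deviation)`` of the panel gene's. If a panel gene has an
    empty eligible pool, the interval widens in +5% steps (with a warning and
    a fallback count). Different seeds give different samples.
    """
    rng = np.random.default_rng(seed)
    gene_ids = matrix.gene_ids
    means = np.asarray(matrix.counts.mean(axis=0)).ravel()
    n_expressing = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    panel_genes = [g for g in panel.genes if g in gene_ids]
    panel_mask = gene_ids.isin(panel.genes)
    background = np.flatnonzero(~panel_mask & (n_expressing >= min_cells))
    if background.size == 0:
        raise ValueError("no eligible background genes after filtering")
    bg_means = means[background]
    mapping: dict[str, str] = {}
    fallback = 0
    for g in panel_genes:
        mu = means[gene_ids.get_loc(g)]
        dev = deviation
        while True:
            lo, hi = mu * (1 - dev), mu * (1 + dev)
            pool = background[(bg_means >= lo) & (bg_means <= hi)]
            if pool.size:
                break
            dev += 0.05
            fallback += 1
        mapping[g] = gene_ids[rng.choice(pool)]
    if fallback:
        warnings.warn(
            f"{fallback} interval widenings were needed during matched sampling"
        )
    return MatchedGeneSample(
        mapping=mapping, deviation=deviation, seed=seed, fallback_count=fallback
    )


def inverse_simpson(p) -> float:
    """Inverse Simpson index of a probability vector (effective categories)."""
    p = np.asarray(p, dtype=np.float64)
    return float(1.0 / np.sum(p**2))


def lisi(
    coords: np.ndarray,
    labels,
    perplexity: float = 30.0,
    tol: float = 1e-5,
    max_iter: int = 64,
) -> np.ndarray:
    """Per-cell local inverse Simpson index of label diversity.

    For each cell, Gaussian kernel weights over its nearest neighbors are
    calibrated so the weight entropy matches ``log(perplexity)``; the score
    is the inverse Simpson index of the weight-aggregated label distribution.
    1 means a homogeneous neighborhood; the maximum is the number of labels.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("LISI needs at least 2 cells")
    if n < 3 * perplexity:
        raise ValueError(
            f"need >= 3*perplexity={3 * perplexity:.0f} cells, got {n}"
        )
    cats, codes = np.unique(labels, return_inverse=True)
    k = min(n - 1, int(np.ceil(perplexity * 3)))
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self when present in the neighbor list
    if (idx[:, 0] == np.arange(n)).all():
        dist, idx = dist[:, 1:], idx[:, 1:]
    d2 = dist**2
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        beta, lo, hi = 1.0, 0.0, np.inf
        di = d2[i] - d2[i].min()
        for _ in range(max_iter):
            w = np.exp(-beta * di)
            sw = w.sum()
            p = w / sw
            h = -(p * np.log(np.where(p > 0, p, 1.0))).sum()
            if abs(h - target) < tol:
                break
            if h > target:  # too diffuse -> sharpen
                lo = beta
                beta = beta * 2 if hi == np.inf else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        probs = np.bincount(codes[idx[i]], weights=p, minlength=cats.size)
        out[i] = inverse_simpson(probs / probs.sum())
    return out


def auroc(scores, positive_mask) -> float:
    """Area under the ROC curve for a score vector and binary truth."""
    return float(roc_auc_score(np.asarray(positive_mask, dtype=int), scores))


@dataclass
class EnrichmentResult:
    """Per (functional group, label) neighbor-voting AUROC table."""

    table: pd.DataFrame  # columns: group, label, auroc
    folds: int
    seed: int
    reporting_threshold: float = 0.55

    def group_means(self) -> pd.Series:
        return self.table.groupby("group")["auroc"].mean()

    def reported_groups(self) -> list[str]:
        means = self.group_means()
        return sorted(means[means > self.reporting_threshold].index)


def _spearman_network(X: np.ndarray) -> np.ndarray:
    """Cell-cell Spearman correlation, rows rank-normalized to (0, 1]."""
    ranks = rankdata(X, axis=1)
    C = np.corrcoef(ranks)
    C = np.nan_to_num(C, nan=0.0)
    # rank-normalize each row of the network
    R = rankdata(C, axis=1) / C.shape[1]
    return R


def neighbor_voting_auroc(
    matrix: CountMatrix,
    gene_set,
    labels,
    folds: int = 3,
    seed: int = 0,
    min_genes: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Neighbor-voting AUROC of one gene set against the given labels.

    Restricted to the set genes, a cell-cell Spearman correlation network is
    built on log-normalized counts and row rank-normalized. In stratified
    k-fold cross-validation, test cells receive per-label votes equal to
    their mean connectivity to training cells of that label; the AUROC of the
    votes against the true test labels is averaged over folds.

    Returns a DataFrame with one row per label (``label``, ``auroc``,
    ``n_cells``). Labels with fewer cells than ``folds`` are skipped.
    """
    present = [g for g in gene_set if g in matrix.gene_ids]
    if len(present) < min_genes:
        raise ValueError(
            f"gene set needs >= {min_genes} genes present, found {len(present)}"
        )
    labels = np.asarray(labels, dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValueError("labels length mismatch")
    X = log_normalize(matrix)[:, matrix.gene_index(present)]
    net = _spearman_network(X)
    np.fill_diagonal(net, 0.0)

    counts = pd.Series(labels).value_counts()
    keep_labels = [l for l in counts.index if counts[l] >= folds]
    skipped = [l for l in counts.index if counts[l] < folds]
    if skipped:
        warnings.warn(f"labels with < {folds} cells skipped: {skipped}")
    n = len(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: dict[str, list[float]] = {l: [] for l in keep_labels}
    y = labels.astype(str)
    for train, test in skf.split(np.zeros(n), y):
        for lab in keep_labels:
            train_pos = train[y[train] == str(lab)]
            if train_pos.size == 0:
                continue
            votes = net[np.ix_(test, train_pos)].mean(axis=1)
            truth = y[test] == str(lab)
            if truth.all() or not truth.any():
                continue
            scores[lab].append(auroc(votes, truth))
    rows = [
        {
            "label": lab,
            "auroc": float(np.mean(scores[lab])) if scores[lab] else np.nan,
            "n_cells": int(counts[lab]),
        }
        for lab in keep_labels
    ]
    return pd.DataFrame(rows)


def enrichment_by_group(
    matrix: CountMatrix,
    panel: GenePanel,
    labels,
    folds: int = 3,
    seed: int = 0,
    reporting_threshold: float = 0.55,
) -> EnrichmentResult:
    """Neighbor-voting AUROC for every enrichment-eligible functional group."""
    frames = []
    for group in panel.eligible_groups():
        members = [g for g in panel.group_members(group) if g in matrix.gene_ids]
        if len(members) < MIN_GROUP_SIZE:
            continue
        df = neighbor_voting_auroc(
            matrix, members, labels, folds=folds, seed=seed
        )
        df.insert(0, "group", group)
        frames.append(df)
    if not frames:
        raise ValueError("no eligible functional group had enough genes")
    table = pd.concat(frames, ignore_index=True).rename(
        columns={"label": "label"}
    )
    return EnrichmentResult(
        table=table, folds=folds, seed=seed,
        reporting_threshold=reporting_threshold,
    )


def factor_mutual_information(
    model: FactorModel, bins: int = 10
) -> np.ndarray:
    """K x K normalized mutual information between quantile-binned factors.

    Used to assess factor redundancy: near-duplicate factors score close
    to 1 off-diagonal, independent factors close to 0. Constant factors are
    defined as NMI 0 against every other factor (with a warning).
    """
    if model.K < 2:
        raise ValueError("need K >= 2 factors")
    S = model.cell_scores
    K = model.K
    digitized = np.empty_like(S, dtype=int)
    constant = []
    for k in range(K):
        col = S[:, k]
        if np.ptp(col) == 0:
            constant.append(k)
            digitized[:, k] = 0
            continue
        qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
        digitized[:, k] = np.digitize(col, qs)
    if constant:
        warnings.warn(f"constant factor(s) {constant}: NMI set to 0")
    out = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            if i in constant or j in constant:
                v = 0.0
            else:
                v = normalized_mutual_info_score(
                    digitized[:, i], digitized[:, j]
                )
            out[i, j] = out[j, i] = v
    return out
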