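"""Hierarchical gamma-Poisson factorization of panel-restricted UMI counts.

The generative model (per cell i, gene j, factor k):

    xi_i   ~ Gamma(a', a'/b')            per-cell capacity
    theta_ik ~ Gamma(a, xi_i)            cell loadings
    eta_j  ~ Gamma(c', c'/d')            per-gene capacity
    beta_jk ~ Gamma(c, eta_j)            gene loadings
    y_ij   ~ Poisson(sum_k theta_ik * beta_jk)

Inference is mean-field coordinate-ascent variational inference (CAVI) with
gamma variational factors and an implicit multinomial allocation of each
nonzero count across factors. Every update is an exact coordinate step, so
the evidence lower bound (ELBO) is non-decreasing.

``cell_scores``/``gene_scores`` on the fitted model are the expected loadings
E[theta] and E[beta]; their inner product is the Poisson rate matrix used as
a denoised cell-gene count matrix downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import digamma, gammaln

from .containers import CountMatrix, log_normalize

__all__ = [
    "HPFHyperparameters",
    "FactorModel",
    "fit_hpf",
    "select_k",
    "SelectKResult",
    "normalize_profiles",
    "top_m_share",
    "flag_marker_correlated_factors",
]


@dataclass(frozen=True)
class HPFHyperparameters:
    """Gamma shape/rate settings of the hierarchical model.

    ``a``/``c`` are the loading shapes (sparsity; 0.3 is the conventional
    default for this model family), ``a_prime``/``c_prime`` the capacity
    shapes. Capacity prior means ``b_prime``/``d_prime`` are set empirically
    from the data when None, so that the prior expected rate matches the
    empirical mean count split symmetrically between cells and genes.
    """

    a: float = 0.3
    a_prime: float = 1.0
    c: float = 0.3
    c_prime: float = 1.0
    b_prime: float | None = None
    d_prime: float | None = None

    def resolved(self, mean_count: float, K: int) -> "HPFHyperparameters":
        """Fill in data-dependent capacity means."""
        target_loading = np.sqrt(max(mean_count, 1e-12) / K)
        b = self.b_prime if self.b_prime is not None else self.a / target_loading
        d = self.d_prime if self.d_prime is not None else self.c / target_loading
        return HPFHyperparameters(
            a=self.a, a_prime=self.a_prime, c=self.c, c_prime=self.c_prime,
            b_prime=b, d_prime=d,
        )


@dataclass
class FactorModel:
    """A fitted factorization.

    ``cell_scores`` (cells x K) and ``gene_scores`` (genes x K) are the
    expected nonnegative loadings; ``elbo_trace`` is the per-sweep objective.
    """

    K: int
    cell_scores: np.ndarray
    gene_scores: np.ndarray
    hyperparameters: HPFHyperparameters
    elbo_trace: np.ndarray
    seed: int
    converged: bool
    n_iter: int
    cell_ids: pd.Index | None = None
    gene_ids: pd.Index | None = None

    @property
    def n_cells(self) -> int:
        return self.cell_scores.shape[0]

    @property
    def n_genes(self) -> int:
        return self.gene_scores.shape[0]

    def drop_factors(self, factor_indices) -> "FactorModel":
        """Return a copy with the given factor columns removed."""
        keep = np.setdiff1d(np.arange(self.K), np.asarray(factor_indices, int))
        if keep.size == 0:
            raise ValueError("cannot drop every factor")
        return FactorModel(
            K=keep.size,
            cell_scores=self.cell_scores[:, keep].copy(),
            gene_scores=self.gene_scores[:, keep].copy(),
            hyperparameters=self.hyperparameters,
            elbo_trace=self.elbo_trace,
            seed=self.seed,
            converged=self.converged,
            n_iter=self.n_iter,
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids,
        )


def _gamma_entropy(shp: np.ndarray, rte: np.ndarray) -> float:
    return float(
        np.sum(shp - np.log(rte) + gammaln(shp) + (1.0 - shp) * digamma(shp))
    )


@numba.njit(cache=True)
def _allocate_and_aggregate(ii, jj, y, elog_theta, elog_beta, n, g):
    """One pass over the nonzero counts: optimal multinomial allocation.

    Returns (sum_j y*phi by cell, sum_i y*phi by gene, sum_ij y*logsumexp),
    i.e. both sufficient statistics of the allocation step plus the Poisson
    ELBO term, without materializing the nnz x K allocation matrix.
    """
    K = elog_theta.shape[1]
    theta_agg = np.zeros((n, K))
    beta_agg = np.zeros((g, K))
    ylse = 0.0
    buf = np.empty(K)
    for e in range(y.shape[0]):
        i, j = ii[e], jj[e]
        mx = -np.inf
        for k in range(K):
            v = elog_theta[i, k] + elog_beta[j, k]
            buf[k] = v
            if v > mx:
                mx = v
        s = 0.0
        for k in range(K):
            buf[k] = np.exp(buf[k] - mx)
            s += buf[k]
        ylse += y[e] * (mx + np.log(s))
        w = y[e] / s
        for k in range(K):
            theta_agg[i, k] += w * buf[k]
            beta_agg[j, k] += w * buf[k]
    return theta_agg, beta_agg, ylse


def _as_counts(matrix) -> tuple[sp.csr_matrix, pd.Index | None, pd.Index | None]:
    if isinstance(matrix, CountMatrix):
        return matrix.counts.tocsr(), matrix.cell_ids, matrix.gene_ids
    return sp.csr_matrix(matrix), None, None


def fit_hpf(
    matrix,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    patience: int = 10,
    min_iter: int = 30,
    hyper: HPFHyperparameters | None = None,
) -> FactorModel:
    """Fit the hierarchical gamma-Poisson model by CAVI.

    Parameters
    ----------
    matrix
        :class:`CountMatrix` or sparse/dense nonnegative integer array,
        cells x genes.
    K
        Number of latent factors (>= 1).
    seed
        Seeds the variational initialization; identical seeds give
        bit-identical fits.
    max_iter, tol, patience, min_iter
        Stop when the relative ELBO change stays below ``tol`` for
        ``patience`` consecutive sweeps (checked only after ``min_iter``
        sweeps, so a slow early climb out of the symmetric initialization is
        not mistaken for convergence), or at ``max_iter`` with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X, cell_ids, gene_ids = _as_counts(matrix)
    n, g = X.shape
    if X.nnz == 0:
        raise ValueError("all-zero count matrix cannot be factorized")

    coo = X.tocoo()
    ii, jj, y = coo.row, coo.col, coo.data.astype(np.float64)
    mean_count = float(y.sum()) / (n * g)
    hp = (hyper or HPFHyperparameters()).resolved(mean_count, K)
    a, ap, bp = hp.a, hp.a_prime, hp.b_prime
    c, cp, dp = hp.c, hp.c_prime, hp.d_prime

    rng = np.random.default_rng(seed)
    target = np.sqrt(mean_count / K)
    # variational gamma params: loading (n|g, K), capacity (n|g,)
    theta_shp = a * (1.0 + 0.2 * rng.random((n, K)))
    theta_rte = (a / target) * (1.0 + 0.2 * rng.random((n, K)))
    beta_shp = c * (1.0 + 0.2 * rng.random((g, K)))
    beta_rte = (c / target) * (1.0 + 0.2 * rng.random((g, K)))
    xi_shp = np.full(n, ap + K * a)
    xi_rte = np.full(n, (ap + K * a) / bp) * (1.0 + 0.1 * rng.random(n))
    eta_shp = np.full(g, cp + K * c)
    eta_rte = np.full(g, (cp + K * c) / dp) * (1.0 + 0.1 * rng.random(g))

    log_fact_y = float(gammaln(y + 1.0).sum())

    def expectations():
        Etheta = theta_shp / theta_rte
        Ebeta = beta_shp / beta_rte
        return Etheta, Ebeta

    def log_expectations():
        Elog_theta = digamma(theta_shp) - np.log(theta_rte)
        Elog_beta = digamma(beta_shp) - np.log(beta_rte)
        return Elog_theta, Elog_beta

    def elbo(ylse: float) -> float:
        """Variational bound, with the allocation step already optimal
        (``ylse`` = sum_ij y_ij * logsumexp_k(E[log theta]+E[log beta]))."""
        Etheta, Ebeta = expectations()
        Exi = xi_shp / xi_rte
        Eeta = eta_shp / eta_rte
        Elog_xi = digamma(xi_shp) - np.log(xi_rte)
        Elog_eta = digamma(eta_shp) - np.log(eta_rte)
        Elog_theta, Elog_beta = log_expectations()
        # Poisson term with optimal allocation
        ll = ylse - log_fact_y
        ll -= float(Etheta.sum(axis=0) @ Ebeta.sum(axis=0))
        # loadings: prior cross-entropy + entropy
        ll += float(
            np.sum(
                a * Elog_xi[:, None]
                - gammaln(a)
                + (a - 1.0) * Elog_theta
                - Exi[:, None] * Etheta
            )
        )
        ll += _gamma_entropy(theta_shp, theta_rte)
        ll += float(
            np.sum(
                c * Elog_eta[:, None]
                - gammaln(c)
                + (c - 1.0) * Elog_beta
                - Eeta[:, None] * Ebeta
            )
        )
        ll += _gamma_entropy(beta_shp, beta_rte)
        # capacities
        ll += float(
            np.sum(
                ap * np.log(ap / bp) - gammaln(ap)
                + (ap - 1.0) * Elog_xi - (ap / bp) * Exi
            )
        )
        ll += _gamma_entropy(xi_shp, xi_rte)
        ll += float(
            np.sum(
                cp * np.log(cp / dp) - gammaln(cp)
                + (cp - 1.0) * Elog_eta - (cp / dp) * Eeta
            )
        )
        ll += _gamma_entropy(eta_shp, eta_rte)
        return ll

    trace: list[float] = []
    still = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # allocation step: both sufficient statistics + Poisson ELBO term.
        # The allocation is an explicit variational parameter, so updating
        # theta and beta from the same allocation is exact coordinate ascent.
        Elog_theta, Elog_beta = log_expectations()
        theta_agg, beta_agg, ylse = _allocate_and_aggregate(
            ii, jj, y, Elog_theta, Elog_beta, n, g
        )
        # bound at the current loadings with the allocation re-optimized
        trace.append(elbo(ylse))
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
            still = still + 1 if rel < tol else 0
            if still >= patience and it >= min_iter:
                converged = True
                break
        # cells
        theta_shp = a + theta_agg
        _, Ebeta = expectations()
        theta_rte = (xi_shp / xi_rte)[:, None] + Ebeta.sum(axis=0)[None, :]
        # genes
        beta_shp = c + beta_agg
        Etheta, _ = expectations()
        beta_rte = (eta_shp / eta_rte)[:, None] + Etheta.sum(axis=0)[None, :]
        # capacities
        Etheta, Ebeta = expectations()
        xi_rte = ap / bp + Etheta.sum(axis=1)
        eta_rte = cp / dp + Ebeta.sum(axis=1)

    if not converged:
        warnings.warn(
            f"HPF did not converge in {max_iter} iterations (K={K}, seed={seed})"
        )

    Etheta, Ebeta = expectations()
    return FactorModel(
        K=K,
        cell_scores=Etheta,
        gene_scores=Ebeta,
        hyperparameters=hp,
        elbo_trace=np.asarray(trace),
        seed=seed,
        converged=converged,
        n_iter=it,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
    )


def normalize_profiles(model: FactorModel) -> np.ndarray:
    """Per-cell probability vectors over factors (rows sum to 1)."""
    totals = model.cell_scores.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        ids = (
            list(model.cell_ids[zero[:5]]) if model.cell_ids is not None
            else zero[:5].tolist()
        )
        raise ValueError(f"cells with zero total factor score: {ids}")
    return model.cell_scores / totals[:, None]


def top_m_share(profiles: np.ndarray, m: int) -> np.ndarray:
    """Per-cell share captured by each cell's top ``m`` factors."""
    m = min(m, profiles.shape[1])
    part = np.partition(profiles, profiles.shape[1] - m, axis=1)
    return part[:, profiles.shape[1] - m :].sum(axis=1)


@dataclass
class SelectKResult:
    selected_k: int
    coverage_table: pd.DataFrame  # index K, columns: per-restart + mean
    m: int
    coverage: float
    satisfied: bool


def select_k(
    matrix,
    candidate_ks,
    m: int = 4,
    coverage: float = 0.70,
    restarts: int = 3,
    seed: int = 0,
    **fit_kwargs,
) -> SelectKResult:
    """Model-size selection by the top-m coverage rule.

    For each candidate K (averaged over ``restarts`` independent fits), the
    mean over cells of the summed top-``m`` normalized factor scores is
    computed; the selected K is the **largest** candidate whose mean coverage
    is at least ``coverage``. If no candidate satisfies the rule the smallest
    candidate is returned with ``satisfied=False`` and a warning.
    """
    candidate_ks = sorted(int(k) for k in candidate_ks)
    if not candidate_ks:
        raise ValueError("no candidate K values")
    if min(candidate_ks) < m:
        raise ValueError(f"candidates must be >= m={m}")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(restarts)]
    rows = {}
    for K in candidate_ks:
        shares = []
        for s in seeds:
            model = fit_hpf(matrix, K=K, seed=s, **fit_kwargs)
            shares.append(float(top_m_share(normalize_profiles(model), m).mean()))
        rows[K] = shares + [float(np.mean(shares))]
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"restart_{i}" for i in range(restarts)] + ["mean"],
    )
    table.index.name = "K"
    ok = table.index[table["mean"] >= coverage]
    if len(ok):
        return SelectKResult(int(ok.max()), table, m, coverage, True)
    warnings.warn(
        f"no candidate K reached top-{m} coverage {coverage}; "
        f"returning smallest candidate {candidate_ks[0]}"
    )
    return SelectKResult(candidate_ks[0], table, m, coverage, False)


def flag_marker_correlated_factors(
    model: FactorModel,
    matrix: CountMatrix,
    markers,
    r_threshold: float = 0.3,
) -> tuple[list[int], pd.DataFrame]:
    """Flag factors whose cell scores track marker-gene expression.

    Pearson correlations are computed between each factor's cell scores and
    the log1p-normalized (counts per 10k) expression of each marker gene;
    a factor is flagged when its max correlation over markers reaches
    ``r_threshold``. The full factor x marker table is returned so callers
    can flag manually. Used to strip cell-cycle factors (markers TOP2A,
    MKI67, BIRC5 in the human analysis).
    """
    present = [mk for mk in markers if mk in matrix.gene_ids]
    absent = [mk for mk in markers if mk not in matrix.gene_ids]
    if absent:
        if not present:
            raise ValueError(f"none of the marker genes found: {list(markers)}")
        warnings.warn(f"marker gene(s) absent, skipped: {absent}")
    cols = matrix.gene_index(present)
    expr = log_normalize(matrix)[:, cols]  # cells x markers
    table = np.zeros((model.K, len(present)))
    for ki in range(model.K):
        scores = model.cell_scores[:, ki]
        for mi in range(len(present)):
            em = expr[:, mi]
            if scores.std() == 0 or em.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(scores, em)[0, 1])
            table[ki, mi] = r
    df = pd.DataFrame(
        table, columns=present,
        index=pd.Index(range(model.K), name="factor"),
    )
    flagged = sorted(np.flatnonzero(np.max(table, axis=1) >= r_threshold).tolist())
    return flagged, df
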