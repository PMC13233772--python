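"""Rate reconstruction, rankings, gene-set scores, DE, gene programs."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from castate.containers import CountMatrix, log_normalize
from castate.gene_scores import (
    RateMatrix,
    benjamini_hochberg,
    cluster_gene_programs,
    define_rgc_cells,
    differential_expression,
    reconstruct_rates,
    score_gene_set,
    top_state_genes,
)
from castate.state_graph import StateAssignment


def _model(cell_scores, gene_scores):
    class M:
        pass

    M.cell_scores = np.asarray(cell_scores, float)
    M.gene_scores = np.asarray(gene_scores, float)
    M.cell_ids = None
    M.gene_ids = pd.Index([f"G{i}" for i in range(M.gene_scores.shape[0])])
    return M


def _assignment(labels):
    labels = np.asarray(labels, dtype=object)
    return StateAssignment(
        cell_ids=pd.Index([f"c{i}" for i in range(len(labels))]),
        labels=labels, resolution=1.0, seed=0,
    )


def _count_matrix(X, genes=None):
    X = sp.csr_matrix(np.asarray(X))
    genes = genes or [f"G{j}" for j in range(X.shape[1])]
    return CountMatrix(
        counts=X,
        cell_meta=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        gene_ids=genes,
    )


class TestRates:
    def test_worked_two_factor_example(self):
        # cell (1,2); genes g1=(0.5,1), g2=(2,0) -> rates (2.5, 2.0)
        m = _model([[1.0, 2.0]], [[0.5, 1.0], [2.0, 0.0]])
        rates = reconstruct_rates(m, z_normalize=False)
        assert np.allclose(rates.values, [[2.5, 2.0]])

    def test_z_normalization_closed_form(self):
        m = _model(np.eye(3), [[1.0, 2.0, 3.0]])
        rates = reconstruct_rates(m, z_normalize=True)
        # column (1,2,3): mean 2, population SD sqrt(2/3)
        expected = np.array([-1.2247449, 0.0, 1.2247449])
        assert np.allclose(rates.z_values[:, 0], expected, atol=1e-6)
        assert abs(rates.z_values[:, 0].mean()) < 1e-9
        assert rates.z_values[:, 0].std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_maps_to_zero(self):
        m = _model(np.ones((4, 1)), [[2.0]])
        rates = reconstruct_rates(m, z_normalize=True)
        assert (rates.z_values == 0.0).all()

    def test_bilinearity_in_cell_scores(self, rng):
        cs = rng.gamma(1, 1, (10, 3))
        gs = rng.gamma(1, 1, (7, 3))
        a = reconstruct_rates(_model(cs, gs), z_normalize=False).values
        b = reconstruct_rates(_model(3.0 * cs, gs), z_normalize=False).values
        assert np.allclose(b, 3.0 * a)


class TestTopStateGenes:
    def test_factor_defining_gene_ranks_first(self):
        cell_scores = np.array([[5.0, 0.1]] * 3 + [[0.1, 5.0]] * 3)
        gene_scores = np.array([[3.0, 0.0], [0.5, 0.5], [0.0, 3.0]])
        rates = reconstruct_rates(_model(cell_scores, gene_scores),
                                  z_normalize=False)
        top = top_state_genes(
            rates, _assignment(["A"] * 3 + ["B"] * 3), n=3,
            gene_ids=["ga", "mid", "gb"],
        )
        assert top["A"][0] == "ga"
        assert top["B"][0] == "gb"

    def test_n_beyond_gene_count_returns_full_ranking(self):
        rates = RateMatrix(values=np.ones((2, 3)))
        top = top_state_genes(
            rates, _assignment(["A", "A"]), n=99, gene_ids=["b", "a", "c"]
        )
        assert sorted(top["A"]) == ["a", "b", "c"]
        assert top["A"] == ["a", "b", "c"]  # ties broken lexicographically

    def test_cell_order_invariance_within_state(self, rng):
        values = rng.gamma(1, 1, (20, 10))
        labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        perm = rng.permutation(20)
        t1 = top_state_genes(RateMatrix(values=values), _assignment(labels),
                             n=5, gene_ids=[f"G{i}" for i in range(10)])
        t2 = top_state_genes(RateMatrix(values=values[perm]),
                             _assignment(labels[perm]),
                             n=5, gene_ids=[f"G{i}" for i in range(10)])
        assert t1 == t2

    def test_planted_marker_recovery_in_top50(self, fixtures):
        """Markers of each state's dominant factor rank inside its top-50.

        Uses the peaked-usage fixture: state-defining genes only dominate
        a state's absolute mean-rate ranking when the state concentrates
        its scores on the marker factor.
        """
        from castate.factorize import fit_hpf

        fx = fixtures["impure"]
        model = fit_hpf(fx.matrix, K=6, seed=2, max_iter=200)
        rates = reconstruct_rates(model, z_normalize=False)
        assignment = _assignment(fx.truth.group_labels)
        top = top_state_genes(rates, assignment, n=50,
                              gene_ids=fx.matrix.gene_ids)
        for state, genes in top.items():
            markers = fx.truth.marker_map[state]
            recovery = len(set(genes) & set(markers)) / len(markers)
            assert recovery >= 0.9


class TestGeneSetScore:
    def test_planted_shift_scores_high_and_binarizes(self, rng):
        n, g = 400, 200
        X = rng.poisson(2.0, size=(n, g)).astype(float)
        # planted subpopulation: set genes shifted up strongly
        X[:100, :5] *= 25
        matrix = _count_matrix(X)
        score = score_gene_set(
            matrix, [f"G{i}" for i in range(5)], seed=0, cutoff=1.0,
        )
        assert score.raw[:100].mean() > 1.0
        assert score.binarized[:100].mean() > 0.9
        assert score.binarized[100:].mean() < 0.1

    def test_null_set_scores_near_zero(self, rng):
        X = rng.poisson(5.0, size=(500, 300)).astype(float)
        matrix = _count_matrix(X)
        score = score_gene_set(
            matrix, [f"G{i}" for i in range(10)], seed=0, cutoff=1.0
        )
        assert abs(score.raw.mean()) < 0.1
        assert score.binarized.mean() <= 0.01

    def test_minus_infinity_cutoff_binarizes_all(self, rng):
        X = rng.poisson(1.0, size=(50, 40)).astype(float)
        score = score_gene_set(
            _count_matrix(X), ["G0", "G1"], seed=0, cutoff=-np.inf
        )
        assert (score.binarized == 1).all()

    def test_translation_consistency(self, rng):
        X = rng.poisson(2.0, size=(100, 60)).astype(float)
        matrix = _count_matrix(X)
        logv = log_normalize(matrix)
        s1 = score_gene_set(matrix, ["G0", "G1"], seed=3, log_values=logv)
        s2 = score_gene_set(matrix, ["G0", "G1"], seed=3, log_values=logv + 5.0)
        assert np.allclose(s1.raw, s2.raw, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        X = rng.poisson(2.0, size=(100, 60)).astype(float)
        matrix = _count_matrix(X)
        a = score_gene_set(matrix, ["G0"], seed=5)
        b = score_gene_set(matrix, ["G0"], seed=5)
        assert np.array_equal(a.raw, b.raw)

    def test_no_set_gene_present_errors(self, rng):
        X = rng.poisson(1.0, size=(20, 10)).astype(float)
        with pytest.raises(ValueError, match="no gene"):
            score_gene_set(_count_matrix(X), ["NOPE"], seed=0)

    def test_agrees_with_scanpy_scoring_oracle(self, rng):
        """Independent cross-check against scanpy's binned-control scorer."""
        import scanpy as sc

        n, g = 300, 200
        X = rng.poisson(3.0, size=(n, g)).astype(float)
        X[:80, :6] *= 6  # planted high-scoring subpopulation
        matrix = _count_matrix(X)
        ours = score_gene_set(
            matrix, [f"G{i}" for i in range(6)], seed=0,
            control_bins=25, control_size=50,
        )
        adata = matrix.to_anndata()
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.tl.score_genes(
            adata, [f"G{i}" for i in range(6)], ctrl_size=50, n_bins=25,
            score_name="ref", random_state=0,
        )
        # the two scorers draw different control sets, so agreement is
        # strong but not exact
        r = np.corrcoef(ours.raw, adata.obs["ref"].to_numpy())[0, 1]
        assert r >= 0.9


class TestRGCDefinition:
    def _matrix_with_markers(self, rng):
        # baseline depth high enough that log-normalized values are not
        # dominated by single-count quantization noise
        n = 300
        X = rng.poisson(5.0, size=(n, 150)).astype(float)
        genes = [f"G{j}" for j in range(145)] + [
            "HES1", "NES", "SOX2", "BCAN", "NHLH1"
        ]
        # 0..99: RGC-like (positive high, negative low)
        X[:100, 145:148] = rng.poisson(60.0, size=(100, 3))
        X[:100, 148:150] = 0
        # 100..149: high in both sets
        X[100:150, 145:150] = rng.poisson(60.0, size=(50, 5))
        return _count_matrix(X, genes=genes)

    def test_planted_rgc_cells_flagged(self, rng):
        matrix = self._matrix_with_markers(rng)
        flags = define_rgc_cells(matrix, seed=0)
        assert flags[:100].mean() > 0.9
        assert flags[150:].mean() < 0.05

    def test_double_positive_cells_excluded_under_conjunction(self, rng):
        matrix = self._matrix_with_markers(rng)
        flags = define_rgc_cells(matrix, seed=0, mode="and")
        assert flags[100:150].mean() < 0.1
        flags_pos = define_rgc_cells(matrix, seed=0, mode="positive-only")
        assert flags_pos[100:150].mean() > 0.9


def _rank_sum_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.asarray(stats)
    p_ge = np.mean(stats >= obs)
    p_le = np.mean(stats <= obs)
    return min(1.0, 2 * min(p_ge, p_le))


class TestDifferentialExpression:
    def test_three_vs_three_exact_p(self):
        values = np.array([[5.0], [6.0], [7.0], [1.0], [2.0], [3.0]])
        labels = ["A"] * 3 + ["B"] * 3
        res = differential_expression(
            values, labels, ("A", "B"), gene_ids=["g"], logfc_threshold=0.0
        )
        assert res["pvalue"][0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_not_significant(self):
        values = np.tile([[1.0], [2.0], [3.0]], (2, 1))
        labels = ["A"] * 3 + ["B"] * 3
        res = differential_expression(
            values, labels, ("A", "B"), gene_ids=["g"], logfc_threshold=0.0
        )
        assert res["pvalue"][0] == pytest.approx(1.0)
        assert not res["significant"][0]

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 4), (8, 8)])
    def test_exact_p_matches_permutation_oracle(self, n1, n2, rng):
        # distinct values so the exact method applies (no ties)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        a, b = vals[:n1], vals[n1:]
        res = differential_expression(
            np.concatenate([a, b])[:, None],
            ["A"] * n1 + ["B"] * n2,
            ("A", "B"),
            gene_ids=["g"],
            logfc_threshold=0.0,
        )
        assert res["pvalue"][0] == pytest.approx(_rank_sum_oracle(a, b),
                                                 abs=1e-12)

    def test_planted_twofold_genes_recovered(self, rng):
        n, g = 200, 300
        base = rng.gamma(2.0, 1.0, size=g)
        ratesA = np.tile(base, (n, 1))
        ratesB = ratesA.copy()
        planted = np.arange(30)
        ratesB[:, planted] *= 2.0
        X = np.vstack([rng.poisson(ratesA * 4), rng.poisson(ratesB * 4)])
        matrix = _count_matrix(X)
        res = differential_expression(
            log_normalize(matrix),
            ["A"] * n + ["B"] * n,
            ("B", "A"),
            gene_ids=matrix.gene_ids,
            logfc_threshold=0.5,
        )
        called = set(res.loc[res["significant"], "gene"])
        recall = len(called & {f"G{i}" for i in planted}) / len(planted)
        fdr = (
            len(called - {f"G{i}" for i in planted}) / max(len(called), 1)
        )
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 cells"):
            differential_expression(
                np.ones((3, 1)), ["A", "A", "A"], ("A", "B"), gene_ids=["g"]
            )

    def test_bh_adjustment_is_monotone_step_up(self, rng):
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref)


class TestGenePrograms:
    def test_two_shape_families_give_two_programs(self):
        up = np.tile(np.linspace(0.1, 1.0, 10), (5, 1))
        down = np.tile(np.linspace(1.0, 0.1, 10), (5, 1))
        labels = cluster_gene_programs(np.vstack([up, down]), n_programs=2)
        assert labels.nunique() == 2
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1

    def test_scalar_multiples_co_cluster(self, rng):
        trend = rng.uniform(0.1, 1.0, size=12)
        other = rng.uniform(0.1, 1.0, size=12)
        trends = np.vstack([trend, 7.0 * trend, other])
        labels = cluster_gene_programs(trends, n_programs=2)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[0] != labels.iloc[2]

    def test_planted_23_shape_families_recovered(self, rng):
        # 23 trend shapes x 5 genes each, as in a pseudotime program analysis
        from sklearn.metrics import adjusted_rand_score

        t = np.linspace(0, 1, 40)
        shapes = []
        for i in range(23):
            center = i / 22
            width = 0.08 + 0.04 * (i % 3)
            shapes.append(np.exp(-((t - center) ** 2) / (2 * width**2)))
        rows, truth = [], []
        for i, s in enumerate(shapes):
            for rep in range(5):
                noise = 1.0 + 0.05 * rng.standard_normal(len(t))
                rows.append(np.clip(s * noise, 1e-6, None) * (1 + rep))
                truth.append(i)
        labels = cluster_gene_programs(np.vstack(rows), n_programs=23)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_all_zero_trend_names_gene(self):
        trends = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="bad"):
            cluster_gene_programs(trends, 2, gene_ids=["ok", "bad"])
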