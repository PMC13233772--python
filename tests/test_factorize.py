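"""Hierarchical gamma-Poisson factorization: fit, selection rule, flagging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from castate.containers import CountMatrix
from castate.factorize import (
    fit_hpf,
    flag_marker_correlated_factors,
    normalize_profiles,
    select_k,
    top_m_share,
)


def _count_matrix(X, gene_prefix="G"):
    X = sp.csr_matrix(X)
    return CountMatrix(
        counts=X,
        cell_meta=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        gene_ids=[f"{gene_prefix}{j}" for j in range(X.shape[1])],
    )


class TestFitHPF:
    def test_rank_one_structure_is_recovered(self, rng):
        # rows are scalar multiples of one gene profile -> K=1 fits exactly
        profile = rng.gamma(2.0, 1.0, size=60)
        scale = rng.uniform(0.5, 3.0, size=150)
        rates = np.outer(scale, profile)
        X = rng.poisson(rates)
        model = fit_hpf(_count_matrix(X), K=1, seed=0, max_iter=200)
        recon = model.cell_scores @ model.gene_scores.T
        r = np.corrcoef(recon.ravel(), rates.ravel())[0, 1]
        assert r >= 0.99

    def test_elbo_trace_is_monotone(self, six_state_model):
        trace = six_state_model.elbo_trace
        diffs = np.diff(trace)
        # CAVI: non-decreasing up to relative float slack
        assert (diffs >= -1e-6 * np.abs(trace[:-1])).all()

    def test_same_seed_gives_bit_identical_fit(self, rng):
        X = rng.poisson(1.0, size=(80, 40))
        a = fit_hpf(_count_matrix(X), K=3, seed=42, max_iter=60)
        b = fit_hpf(_count_matrix(X), K=3, seed=42, max_iter=60)
        assert np.array_equal(a.cell_scores, b.cell_scores)
        assert np.array_equal(a.gene_scores, b.gene_scores)
        assert np.array_equal(a.elbo_trace, b.elbo_trace)

    def test_reconstruction_matches_empirical_mean(self, six_state_model,
                                                   six_state_panel_matrix):
        recon_mean = (
            six_state_model.cell_scores @ six_state_model.gene_scores.T
        ).mean()
        empirical = six_state_panel_matrix.counts.sum() / np.prod(
            six_state_panel_matrix.counts.shape
        )
        assert abs(recon_mean - empirical) / empirical <= 0.10

    def test_scaling_counts_scales_reconstructed_rates(self, rng):
        base_rates = rng.gamma(1.0, 1.0, size=(150, 60))
        c = 4.0
        X1 = rng.poisson(base_rates)
        X2 = rng.poisson(c * base_rates)
        m1 = fit_hpf(_count_matrix(X1), K=2, seed=0, max_iter=150)
        m2 = fit_hpf(_count_matrix(X2), K=2, seed=0, max_iter=150)
        r1 = (m1.cell_scores @ m1.gene_scores.T).mean()
        r2 = (m2.cell_scores @ m2.gene_scores.T).mean()
        assert r2 / r1 == pytest.approx(c, rel=0.15)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_hpf(_count_matrix(np.zeros((5, 5))), K=2)

    def test_non_convergence_warns(self, rng):
        X = rng.poisson(1.0, size=(50, 30))
        with pytest.warns(UserWarning, match="did not converge"):
            m = fit_hpf(_count_matrix(X), K=2, seed=0, max_iter=3, min_iter=1)
        assert not m.converged


class TestProfilesAndCoverage:
    def test_profile_normalization(self):
        class Dummy:
            cell_scores = np.array([[2.0, 6.0, 2.0], [1.0, 1.0, 2.0]])
            cell_ids = None

        p = normalize_profiles(Dummy)
        assert np.allclose(p[0], [0.2, 0.6, 0.2])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_one_factor_profiles_are_unity(self, rng):
        X = rng.poisson(1.0, size=(40, 20))
        m = fit_hpf(_count_matrix(X), K=1, seed=0, max_iter=60, min_iter=5)
        assert np.allclose(normalize_profiles(m), 1.0)

    def test_zero_score_cell_is_named(self):
        class Dummy:
            cell_scores = np.array([[1.0, 1.0], [0.0, 0.0]])
            cell_ids = pd.Index(["good", "bad"])

        with pytest.raises(ValueError, match="bad"):
            normalize_profiles(Dummy)

    def test_top_m_share_arithmetic(self):
        profile = np.array([[0.4, 0.3, 0.2, 0.05, 0.05]])
        assert top_m_share(profile, 4)[0] == pytest.approx(0.95)

    def test_fitted_profiles_sum_to_one(self, six_state_model):
        p = normalize_profiles(six_state_model)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestSelectK:
    def test_rule_applies_to_coverage_table(self, monkeypatch, rng):
        # stub the fit so the rule itself is exercised on a known table
        shares = {10: 0.82, 15: 0.74, 20: 0.66}

        def fake_fit(matrix, K, seed, **kw):
            class M:
                cell_scores = np.full((10, K), 1e-6)
            M.cell_scores = M.cell_scores.copy()
            top = shares[K] / 4
            rest = (1 - shares[K]) / (K - 4)
            M.cell_scores[:, :4] = top
            M.cell_scores[:, 4:] = rest
            M.cell_ids = None
            return M

        import castate.factorize as fz
        monkeypatch.setattr(fz, "fit_hpf", fake_fit)
        res = fz.select_k(None, [10, 15, 20], m=4, coverage=0.70, restarts=2)
        assert res.selected_k == 15
        assert res.satisfied

    def test_no_candidate_satisfies_returns_smallest_with_warning(
        self, monkeypatch
    ):
        def fake_fit(matrix, K, seed, **kw):
            class M:
                cell_scores = np.full((10, K), 1.0 / K)
                cell_ids = None
            return M

        import castate.factorize as fz
        monkeypatch.setattr(fz, "fit_hpf", fake_fit)
        with pytest.warns(UserWarning, match="smallest candidate"):
            res = fz.select_k(None, [8, 10], m=4, coverage=0.95, restarts=1)
        assert res.selected_k == 8
        assert not res.satisfied

    def test_candidates_below_m_rejected(self):
        with pytest.raises(ValueError, match=">= m"):
            select_k(None, [2, 8], m=4)


class TestMarkerFlagging:
    def test_duplicated_marker_factor_is_flagged(self, rng):
        from castate.containers import log_normalize

        n = 300
        marker = rng.poisson(5.0, size=n)
        X = rng.poisson(1.0, size=(n, 10))
        X[:, 0] = marker
        matrix = _count_matrix(X)
        # factor scores equal to the marker's log-normalized expression
        marker_expr = log_normalize(matrix)[:, 0]

        class Dummy:
            K = 2
            cell_scores = np.stack(
                [marker_expr + 0.01, rng.random(n)], axis=1
            )

        flagged, table = flag_marker_correlated_factors(
            Dummy, matrix, markers=["G0"], r_threshold=0.3
        )
        assert 0 in flagged and 1 not in flagged
        assert table.loc[0, "G0"] > 0.9

    def test_independent_factor_not_flagged(self, rng):
        n = 2000
        X = rng.poisson(1.0, size=(n, 20))
        matrix = _count_matrix(X)

        class Dummy:
            K = 1
            cell_scores = rng.random((n, 1))

        flagged, table = flag_marker_correlated_factors(
            Dummy, matrix, markers=["G3"], r_threshold=0.3
        )
        assert flagged == []
        assert abs(table.loc[0, "G3"]) < 0.1

    def test_absent_markers_warn_all_absent_error(self, rng):
        X = rng.poisson(1.0, size=(50, 5))
        matrix = _count_matrix(X)

        class Dummy:
            K = 1
            cell_scores = rng.random((50, 1))

        with pytest.warns(UserWarning, match="absent"):
            flag_marker_correlated_factors(
                Dummy, matrix, markers=["G0", "NOPE"], r_threshold=0.3
            )
        with pytest.raises(ValueError, match="none of the marker"):
            flag_marker_correlated_factors(
                Dummy, matrix, markers=["NOPE"], r_threshold=0.3
            )

    def test_cycling_fixture_confound_factor_flagged(self, fixtures):
        fx = fixtures["cycling"]
        from castate.gene_panel import intersect_with_matrix

        restricted, _ = intersect_with_matrix(fx.panel, fx.matrix)
        model = fit_hpf(restricted, K=5, seed=3, max_iter=200)
        flagged, table = flag_marker_correlated_factors(
            model, fx.matrix, markers=fx.truth.confound_markers,
            r_threshold=0.3,
        )
        assert len(flagged) >= 1
        # the flagged factor's cell scores track the true confound loading
        conf = fx.truth.theta[:, fx.truth.confound_factor]
        best = max(
            range(model.K),
            key=lambda k: abs(np.corrcoef(model.cell_scores[:, k], conf)[0, 1]),
        )
        assert best in flagged
        dropped = model.drop_factors(flagged)
        assert dropped.K == model.K - len(flagged)
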