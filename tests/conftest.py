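"""Shared fixtures. Heavy artifacts (generated data, fitted models, pipeline
runs) are session-scoped so the whole suite pays for them once."""

import warnings

import numpy as np
import pytest

from castate.config import RunConfig
from castate.factorize import fit_hpf
from castate.gene_panel import intersect_with_matrix
from castate.pipeline import run_pipeline
from castate.synthetic_data import standard_fixtures

warnings.filterwarnings("ignore", message=".*isolated after radius pruning.*")


@pytest.fixture(scope="session")
def fixtures():
    """All named synthetic fixtures at the canonical seed."""
    return standard_fixtures(seed=1)


@pytest.fixture(scope="session")
def six_state(fixtures):
    return fixtures["six_state"]


@pytest.fixture(scope="session")
def six_state_panel_matrix(six_state):
    restricted, _ = intersect_with_matrix(six_state.panel, six_state.matrix)
    return restricted


@pytest.fixture(scope="session")
def six_state_model(six_state_panel_matrix):
    """HPF fit at the true factor count of the six_state fixture."""
    return fit_hpf(six_state_panel_matrix, K=8, seed=7, max_iter=300)


@pytest.fixture(scope="session")
def six_state_run(six_state):
    """Full pipeline on six_state with fixed K (deterministic)."""
    cfg = RunConfig(K=8, seed=5, output_dir="scratch/test_run")
    return run_pipeline(
        cfg, matrix=six_state.matrix, panel=six_state.panel, write=False
    )


@pytest.fixture(scope="session")
def six_state_select_k(six_state_panel_matrix):
    """Top-m coverage scan over even candidate K values (3 restarts)."""
    from castate.factorize import select_k

    return select_k(
        six_state_panel_matrix,
        list(range(4, 17, 2)),
        m=4,
        coverage=0.70,
        restarts=3,
        seed=13,
        max_iter=150,
        tol=1e-4,
        patience=5,
    )


@pytest.fixture(scope="session")
def random_gene_embedding(six_state):
    """Visualization embedding of a mean-matched random-gene run."""
    from castate.diagnostics import sample_matched_genes
    from castate.factorize import fit_hpf, normalize_profiles
    from castate.refine import embed_for_visualization

    sample = sample_matched_genes(
        six_state.matrix, six_state.panel, deviation=0.10, seed=8
    )
    rand = six_state.matrix.subset_genes(
        six_state.matrix.gene_index(sorted(set(sample.sampled_genes)))
    )
    model = fit_hpf(rand, K=8, seed=8, max_iter=150, tol=1e-4, patience=5)
    return embed_for_visualization(
        normalize_profiles(model), dims=2, seed=8, n_neighbors=50
    )


@pytest.fixture(scope="session")
def six_state_model_selected(six_state_panel_matrix, six_state_select_k):
    """HPF fit at the K chosen by the coverage rule (recovery harness)."""
    return fit_hpf(
        six_state_panel_matrix,
        K=six_state_select_k.selected_k,
        seed=7,
        max_iter=300,
    )


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(0)
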