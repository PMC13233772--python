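"""Readers and writers for counts, models, graphs, and run artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CountMatrix
from .factorize import FactorModel, HPFHyperparameters
from .state_graph import NeighborGraph

__all__ = [
    "read_counts",
    "write_counts_mtx",
    "save_model",
    "load_model",
    "write_edge_list",
    "write_manifest",
]


def _round_or_raise(X: sp.csr_matrix, do_round: bool) -> sp.csr_matrix:
    if X.nnz and not np.allclose(X.data, np.round(X.data)):
        if not do_round:
            raise ValueError(
                "matrix has non-integer values; pass round=True to round"
            )
        X.data = np.round(X.data)
    return X


def read_counts(path, fmt: str | None = None, round: bool = False) -> CountMatrix:
    """Read a UMI count matrix from MTX-with-sidecars or h5ad.

    ``path`` is either a directory containing ``matrix.mtx`` + ``genes.tsv``
    + ``barcodes.tsv`` (optionally ``metadata.tsv`` indexed by barcode) or an
    ``.h5ad`` file. For h5ad, ``spliced``/``unspliced`` layers are summed
    when both are present. Non-integer values raise unless ``round=True``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "h5ad" if path.suffix == ".h5ad" else "mtx"
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if {"spliced", "unspliced"} <= set(adata.layers):
            X = adata.layers["spliced"] + adata.layers["unspliced"]
        X = _round_or_raise(sp.csr_matrix(X), round)
        return CountMatrix(
            counts=X,
            cell_meta=adata.obs.copy(),
            gene_ids=list(adata.var_names),
        )
    if fmt != "mtx":
        raise ValueError(f"unsupported format {fmt!r} (mtx or h5ad)")
    X = sp.csr_matrix(mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    if X.shape != (len(barcodes), len(genes)):
        if X.shape == (len(genes), len(barcodes)):
            X = X.T.tocsr()  # gene-major convention
        else:
            raise ValueError("matrix dimensions do not match sidecars")
    meta_path = path / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta = meta.reindex(barcodes)
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    meta.index = pd.Index(barcodes, name="cell")
    return CountMatrix(
        counts=_round_or_raise(X, round), cell_meta=meta, gene_ids=list(genes)
    )


def write_counts_mtx(matrix: CountMatrix, outdir) -> Path:
    """Write counts as MTX + TSV sidecars (cell-major)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_ids).to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    matrix.cell_meta.to_csv(outdir / "metadata.tsv", sep="\t")
    return outdir


def save_model(model: FactorModel, path) -> Path:
    """Serialize a fitted model to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("cell_scores", data=model.cell_scores)
        f.create_dataset("gene_scores", data=model.gene_scores)
        f.create_dataset("elbo_trace", data=model.elbo_trace)
        if model.cell_ids is not None:
            f.create_dataset(
                "cell_ids", data=np.asarray(model.cell_ids, dtype="S")
            )
        if model.gene_ids is not None:
            f.create_dataset(
                "gene_ids", data=np.asarray(model.gene_ids, dtype="S")
            )
        f.attrs["K"] = model.K
        f.attrs["seed"] = model.seed
        f.attrs["converged"] = model.converged
        f.attrs["n_iter"] = model.n_iter
        hp = model.hyperparameters
        for name in ("a", "a_prime", "c", "c_prime", "b_prime", "d_prime"):
            f.attrs[f"hyper_{name}"] = getattr(hp, name)
    return path


def load_model(path) -> FactorModel:
    with h5py.File(Path(path), "r") as f:
        hp = HPFHyperparameters(
            a=float(f.attrs["hyper_a"]),
            a_prime=float(f.attrs["hyper_a_prime"]),
            c=float(f.attrs["hyper_c"]),
            c_prime=float(f.attrs["hyper_c_prime"]),
            b_prime=float(f.attrs["hyper_b_prime"]),
            d_prime=float(f.attrs["hyper_d_prime"]),
        )
        cell_ids = (
            pd.Index([s.decode() for s in f["cell_ids"][:]])
            if "cell_ids" in f
            else None
        )
        gene_ids = (
            pd.Index([s.decode() for s in f["gene_ids"][:]])
            if "gene_ids" in f
            else None
        )
        return FactorModel(
            K=int(f.attrs["K"]),
            cell_scores=f["cell_scores"][:],
            gene_scores=f["gene_scores"][:],
            hyperparameters=hp,
            elbo_trace=f["elbo_trace"][:],
            seed=int(f.attrs["seed"]),
            converged=bool(f.attrs["converged"]),
            n_iter=int(f.attrs["n_iter"]),
            cell_ids=cell_ids,
            gene_ids=gene_ids,
        )


def write_edge_list(graph: NeighborGraph, path) -> Path:
    path = Path(path)
    graph.to_edge_table().to_csv(path, sep="\t", index=False)
    return path


def write_manifest(run_dir, extra: dict | None = None) -> Path:
    """Write a manifest of content hashes for every file in a run directory."""
    run_dir = Path(run_dir)
    manifest = {"files": {}}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(run_dir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    if extra:
        manifest.update(extra)
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
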