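"""Standard-format I/O: MatrixMarket matrices with TSV sidecars.

Expression datasets are written as ``matrix.mtx`` (cells x genes, raw
counts), ``genes.tsv``, ``barcodes.tsv`` and ``cell_meta.tsv``; hypergraph
matrices as MatrixMarket with node/edge symbol TSVs and a JSON sidecar
holding the threshold and settings; velocity arrays as dense TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .hypergraph import CliqueReduction, IncidenceMatrix
from .simulate import VelocityDataset

__all__ = [
    "write_expression",
    "read_expression",
    "write_hypergraph",
    "read_hypergraph",
    "write_velocity",
    "read_velocity",
]


def write_expression(adata: ad.AnnData, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(outdir / "matrix.mtx", X.tocoo())
    (outdir / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    return outdir


def read_expression(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(mmread(indir / "matrix.mtx")).astype(np.int32)
    genes = (indir / "genes.tsv").read_text().splitlines()
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    obs = pd.read_csv(indir / "cell_meta.tsv", sep="\t")
    obs.index = pd.Index(barcodes)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return ad.AnnData(X=X, obs=obs, var=var)


def write_hypergraph(
    incidence: IncidenceMatrix, clique: CliqueReduction, outdir, settings: dict | None = None
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "incidence.mtx", sp.coo_matrix(incidence.B))
    mmwrite(outdir / "clique.mtx", sp.coo_matrix(clique.M))
    (outdir / "nodes.tsv").write_text("\n".join(incidence.nodes) + "\n")
    (outdir / "edges.tsv").write_text("\n".join(incidence.edges) + "\n")
    meta = {"tau": incidence.tau, **(settings or {})}
    (outdir / "hypergraph.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir


def read_hypergraph(indir) -> tuple[IncidenceMatrix, CliqueReduction, dict]:
    indir = Path(indir)
    nodes = (indir / "nodes.tsv").read_text().splitlines()
    edges = (indir / "edges.tsv").read_text().splitlines()
    meta = json.loads((indir / "hypergraph.json").read_text())
    B = np.asarray(mmread(indir / "incidence.mtx").todense()).astype(np.int8)
    M = np.asarray(mmread(indir / "clique.mtx").todense()).astype(np.int64)
    inc = IncidenceMatrix(B=B, nodes=nodes, edges=edges, tau=float(meta["tau"]))
    return inc, CliqueReduction(M=M, nodes=nodes), meta


def write_velocity(vel: VelocityDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "embedding.tsv", vel.embedding, delimiter="\t")
    np.savetxt(outdir / "velocity.tsv", vel.velocity, delimiter="\t")
    (outdir / "labels.tsv").write_text("\n".join(vel.labels) + "\n")
    return outdir


def read_velocity(indir) -> VelocityDataset:
    indir = Path(indir)
    emb = np.loadtxt(indir / "embedding.tsv", delimiter="\t", ndmin=2)
    vel = np.loadtxt(indir / "velocity.tsv", delimiter="\t", ndmin=2)
    labels = np.asarray((indir / "labels.tsv").read_text().splitlines())
    return VelocityDataset(embedding=emb, velocity=vel, labels=labels)
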