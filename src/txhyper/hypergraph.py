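"""Correlation hypergraph construction and degree centrality.

The hypergraph's nodes are the selected differentially expressed genes and
each remaining transcriptome gene defines one hyperedge containing the node
genes it is strongly correlated with.  Construction: correlate every node
gene against every edge gene across the selected cells, binarize at a
threshold equal to the population standard deviation of all correlation
entries (|r| > tau), and multiply the binary incidence matrix by its
transpose to obtain the clique-reduction ("reduced adjacency") matrix whose
entries count hyperedges shared by each node pair.  Degree centrality is the
row sum in either representation, ranked descending with average split
ranks.

The statsmodels-style entry point is :class:`TranscriptomeHypergraph`
(model) whose :meth:`~TranscriptomeHypergraph.fit` returns a
:class:`HypergraphFit` carrying the incidence matrix, clique reduction,
degree table, central cluster and optional permutation-null Z table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "HypergraphError",
    "CorrelationMatrix",
    "IncidenceMatrix",
    "CliqueReduction",
    "build_correlation",
    "binarize",
    "clique_reduction",
    "degree_rank",
    "TranscriptomeHypergraph",
    "HypergraphFit",
]


class HypergraphError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # nodes x edges, in [-1, 1]
    nodes: list[str]
    edges: list[str]
    method: str
    flagged_nodes: list[str] = field(default_factory=list)  # zero-variance
    flagged_edges: list[str] = field(default_factory=list)


@dataclass
class IncidenceMatrix:
    B: np.ndarray  # nodes x edges, {0, 1}
    nodes: list[str]
    edges: list[str]
    tau: float


@dataclass
class CliqueReduction:
    M: np.ndarray  # nodes x nodes, symmetric non-negative integers
    nodes: list[str]

    def offdiag_rowsums(self) -> np.ndarray:
        return self.M.sum(axis=1) - np.diag(self.M)


def _dense_layer(adata: ad.AnnData, layer: str) -> np.ndarray:
    if layer not in adata.layers:
        raise HypergraphError(f"layer {layer!r} not present; run normalize_log first")
    X = adata.layers[layer]
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def build_correlation(
    adata: ad.AnnData,
    nodes,
    edge_genes: list[str] | None = None,
    cells=None,
    method: str = "pearson",
    layer: str = "normalized",
) -> CorrelationMatrix:
    """Correlate each node gene against each edge gene across selected cells.

    ``nodes`` may be a NodeSet or a list of gene symbols; ``edge_genes``
    defaults to every dataset gene not in the node set.  ``cells`` is an
    optional boolean mask or pandas query string over ``obs``.  Genes with
    zero variance across the selected cells get correlation 0 and are
    flagged.
    """
    node_list = list(getattr(nodes, "genes", nodes))
    if method not in ("pearson", "spearman"):
        raise HypergraphError(f"unknown correlation method {method!r}")
    var_index = adata.var_names
    missing = [g for g in node_list if g not in var_index]
    if missing:
        raise HypergraphError(f"node gene(s) absent from dataset: {missing[:5]}")
    if edge_genes is None:
        node_set = set(node_list)
        edge_list = [g for g in var_index if g not in node_set]
    else:
        edge_list = list(edge_genes)
        missing = [g for g in edge_list if g not in var_index]
        if missing:
            raise HypergraphError(f"edge gene(s) absent from dataset: {missing[:5]}")
        overlap = set(node_list) & set(edge_list)
        if overlap:
            raise HypergraphError(f"genes appear as both node and edge: {sorted(overlap)[:5]}")

    if cells is None:
        mask = np.ones(adata.n_obs, bool)
    elif isinstance(cells, str):
        mask = np.asarray(adata.obs.eval(cells))
    else:
        mask = np.asarray(cells)
    if mask.dtype != bool or mask.shape != (adata.n_obs,):
        raise HypergraphError("cells selector must resolve to a boolean mask")
    n_cells = int(mask.sum())
    if n_cells < 3:
        raise HypergraphError(f"need at least 3 cells for correlation, got {n_cells}")

    dense = _dense_layer(adata, layer)[mask]
    col = {g: i for i, g in enumerate(var_index)}
    xn = dense[:, [col[g] for g in node_list]]
    xe = dense[:, [col[g] for g in edge_list]]
    if method == "spearman":
        xn = stats.rankdata(xn, axis=0)
        xe = stats.rankdata(xe, axis=0)

    def standardize(x):
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        flagged = sd == 0
        z = (x - mu) / np.where(flagged, 1.0, sd)
        z[:, flagged] = 0.0
        return z, flagged

    zn, flag_n = standardize(xn)
    ze, flag_e = standardize(xe)
    corr = np.clip(zn.T @ ze / n_cells, -1.0, 1.0)
    return CorrelationMatrix(
        values=corr,
        nodes=node_list,
        edges=edge_list,
        method=method,
        flagged_nodes=[g for g, f in zip(node_list, flag_n) if f],
        flagged_edges=[g for g, f in zip(edge_list, flag_e) if f],
    )


def binarize(corr: CorrelationMatrix) -> IncidenceMatrix:
    """Threshold |r| strictly above tau = population SD of all entries."""
    if corr.values.size == 0:
        raise HypergraphError("empty correlation matrix")
    tau = float(np.std(corr.values))  # population SD (ddof=0)
    B = (np.abs(corr.values) > tau).astype(np.int8)
    return IncidenceMatrix(B=B, nodes=list(corr.nodes), edges=list(corr.edges), tau=tau)


def clique_reduction(incidence: IncidenceMatrix) -> CliqueReduction:
    """M = B B^T: shared-hyperedge counts per node pair (diagonal = degree)."""
    B = incidence.B
    if not np.isin(B, (0, 1)).all():
        raise HypergraphError("incidence matrix must be binary")
    M = B.astype(np.int64) @ B.astype(np.int64).T
    return CliqueReduction(M=M, nodes=list(incidence.nodes))


def degree_rank(incidence: IncidenceMatrix, clique: CliqueReduction) -> pd.DataFrame:
    """Row sums and descending average-split ranks in both representations."""
    if list(incidence.nodes) != list(clique.nodes):
        raise HypergraphError("incidence and clique reduction node sets differ")
    inc_rowsum = incidence.B.sum(axis=1).astype(float)
    cli_rowsum = clique.offdiag_rowsums().astype(float)
    return pd.DataFrame(
        {
            "incidence_rowsum": inc_rowsum,
            "clique_rowsum": cli_rowsum,
            "rank_incidence": stats.rankdata(-inc_rowsum, method="average"),
            "rank_clique": stats.rankdata(-cli_rowsum, method="average"),
        },
        index=pd.Index(incidence.nodes, name="gene"),
    )


class TranscriptomeHypergraph:
    """Correlation-hypergraph model of one cell subset.

    Parameters
    ----------
    dataset
        AnnData with a normalized layer.
    nodes
        NodeSet or list of node gene symbols (typically top DEGs).
    edge_genes
        Edge gene symbols; defaults to all remaining dataset genes.
    cells
        Boolean mask or pandas query string over ``obs`` selecting the cells
        the correlations are computed on.
    method
        "pearson" (default) or "spearman".
    """

    def __init__(
        self,
        dataset: ad.AnnData,
        nodes,
        edge_genes: list[str] | None = None,
        cells=None,
        method: str = "pearson",
        layer: str = "normalized",
    ):
        self.dataset = dataset
        self.nodes = list(getattr(nodes, "genes", nodes))
        self.edge_genes = edge_genes
        self.cells = cells
        self.method = method
        self.layer = layer

    def fit(
        self,
        k: int | str = 2,
        null_iterations: int = 0,
        null_genes: list[str] | None = None,
        seed: int = 0,
    ) -> "HypergraphFit":
        """Build the hypergraph; optionally detect the central cluster and
        compute permutation-null Z-scores.

        ``k`` is the number of hierarchical clusters ("auto" selects k in
        2..6 by silhouette); ``null_iterations`` > 0 adds an entry-shuffle
        null with that many iterations for ``null_genes`` (default: all
        nodes).
        """
        from .cluster import find_central_cluster
        from .nullmodel import null_z

        corr = build_correlation(
            self.dataset, self.nodes, self.edge_genes, self.cells, self.method, self.layer
        )
        incidence = binarize(corr)
        clique = clique_reduction(incidence)
        degrees = degree_rank(incidence, clique)
        central = find_central_cluster(clique, k=k) if len(self.nodes) >= 2 else None
        null = (
            null_z(clique, genes=null_genes, iterations=null_iterations, seed=seed)
            if null_iterations
            else None
        )
        return HypergraphFit(
            model=self,
            correlation=corr,
            incidence=incidence,
            clique=clique,
            degrees=degrees,
            central=central,
            null=null,
        )


@dataclass
class HypergraphFit:
    """Fitted hypergraph: incidence + clique reduction + centralities."""

    model: TranscriptomeHypergraph
    correlation: CorrelationMatrix
    incidence: IncidenceMatrix
    clique: CliqueReduction
    degrees: pd.DataFrame
    central: object | None = None
    null: pd.DataFrame | None = None

    @property
    def tau(self) -> float:
        return self.incidence.tau

    def summary(self) -> str:
        B = self.incidence.B
        lines = [
            "Transcriptome hypergraph",
            "========================",
            f"nodes:            {len(self.incidence.nodes)}",
            f"edges:            {len(self.incidence.edges)}",
            f"method:           {self.model.method}",
            f"tau (pop. SD):    {self.tau:.4f}",
            f"incidence density:{B.mean():.4f}",
        ]
        if self.central is not None:
            lines.append(f"central cluster:  {len(self.central.members)} genes (k={self.central.k})")
        top = self.degrees.sort_values("rank_clique").head(10)
        lines.append("top nodes by clique-reduction rank:")
        for gene, row in top.iterrows():
            lines.append(
                f"  {gene:<12s} clique_rowsum={row.clique_rowsum:10.0f} "
                f"rank={row.rank_clique:6.1f}"
            )
        if self.null is not None:
            lines.append(
                f"null: {self.null.attrs.get('iterations')} iterations "
                f"({self.null.attrs.get('scheme')})"
            )
        return "\n".join(lines)
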