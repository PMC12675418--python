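"""GWAS variant -> eQTL gene mapping and hypergraph intersection.

Takes GWAS summary statistics (rsID, p-value) and an offline variant->gene
eQTL table (rsID, gene, tissue), selects the lowest-p variants (ties at the
boundary included), filters out excluded tissues, maps to genes, and
intersects the mapped genes with the hypergraph node set and per-tissue
central clusters.  Per-tissue centrality ranks and null Z-scores can then
be attached for node-member genes.

Gene matching is exact on symbol after uppercase normalization; no alias
resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GwasError",
    "GwasGeneReport",
    "read_gwas_summary",
    "read_eqtl_map",
    "validate_gwas_summary",
    "validate_eqtl_map",
    "map_and_intersect",
    "rank_lookup",
]


class GwasError(ValueError):
    pass


def validate_gwas_summary(gwas: pd.DataFrame) -> pd.DataFrame:
    """Check columns and p range; collapse duplicate rsIDs keeping smallest p."""
    required = {"rsid", "p_value"}
    if not required.issubset(gwas.columns):
        raise GwasError(f"GWAS summary must have columns {sorted(required)}")
    p = gwas["p_value"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise GwasError("GWAS p-values must lie in (0, 1]")
    out = gwas.sort_values("p_value", kind="stable").drop_duplicates("rsid", keep="first")
    return out.reset_index(drop=True)


def validate_eqtl_map(eqtl: pd.DataFrame) -> pd.DataFrame:
    required = {"rsid", "gene", "tissue"}
    if not required.issubset(eqtl.columns):
        raise GwasError(f"eQTL map must have columns {sorted(required)}")
    return eqtl.drop_duplicates().reset_index(drop=True)


def read_gwas_summary(path) -> pd.DataFrame:
    return validate_gwas_summary(pd.read_csv(path, sep="\t"))


def read_eqtl_map(path) -> pd.DataFrame:
    return validate_eqtl_map(pd.read_csv(path, sep="\t"))


@dataclass
class GwasGeneReport:
    """Mapped genes with node/central membership, per-tissue ranks and Z."""

    table: pd.DataFrame  # indexed by gene symbol (uppercase)
    n_variants: int
    n_lowest: int
    n_genes_mapped: int
    n_genes_in_nodes: int
    n_genes_in_central: int
    n_rsids_mapped_to_nodes: int
    tissues: list[str] = field(default_factory=list)

    def counts(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "n_lowest": self.n_lowest,
            "n_genes_mapped": self.n_genes_mapped,
            "n_genes_in_nodes": self.n_genes_in_nodes,
            "n_genes_in_central": self.n_genes_in_central,
            "n_rsids_mapped_to_nodes": self.n_rsids_mapped_to_nodes,
        }


def map_and_intersect(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    nodes,
    clusters: dict[str, object] | None = None,
    n_lowest: int = 10_000,
    tissue_exclude: tuple[str, ...] = ("nervous_system",),
) -> GwasGeneReport:
    """Select the lowest-p variants, map through eQTLs, intersect with nodes.

    ``clusters`` maps a tissue label to a CentralCluster (or a plain set of
    gene symbols); membership flags ``in_central_<tissue>`` are emitted per
    cluster.  An excluded tissue label absent from the eQTL table raises a
    warning, not an error.
    """
    if n_lowest < 1:
        raise GwasError("n_lowest must be >= 1")
    gwas = validate_gwas_summary(gwas)
    eqtl = validate_eqtl_map(eqtl)
    clusters = clusters or {}
    node_list = [g.upper() for g in getattr(nodes, "genes", nodes)]
    node_set = set(node_list)

    known_tissues = set(eqtl["tissue"].astype(str))
    for t in tissue_exclude:
        if t not in known_tissues:
            warnings.warn(f"excluded tissue {t!r} not present in eQTL table", stacklevel=2)

    p_sorted = np.sort(gwas["p_value"].to_numpy())
    if n_lowest >= len(p_sorted):
        threshold = p_sorted[-1] if len(p_sorted) else np.inf
    else:
        threshold = p_sorted[n_lowest - 1]  # boundary ties included
    selected = gwas[gwas["p_value"] <= threshold]
    best_p = dict(zip(selected["rsid"], selected["p_value"]))

    rows = eqtl[
        eqtl["rsid"].isin(best_p) & ~eqtl["tissue"].astype(str).isin(set(tissue_exclude))
    ].copy()
    rows["gene"] = rows["gene"].astype(str).str.upper()

    cluster_sets = {
        t: {g.upper() for g in getattr(c, "members", c)} for t, c in clusters.items()
    }

    records = []
    for gene, grp in rows.groupby("gene", sort=True):
        rsids = sorted(grp["rsid"].unique())
        rec = {
            "gene": gene,
            "n_rsids": len(rsids),
            "rsids": ",".join(rsids),
            "best_p": min(best_p[r] for r in rsids),
            "in_nodes": gene in node_set,
        }
        for t, cset in cluster_sets.items():
            rec[f"in_central_{t}"] = gene in cset and gene in node_set
        records.append(rec)

    table = pd.DataFrame.from_records(records)
    if table.empty:
        cols = ["gene", "n_rsids", "rsids", "best_p", "in_nodes"] + [
            f"in_central_{t}" for t in cluster_sets
        ]
        table = pd.DataFrame(columns=cols)
    table = table.set_index("gene")

    in_nodes = table[table["in_nodes"]] if len(table) else table
    central_cols = [c for c in table.columns if c.startswith("in_central_")]
    n_central = int(in_nodes[central_cols].any(axis=1).sum()) if central_cols and len(in_nodes) else 0
    node_rsids = set()
    if len(in_nodes):
        for rs in in_nodes["rsids"]:
            node_rsids.update(rs.split(","))

    return GwasGeneReport(
        table=table,
        n_variants=len(gwas),
        n_lowest=n_lowest,
        n_genes_mapped=len(table),
        n_genes_in_nodes=len(in_nodes),
        n_genes_in_central=n_central,
        n_rsids_mapped_to_nodes=len(node_rsids),
        tissues=list(cluster_sets),
    )


def rank_lookup(
    report: GwasGeneReport,
    degrees: dict[str, pd.DataFrame],
    z_tables: dict[str, pd.DataFrame] | None = None,
) -> GwasGeneReport:
    """Attach per-tissue centrality ranks (and Z when given) to node members.

    ``degrees`` maps tissue label -> degree table from
    :func:`txhyper.hypergraph.degree_rank` computed on the same node set.
    Non-node genes get NaN ranks.
    """
    table = report.table.copy()
    z_tables = z_tables or {}
    for tissue, deg in degrees.items():
        upper = deg.copy()
        upper.index = upper.index.str.upper()
        for col in ("rank_incidence", "rank_clique"):
            table[f"{col}_{tissue}"] = [
                float(upper.at[g, col]) if (row.in_nodes and g in upper.index) else np.nan
                for g, row in zip(table.index, table.itertuples())
            ]
    for tissue, ztab in z_tables.items():
        upper = ztab.copy()
        upper.index = upper.index.str.upper()
        table[f"z_{tissue}"] = [
            float(upper.at[g, "z"]) if (row.in_nodes and g in upper.index) else np.nan
            for g, row in zip(table.index, table.itertuples())
        ]
    out = GwasGeneReport(
        table=table,
        n_variants=report.n_variants,
        n_lowest=report.n_lowest,
        n_genes_mapped=report.n_genes_mapped,
        n_genes_in_nodes=report.n_genes_in_nodes,
        n_genes_in_central=report.n_genes_in_central,
        n_rsids_mapped_to_nodes=report.n_rsids_mapped_to_nodes,
        tissues=sorted(set(report.tissues) | set(degrees)),
    )
    return out
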