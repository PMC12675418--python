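"""End-to-end pipeline: simulate/load -> QC -> normalize -> DE -> nodes ->
per-tissue hypergraphs -> central clusters -> Venn -> GWAS/eQTL integration
with permutation-null Z-scores -> velocity metrics.

One config object (loadable from YAML) drives every stage; all randomness
derives from the single global seed via stage-keyed substreams, so identical
config + seed gives a byte-identical JSON report.
"""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .cluster import find_central_cluster, venn_compare
from .de import rank_sum_de, select_nodes
from .gwas import map_and_intersect, rank_lookup, read_eqtl_map, read_gwas_summary
from .hypergraph import TranscriptomeHypergraph
from .io import read_expression, write_expression, write_hypergraph
from .nullmodel import SCHEME, null_z
from .qc import QCParams, apply_qc, normalize_log
from .simulate import (
    DEFAULT_VELOCITY_CLUSTERS,
    SimConfig,
    VelocityClusterSpec,
    simulate_dataset,
    simulate_gwas_tables,
    simulate_velocity,
)
from .velocity import cluster_summary, compute_metrics

__all__ = ["PipelineConfig", "PipelineReport", "StageError", "run_pipeline", "demo_config"]

log = logging.getLogger("txhyper")


class SimBlock(BaseModel):
    n_cells_per_group: int = 300
    n_genes: int = 2000
    n_clusters: int = 3
    de_genes: int = 200
    de_log2fc: float = 1.5
    module_sizes: list[int] = Field(default_factory=lambda: [120, 60])
    module_rho: float = 0.6
    hub_genes: int = 3
    nb_mean: float = 2.0
    nb_dispersion: float = 1.5
    dropout_rate: float = 0.1
    mito_fraction_range: tuple[float, float] = (0.01, 0.15)
    module_de_fraction: float = 0.25
    module_scopes: Optional[list[str]] = None
    n_mito_genes: int = 10
    secretory_fraction: float = 0.7


class QCBlock(BaseModel):
    min_genes_per_cell: Optional[int] = 200
    min_cells_per_gene: Optional[int] = 3
    max_total_counts: Optional[int] = 850_000
    max_mito_fraction: Optional[float] = 0.30
    max_genes_per_cell: Optional[int] = 8000
    mito_prefix: str = "MT-"


class GwasSimBlock(BaseModel):
    n_variants: int = 10_000
    n_overlap: int = 22
    n_from_preferred: int = 13
    n_background_rows: int = 1000
    rsids_per_gene: tuple[int, int] = (10, 110)


class VelocityClusterBlock(BaseModel):
    name: str
    mean_speed: float
    angular_noise: float  # may be inf (isotropic)


class VelocityBlock(BaseModel):
    n_cells_per_cluster: int = 100
    k: int = 30
    clusters: Optional[list[VelocityClusterBlock]] = None


class PipelineConfig(BaseModel):
    """Full parameter set; every value is echoed into the report."""

    seed: int = 17
    output_dir: str = "txhyper_out"
    simulate: Optional[SimBlock] = Field(default_factory=SimBlock)
    input_dir: Optional[str] = None
    qc: QCBlock = Field(default_factory=QCBlock)
    normalize_total: int = 10_000
    de_group_a: str = "(tissue == 'FT') & (phase == 'secretory')"
    de_group_b: str = "(tissue == 'endometrium') & (phase == 'secretory')"
    node_mode: str = "fixed_n"
    node_n: int = 600
    tissues: dict[str, str] = Field(
        default_factory=lambda: {
            "ft": "(tissue == 'FT') & (phase == 'secretory')",
            "glandular": "(tissue == 'endometrium') & (cluster == 'c0') & (phase == 'secretory')",
            "luminal": "(tissue == 'endometrium') & (cluster == 'c1') & (phase == 'secretory')",
        }
    )
    correlation_method: str = "pearson"
    cluster_k: int | str = 2
    null_iterations: int = 1000
    gwas_simulate: Optional[GwasSimBlock] = Field(default_factory=GwasSimBlock)
    gwas_summary_path: Optional[str] = None
    gwas_eqtl_path: Optional[str] = None
    n_lowest: int = 10_000
    tissue_exclude: list[str] = Field(default_factory=lambda: ["nervous_system"])
    velocity: Optional[VelocityBlock] = Field(default_factory=VelocityBlock)
    write_expression_artifacts: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


class PipelineReport(BaseModel):
    version: str
    seed: int
    config: dict
    stages_completed: list[str] = Field(default_factory=list)
    qc: Optional[dict] = None
    de: Optional[dict] = None
    nodes: Optional[dict] = None
    hypergraphs: Optional[dict[str, dict]] = None
    venn: Optional[dict] = None
    gwas: Optional[dict] = None
    null_model: Optional[dict] = None
    velocity: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(_sanitize(self.model_dump()), indent=2, sort_keys=True)


class StageError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, partial: PipelineReport):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


def _sanitize(obj: Any) -> Any:
    """Make a report JSON-safe: NaN/inf -> None, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if (math.isnan(f) or math.isinf(f)) else f
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every configured stage; write artifacts and ``report.json``.

    Any stage failure raises :class:`StageError` naming the stage and
    carrying the partial report of the stages that completed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(
        version=__version__, seed=config.seed, config=_sanitize(config.model_dump())
    )
    stage = "init"

    def tick(name):
        nonlocal stage
        stage = name
        log.info("stage %s", name)
        return time.time()

    try:
        # ------------------------------------------------------------------ data
        tick("simulate" if config.simulate else "load")
        if config.simulate is not None:
            sim_cfg = SimConfig(
                **{
                    **config.simulate.model_dump(),
                    "module_sizes": tuple(config.simulate.module_sizes),
                    "module_scopes": (
                        tuple(config.simulate.module_scopes)
                        if config.simulate.module_scopes
                        else None
                    ),
                },
                seed=config.seed,
            )
            adata = simulate_dataset(sim_cfg)
        else:
            if not config.input_dir or not Path(config.input_dir).exists():
                raise FileNotFoundError(f"input_dir {config.input_dir!r} does not exist")
            adata = read_expression(config.input_dir)
        if config.write_expression_artifacts:
            write_expression(adata, outdir / "expression")
        report.stages_completed.append(stage)

        tick("qc")
        params = QCParams(**config.qc.model_dump())
        adata, qc_report = apply_qc(adata, params)
        report.qc = qc_report.to_dict()
        report.stages_completed.append(stage)

        tick("normalize")
        adata = normalize_log(adata, config.normalize_total)
        report.stages_completed.append(stage)

        tick("de")
        degs = rank_sum_de(adata, config.de_group_a, config.de_group_b)
        degs.to_csv(outdir / "degs.tsv", sep="\t")
        report.de = {
            "n_genes": len(degs),
            "n_sig_raw_p05": int((degs["p_value"] < 0.05).sum()),
            "n_sig_adj_p05": int((degs["p_adjusted"] < 0.05).sum()),
        }
        report.stages_completed.append(stage)

        tick("select_nodes")
        nodes = select_nodes(degs, mode=config.node_mode, n=config.node_n)
        (outdir / "nodes.txt").write_text("\n".join(nodes.genes) + "\n")
        report.nodes = {"n_selected": nodes.n_selected, "rule": nodes.selection_rule}
        report.stages_completed.append(stage)

        tick("hypergraph")
        fits = {}
        hg_report: dict[str, dict] = {}
        for label, query in config.tissues.items():
            model = TranscriptomeHypergraph(
                adata, nodes, cells=query, method=config.correlation_method
            )
            fit = model.fit(k=config.cluster_k)
            fits[label] = fit
            write_hypergraph(
                fit.incidence,
                fit.clique,
                outdir / f"hypergraph_{label}",
                settings={
                    "cells": query,
                    "method": config.correlation_method,
                    "threshold_rule": "abs(r) > population SD of all entries",
                },
            )
            hg_report[label] = {
                "cells_query": query,
                "n_cells": int(np.asarray(adata.obs.eval(query)).sum()),
                "n_edges": len(fit.incidence.edges),
                "tau": fit.tau,
                "incidence_density": float(fit.incidence.B.mean()),
                "central_cluster_size": len(fit.central.members),
                "central_cluster_members": sorted(fit.central.members),
                "central_degenerate": fit.central.degenerate,
                "k": fit.central.k,
            }
        report.hypergraphs = hg_report
        report.stages_completed.append(stage)

        tick("venn")
        if len(fits) >= 2:
            labels = list(fits)[:3]
            venn = venn_compare({t: set(fits[t].central.members) for t in labels})
            report.venn = venn.to_dict()
        report.stages_completed.append(stage)

        tick("gwas")
        centrals = {t: f.central for t, f in fits.items()}
        if config.gwas_simulate is not None:
            preferred = sorted(
                set().union(*(set(c.members) for c in centrals.values())) & set(nodes.genes)
            )
            tables = simulate_gwas_tables(
                nodes.genes,
                n_variants=config.gwas_simulate.n_variants,
                n_overlap=config.gwas_simulate.n_overlap,
                seed=config.seed,
                preferred_genes=preferred,
                n_from_preferred=min(
                    config.gwas_simulate.n_from_preferred, len(preferred)
                ),
                rsids_per_gene=config.gwas_simulate.rsids_per_gene,
                n_background_rows=config.gwas_simulate.n_background_rows,
            )
            gwas_df, eqtl_df = tables.gwas_summary, tables.eqtl_map
            gwas_df.to_csv(outdir / "gwas_summary.tsv", sep="\t", index=False)
            eqtl_df.to_csv(outdir / "eqtl_map.tsv", sep="\t", index=False)
            planted = tables.planted_overlap
        else:
            gwas_df = read_gwas_summary(config.gwas_summary_path)
            eqtl_df = read_eqtl_map(config.gwas_eqtl_path)
            planted = None
        gwas_report = map_and_intersect(
            gwas_df,
            eqtl_df,
            nodes,
            clusters=centrals,
            n_lowest=config.n_lowest,
            tissue_exclude=tuple(config.tissue_exclude),
        )
        report.stages_completed.append(stage)

        tick("null")
        node_hits = sorted(gwas_report.table.index[gwas_report.table["in_nodes"]])
        z_tables = {}
        if node_hits and config.null_iterations:
            upper_to_gene = {g.upper(): g for g in nodes.genes}
            query_genes = [upper_to_gene[g] for g in node_hits if g in upper_to_gene]
            for label, fit in fits.items():
                z = null_z(
                    fit.clique,
                    genes=query_genes,
                    iterations=config.null_iterations,
                    seed=config.seed,
                    stream=label,
                )
                z_tables[label] = z
        report.null_model = {"iterations": config.null_iterations, "scheme": SCHEME}
        report.stages_completed.append(stage)

        tick("gwas_report")
        degrees = {t: f.degrees for t, f in fits.items()}
        gwas_report = rank_lookup(gwas_report, degrees, z_tables)
        gwas_report.table.to_csv(outdir / "gwas_genes.tsv", sep="\t")
        report.gwas = {
            **gwas_report.counts(),
            "planted_overlap": planted,
            "genes": _sanitize(
                gwas_report.table.reset_index().to_dict(orient="records")
            ),
        }
        report.stages_completed.append(stage)

        tick("velocity")
        if config.velocity is not None:
            specs = (
                tuple(
                    VelocityClusterSpec(c.name, c.mean_speed, c.angular_noise)
                    for c in config.velocity.clusters
                )
                if config.velocity.clusters
                else DEFAULT_VELOCITY_CLUSTERS
            )
            vel = simulate_velocity(
                config.velocity.n_cells_per_cluster, specs, seed=config.seed
            )
            metrics = compute_metrics(vel, k=config.velocity.k)
            summary = cluster_summary(metrics)
            summary.to_csv(outdir / "velocity_summary.tsv", sep="\t")
            report.velocity = {
                "k": config.velocity.k,
                "clusters": _sanitize(summary.reset_index().to_dict(orient="records")),
            }
        report.stages_completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        (outdir / "report.partial.json").write_text(report.to_json())
        raise StageError(stage, exc, report) from exc

    (outdir / "report.json").write_text(report.to_json())
    return report


def demo_config(output_dir, seed: int = 17, scale: str = "small") -> PipelineConfig:
    """Bundled demo configurations.

    ``small`` runs the full stage list in seconds (used by the test suite);
    ``full`` is the desk-scale analogue of the study conditions (2000 genes,
    top-600 node set, 1000 null iterations, lowest-10000 variant selection).
    """
    if scale == "small":
        return PipelineConfig(
            seed=seed,
            output_dir=str(output_dir),
            simulate=SimBlock(
                n_cells_per_group=120,
                n_genes=600,
                n_clusters=2,
                de_genes=60,
                de_log2fc=1.5,
                module_sizes=[60, 40],
                module_scopes=["both", "FT"],
                module_rho=0.7,
                hub_genes=2,
                dropout_rate=0.05,
            ),
            qc=QCBlock(min_genes_per_cell=20, min_cells_per_gene=3),
            node_n=150,
            tissues={
                "ft": "(tissue == 'FT') & (phase == 'secretory')",
                "glandular": "(tissue == 'endometrium') & (cluster == 'c0') & (phase == 'secretory')",
                "luminal": "(tissue == 'endometrium') & (cluster == 'c1') & (phase == 'secretory')",
            },
            null_iterations=200,
            gwas_simulate=GwasSimBlock(
                n_variants=4000, n_overlap=10, n_from_preferred=5, n_background_rows=300
            ),
            n_lowest=400,
            velocity=VelocityBlock(n_cells_per_cluster=60, k=15),
        )
    if scale == "full":
        return PipelineConfig(
            seed=seed,
            output_dir=str(output_dir),
            simulate=SimBlock(
                n_cells_per_group=600,
                n_genes=2000,
                n_clusters=2,
                de_genes=300,
                de_log2fc=1.5,
                module_sizes=[150, 80, 60],
                module_scopes=["both", "FT", "endometrium"],
                module_rho=0.7,
                hub_genes=3,
                dropout_rate=0.1,
            ),
            qc=QCBlock(min_genes_per_cell=50, min_cells_per_gene=3),
            node_n=600,
            null_iterations=1000,
            gwas_simulate=GwasSimBlock(
                n_variants=100_000, n_overlap=22, n_from_preferred=13
            ),
            n_lowest=10_000,
            velocity=VelocityBlock(n_cells_per_cluster=150, k=30),
        )
    raise ValueError(f"unknown demo scale {scale!r}")
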