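"""Synthetic single-cell data generator.

Emulates the statistical structure of an integrated two-tissue single-cell
atlas at desk scale: overdispersed (negative-binomial) counts with cluster
structure, planted differentially expressed genes between the two tissues,
planted co-expression modules driven by per-cell latent factors (with hub
genes loading on more than one factor), a mitochondrial gene block for QC,
independent dropout, plus companion generators for a low-dimensional
velocity field and for GWAS/eQTL tables with a planted node-gene overlap.

Everything is deterministic given the config seed; each stage draws from its
own named substream (see :mod:`txhyper._rng`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import stage_rng

__all__ = [
    "SimConfig",
    "SimConfigError",
    "VelocityClusterSpec",
    "VelocityDataset",
    "SyntheticGwasTables",
    "DEFAULT_VELOCITY_CLUSTERS",
    "simulate_dataset",
    "simulate_velocity",
    "simulate_gwas_tables",
]

TISSUES = ("FT", "endometrium")
PHASES = ("secretory", "proliferative")

# Residual SD of log-expression noise used to translate a target within-module
# correlation rho into a latent-factor loading: with log-mean perturbation
# alpha * f (f ~ N(0,1)) on top of residual noise of scale sigma, the shared
# fraction of variance is alpha^2 / (alpha^2 + sigma^2) = rho, hence
# alpha = sigma * sqrt(rho / (1 - rho)).  sigma is the empirical log-scale
# noise of the count model at the default mean/dispersion; count sampling and
# the log1p transform compress high targets, so realized correlations
# saturate below 1 as in real data.
_SIGMA_RESID = 1.6


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Conditions for :func:`simulate_dataset`.

    Defaults describe a desk-scale two-tissue atlas: a few hundred cells per
    tissue, ~2000 genes, a block of planted DE genes and a few correlated
    modules whose members partially overlap the DE set (so that module genes
    can reach the node set while the rest of the module remains on the edge
    side of the hypergraph).
    """

    n_cells_per_group: int = 300
    n_genes: int = 2000
    n_clusters: int = 3
    de_genes: int = 200
    de_log2fc: float = 1.5
    module_sizes: tuple[int, ...] = (120, 60)
    module_rho: float = 0.6
    hub_genes: int = 3
    nb_mean: float = 2.0
    nb_dispersion: float = 1.5
    dropout_rate: float = 0.1
    mito_fraction_range: tuple[float, float] = (0.01, 0.15)
    seed: int = 0
    # fraction of each module's genes that also receive the tissue DE shift
    module_de_fraction: float = 0.25
    # per-module activity scope: "both", "FT" or "endometrium"
    module_scopes: tuple[str, ...] | None = None
    n_mito_genes: int = 10
    secretory_fraction: float = 0.7

    def validate(self) -> None:
        if self.n_cells_per_group < 2:
            raise SimConfigError("n_cells_per_group must be >= 2")
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.n_clusters < 1:
            raise SimConfigError("n_clusters must be >= 1")
        if self.de_genes < 0:
            raise SimConfigError("de_genes must be >= 0")
        if any(s < 1 for s in self.module_sizes):
            raise SimConfigError("module_sizes entries must be >= 1")
        planted = self.de_genes + sum(self.module_sizes) + self.n_mito_genes
        if planted > self.n_genes:
            raise SimConfigError(
                "de_genes + sum(module_sizes) + n_mito_genes exceeds n_genes "
                f"({planted} > {self.n_genes})"
            )
        if not 0.0 <= self.module_rho < 1.0:
            raise SimConfigError("module_rho must be in [0, 1)")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise SimConfigError("dropout_rate must be in [0, 1]")
        if not 0.0 <= self.module_de_fraction <= 1.0:
            raise SimConfigError("module_de_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        if self.nb_mean <= 0:
            raise SimConfigError("nb_mean must be > 0")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise SimConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.hub_genes < 0 or (
            self.module_sizes and self.hub_genes > min(self.module_sizes)
        ):
            raise SimConfigError("hub_genes must be >= 0 and <= smallest module size")
        if self.module_scopes is not None:
            if len(self.module_scopes) != len(self.module_sizes):
                raise SimConfigError("module_scopes length must match module_sizes")
            bad = set(self.module_scopes) - {"both", *TISSUES}
            if bad:
                raise SimConfigError(f"module_scopes contains unknown scope {sorted(bad)}")
        if not 0.0 <= self.secretory_fraction <= 1.0:
            raise SimConfigError("secretory_fraction must be in [0, 1]")


def _module_loading(rho: float) -> float:
    if rho <= 0:
        return 0.0
    return _SIGMA_RESID * math.sqrt(rho / (1.0 - rho))


def simulate_dataset(config: SimConfig) -> ad.AnnData:
    """Draw a synthetic cell x gene count matrix as an :class:`~anndata.AnnData`.

    ``X`` holds raw integer counts (CSR); ``obs`` carries cell_id, tissue,
    cluster and phase; ``var_names`` are unique gene symbols with the
    mitochondrial block prefixed ``MT-``.  Planted ground truth (DE genes and
    their directions, module memberships, hub genes) is stored in
    ``uns["planted"]``.
    """
    config.validate()
    rng = stage_rng(config.seed, "expression")

    n_per = config.n_cells_per_group
    n_cells = 2 * n_per
    n_genes = config.n_genes
    n_mito = config.n_mito_genes
    n_mod = len(config.module_sizes)

    # --- gene layout: [mito | DE | modules... | background] -----------------
    gene_ids: list[str] = [f"MT-{i + 1:02d}" for i in range(n_mito)]
    gene_ids += [f"G{i + 1:05d}" for i in range(n_genes - n_mito)]
    pos = n_mito
    de_idx = np.arange(pos, pos + config.de_genes)
    pos += config.de_genes
    module_idx: list[np.ndarray] = []
    for size in config.module_sizes:
        module_idx.append(np.arange(pos, pos + size))
        pos += size
    nonmito = np.arange(n_mito, n_genes)

    # --- cell metadata ------------------------------------------------------
    tissue = np.repeat(TISSUES, n_per)
    cluster = np.array([f"c{i}" for i in rng.integers(0, config.n_clusters, n_cells)])
    phase = np.where(
        rng.random(n_cells) < config.secretory_fraction, PHASES[0], PHASES[1]
    )
    cell_ids = [f"{t}_{i:05d}" for i, t in enumerate(tissue)]

    # --- log-mean construction ---------------------------------------------
    base = math.log(config.nb_mean) + rng.normal(0.0, 0.7, n_genes)
    cluster_off = rng.normal(0.0, 0.2, (config.n_clusters, n_genes))
    cl_codes = np.array([int(c[1:]) for c in cluster])
    logmu = base[None, :] + cluster_off[cl_codes]

    ft_mask = tissue == "FT"
    shift = config.de_log2fc * math.log(2.0)
    de_sign = np.where(np.arange(config.de_genes) % 2 == 0, 1.0, -1.0)
    if config.de_genes:
        logmu[np.ix_(ft_mask, de_idx)] += de_sign[None, :] * shift

    scopes = config.module_scopes or ("both",) * n_mod
    alpha = _module_loading(config.module_rho)
    factors = rng.normal(0.0, 1.0, (n_cells, n_mod)) if n_mod else None
    module_de: list[np.ndarray] = []
    for m, idx in enumerate(module_idx):
        scope_mask = np.ones(n_cells) if scopes[m] == "both" else (tissue == scopes[m]).astype(float)
        f = factors[:, m] * scope_mask
        logmu[:, idx] += alpha * f[:, None] - alpha**2 / 2.0
        # hub genes additionally load on the next module's factor
        n_hub = min(config.hub_genes, len(idx))
        if n_hub and n_mod > 1:
            f2 = factors[:, (m + 1) % n_mod]
            logmu[:, idx[:n_hub]] += 0.6 * alpha * f2[:, None] - (0.6 * alpha) ** 2 / 2.0
        elif n_hub:
            logmu[:, idx[:n_hub]] += 0.6 * alpha * f[:, None] - (0.6 * alpha) ** 2 / 2.0
        # a slice of each module is also tissue-DE so it can reach the node set
        n_de = int(round(config.module_de_fraction * len(idx)))
        mod_de = idx[:n_de]
        if n_de:
            sgn = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
            logmu[np.ix_(ft_mask, mod_de)] += sgn[None, :] * shift
        module_de.append(mod_de)

    # --- mitochondrial block scaled to hit a per-cell target fraction ------
    if n_mito:
        frac = rng.uniform(*config.mito_fraction_range, n_cells)
        weights = rng.dirichlet(np.ones(n_mito))
        totals = np.exp(logmu[:, nonmito]).sum(axis=1)
        mu_mito = (frac / (1.0 - frac))[:, None] * totals[:, None] * weights[None, :]
        logmu[:, :n_mito] = np.log(np.clip(mu_mito, 1e-12, None))

    mu = np.exp(np.clip(logmu, -30.0, 12.0))
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int32)
    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0

    obs = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "tissue": pd.Categorical(tissue, categories=list(TISSUES)),
            "cluster": cluster,
            "phase": pd.Categorical(phase, categories=list(PHASES)),
        },
        index=cell_ids,
    )
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    genes_arr = np.asarray(gene_ids)
    adata.uns["planted"] = {
        "de_genes": genes_arr[de_idx].tolist(),
        "de_direction": {g: int(s) for g, s in zip(genes_arr[de_idx], de_sign)},
        "modules": [genes_arr[idx].tolist() for idx in module_idx],
        "module_de_genes": [genes_arr[idx].tolist() for idx in module_de],
        "module_scopes": list(scopes),
        "hub_genes": [
            genes_arr[idx[: min(config.hub_genes, len(idx))]].tolist()
            for idx in module_idx
        ],
    }
    adata.uns["sim_config"] = asdict(config)
    return adata


# --------------------------------------------------------------------------
# velocity field
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VelocityClusterSpec:
    """Planted kinetics for one cell population.

    ``angular_noise`` is the SD (radians) of the per-cell deviation from the
    cluster's base direction; ``math.inf`` plants isotropically random
    directions (the progenitor signature: fast but incoherent).
    """

    name: str
    mean_speed: float
    angular_noise: float

    @property
    def expected_coherence(self) -> float:
        # E[cos(theta_i - theta_j)] for independent N(0, s^2) deviations
        if math.isinf(self.angular_noise):
            return 0.0
        return math.exp(-self.angular_noise**2)


# Default conditions: a fast, direction-incoherent progenitor and
# slower, coherent differentiated/transition populations.
DEFAULT_VELOCITY_CLUSTERS: tuple[VelocityClusterSpec, ...] = (
    VelocityClusterSpec("progenitor", 12.47, math.inf),
    VelocityClusterSpec("mature_secretory", 2.0, 0.15),
    VelocityClusterSpec("mature_ciliated", 2.5, 0.15),
    VelocityClusterSpec("pre_ciliated", 5.0, 0.8),
)


@dataclass
class VelocityDataset:
    embedding: np.ndarray  # cells x d
    velocity: np.ndarray  # cells x d
    labels: np.ndarray  # cells, cluster names
    ground_truth: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.embedding.shape != self.velocity.shape:
            raise ValueError("embedding and velocity must have identical shapes")
        if self.embedding.ndim != 2 or self.embedding.shape[1] < 2:
            raise ValueError("embedding must be cells x d with d >= 2")


def simulate_velocity(
    n_cells_per_cluster: int,
    clusters: tuple[VelocityClusterSpec, ...] = DEFAULT_VELOCITY_CLUSTERS,
    seed: int = 0,
) -> VelocityDataset:
    """Plant a 2-d embedding with per-cluster velocity kinetics.

    Each cluster sits on a Gaussian blob; its cells share a base direction
    perturbed by ``angular_noise`` (isotropic when infinite), and per-cell
    speeds are log-normal around the planted mean speed.
    """
    if len(clusters) < 2:
        raise ValueError("at least 2 clusters are required")
    if n_cells_per_cluster < 1:
        raise ValueError("n_cells_per_cluster must be >= 1")
    rng = stage_rng(seed, "velocity")

    emb, vel, labels = [], [], []
    speed_sd = 0.2
    for i, spec in enumerate(clusters):
        angle0 = 2.0 * math.pi * i / len(clusters)
        centre = 8.0 * np.array([math.cos(angle0), math.sin(angle0)])
        emb.append(centre + rng.normal(0.0, 1.0, (n_cells_per_cluster, 2)))
        base = rng.uniform(0.0, 2.0 * math.pi)
        if math.isinf(spec.angular_noise):
            theta = rng.uniform(0.0, 2.0 * math.pi, n_cells_per_cluster)
        else:
            theta = base + rng.normal(0.0, spec.angular_noise, n_cells_per_cluster)
        speed = spec.mean_speed * np.exp(
            rng.normal(-(speed_sd**2) / 2.0, speed_sd, n_cells_per_cluster)
        )
        vel.append(speed[:, None] * np.column_stack([np.cos(theta), np.sin(theta)]))
        labels += [spec.name] * n_cells_per_cluster

    truth = {
        s.name: {"mean_speed": s.mean_speed, "coherence": s.expected_coherence}
        for s in clusters
    }
    return VelocityDataset(
        embedding=np.vstack(emb),
        velocity=np.vstack(vel),
        labels=np.asarray(labels),
        ground_truth=truth,
    )


# --------------------------------------------------------------------------
# GWAS + eQTL tables
# --------------------------------------------------------------------------


@dataclass
class SyntheticGwasTables:
    gwas_summary: pd.DataFrame  # columns rsid, p_value
    eqtl_map: pd.DataFrame  # columns rsid, gene, tissue
    planted_overlap: list[str]  # node genes guaranteed to be recoverable


def simulate_gwas_tables(
    node_genes: list[str],
    n_variants: int = 10_000,
    n_overlap: int = 22,
    seed: int = 0,
    *,
    preferred_genes: list[str] | None = None,
    n_from_preferred: int = 0,
    eqtl_tissues: tuple[str, ...] = ("FT", "uterus", "ovary", "breast"),
    excluded_tissue: str = "nervous_system",
    rsids_per_gene: tuple[int, int] = (10, 110),
    n_background_rows: int = 1000,
    n_novel_genes: int = 200,
    support_quantile: float = 0.1,
) -> SyntheticGwasTables:
    """Draw GWAS summary statistics and an offline variant->gene eQTL table.

    Exactly ``n_overlap`` eQTL genes come from ``node_genes`` (optionally
    ``n_from_preferred`` of them from ``preferred_genes``, e.g. a central
    cluster); all other eQTL genes are novel symbols, so downstream node
    intersection recovers the planted overlap exactly.  Supporting rsIDs for
    planted genes are drawn from the lowest ``support_quantile`` fraction of
    p-values, so they survive a lowest-``n`` variant selection whenever
    ``n_lowest >= support_quantile * n_variants``.  p-values are uniform on a
    log scale over (1e-8, 1].
    """
    node_genes = list(node_genes)
    if n_overlap > len(node_genes):
        raise ValueError(
            f"n_overlap ({n_overlap}) exceeds node gene count ({len(node_genes)})"
        )
    if n_from_preferred > n_overlap:
        raise ValueError("n_from_preferred cannot exceed n_overlap")
    rng = stage_rng(seed, "gwas")

    rs_numbers = rng.choice(900_000_000, size=n_variants, replace=False) + 10_000_000
    rsids = np.array([f"rs{n}" for n in rs_numbers])
    p_values = 10.0 ** (-rng.uniform(0.0, 8.0, n_variants))
    gwas = pd.DataFrame({"rsid": rsids, "p_value": p_values})

    # overlap gene choice (pools sorted for determinism under set inputs)
    chosen: list[str] = []
    if n_from_preferred:
        if not preferred_genes:
            raise ValueError("n_from_preferred > 0 requires preferred_genes")
        pool = sorted(set(preferred_genes) & set(node_genes))
        if len(pool) < n_from_preferred:
            raise ValueError(
                f"only {len(pool)} preferred genes are node genes; "
                f"{n_from_preferred} requested"
            )
        chosen += list(rng.choice(pool, size=n_from_preferred, replace=False))
    rest_pool = sorted(set(node_genes) - set(chosen))
    chosen += list(rng.choice(rest_pool, size=n_overlap - len(chosen), replace=False))

    order = np.argsort(p_values, kind="stable")
    n_low = max(1, int(support_quantile * n_variants))
    low_rsids = rsids[order[:n_low]]
    high_rsids = rsids[order[n_low:]] if n_low < n_variants else rsids

    rows: list[tuple[str, str, str]] = []
    lo, hi = rsids_per_gene
    for gene in chosen:
        k = int(rng.integers(lo, hi + 1))
        support = rng.choice(low_rsids, size=min(k, len(low_rsids)), replace=False)
        for rs in support:
            rows.append((rs, gene, str(rng.choice(eqtl_tissues))))

    novel = [f"NOVEL{i + 1:04d}" for i in range(n_novel_genes)]
    bg_tissues = (*eqtl_tissues, excluded_tissue)
    for _ in range(n_background_rows):
        rs = str(rng.choice(high_rsids))
        rows.append((rs, str(rng.choice(novel)), str(rng.choice(bg_tissues))))

    eqtl = (
        pd.DataFrame(rows, columns=["rsid", "gene", "tissue"])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return SyntheticGwasTables(
        gwas_summary=gwas, eqtl_map=eqtl, planted_overlap=sorted(chosen)
    )
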