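"""Cell/gene quality control and library-size normalization.

QC thresholds default to the standard single-cell filters used for the
two-tissue atlas: cells with fewer than 200 expressed genes, more than
850 000 total counts, more than 30% mitochondrial counts, or more than 8000
expressed genes are removed, then genes expressed in fewer than 3 surviving
cells are dropped.  Removal is by union of the rules; report attribution
assigns each removed cell to the first failing rule in a fixed order
(min_genes, max_genes, max_counts, mito) so that reports are deterministic
and no cell is double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = ["QCParams", "QCReport", "QCError", "apply_qc", "normalize_log"]


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCParams:
    """Thresholds; set a field to ``None`` to disable that rule."""

    min_genes_per_cell: int | None = 200
    min_cells_per_gene: int | None = 3
    max_total_counts: int | None = 850_000
    max_mito_fraction: float | None = 0.30
    max_genes_per_cell: int | None = 8000
    mito_prefix: str = "MT-"

    def validate(self) -> None:
        for name in (
            "min_genes_per_cell",
            "min_cells_per_gene",
            "max_total_counts",
            "max_genes_per_cell",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise QCError(f"{name} must be >= 0")
        if self.max_mito_fraction is not None and not 0.0 <= self.max_mito_fraction <= 1.0:
            raise QCError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    cells_removed_by_rule: dict[str, int] = field(default_factory=dict)
    genes_removed: int = 0

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "cells_removed_by_rule": dict(self.cells_removed_by_rule),
            "genes_removed": self.genes_removed,
        }


# fixed attribution order for the report (removal itself is by union)
_RULE_ORDER = ("min_genes", "max_genes", "max_counts", "mito")


def _cell_stats(adata: ad.AnnData, mito_prefix: str):
    X = adata.X
    if sp.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        n_genes = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    if mito_mask.any():
        sub = X[:, np.asarray(mito_mask)]
        mito = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito = np.zeros(adata.n_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return n_genes, totals, mito_frac


def apply_qc(adata: ad.AnnData, params: QCParams = QCParams()) -> tuple[ad.AnnData, QCReport]:
    """Filter cells then genes; returns the filtered copy and an itemized report."""
    params.validate()
    if "normalized" in adata.layers:
        raise QCError("apply_qc expects the raw count layer; run QC before normalization")

    n_genes, totals, mito_frac = _cell_stats(adata, params.mito_prefix)
    fails = {
        "min_genes": (
            n_genes < params.min_genes_per_cell
            if params.min_genes_per_cell is not None
            else np.zeros(adata.n_obs, bool)
        ),
        "max_genes": (
            n_genes > params.max_genes_per_cell
            if params.max_genes_per_cell is not None
            else np.zeros(adata.n_obs, bool)
        ),
        "max_counts": (
            totals > params.max_total_counts
            if params.max_total_counts is not None
            else np.zeros(adata.n_obs, bool)
        ),
        "mito": (
            mito_frac > params.max_mito_fraction
            if params.max_mito_fraction is not None
            else np.zeros(adata.n_obs, bool)
        ),
    }
    removed = np.zeros(adata.n_obs, bool)
    attributed = np.zeros(adata.n_obs, bool)
    by_rule: dict[str, int] = {}
    for rule in _RULE_ORDER:
        newly = fails[rule] & ~attributed
        by_rule[rule] = int(newly.sum())
        attributed |= fails[rule]
        removed |= fails[rule]

    keep_cells = ~removed
    if not keep_cells.any():
        raise QCError("all cells removed by QC filters")

    sub = adata[keep_cells]
    X = sub.X
    expressed = (
        np.asarray((X > 0).sum(axis=0)).ravel() if sp.issparse(X) else (X > 0).sum(axis=0)
    )
    if params.min_cells_per_gene is not None:
        keep_genes = expressed >= params.min_cells_per_gene
    else:
        keep_genes = np.ones(adata.n_vars, bool)

    out = sub[:, keep_genes].copy()
    report = QCReport(
        cells_in=adata.n_obs,
        cells_out=int(keep_cells.sum()),
        genes_in=adata.n_vars,
        genes_out=int(keep_genes.sum()),
        cells_removed_by_rule=by_rule,
        genes_removed=int((~keep_genes).sum()),
    )
    return out, report


def normalize_log(adata: ad.AnnData, scale_total: int = 10_000) -> ad.AnnData:
    """Scale each cell to ``scale_total`` counts, then log1p.

    The result is stored as ``layers["normalized"]``; the raw counts in ``X``
    are retained.  Normalizing twice is rejected.
    """
    if scale_total <= 0:
        raise QCError("scale_total must be > 0")
    if "normalized" in adata.layers:
        raise QCError("dataset already has a normalized layer")
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        n0 = int((totals == 0).sum())
        raise QCError(
            f"{n0} cell(s) have zero total counts; apply QC before normalizing"
        )
    scale = scale_total / totals
    if sp.issparse(X):
        norm = sp.csr_matrix(X, dtype=np.float64).multiply(scale[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(X * scale[:, None])
    adata.layers["normalized"] = norm
    return adata
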