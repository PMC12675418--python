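"""Wilcoxon rank-sum differential expression and node-gene selection.

The two-sided Mann-Whitney/Wilcoxon rank-sum test is computed per gene on
the normalized layer.  For small tie-free samples (min group size <= 8) the
exact null distribution of U is used; otherwise the tie-corrected,
continuity-corrected normal approximation.  P-values are Benjamini-Hochberg
adjusted across genes.

Node selection offers the fixed-size rule (the top-n smallest-p genes) and
the knee rule that motivates a particular n: on the descending ranked
-log10(p) curve, cut at the rank with the largest vertical drop below the
chord joining the first and last points.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DEError", "NodeSet", "rank_sum_de", "select_nodes"]

_EXACT_MAX_N = 8


class DEError(ValueError):
    pass


@dataclass
class NodeSet:
    genes: list[str]
    selection_rule: str  # "fixed_n" or "inflection"
    n_selected: int

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DEError("node genes must be unique")
        if self.n_selected != len(self.genes):
            raise DEError("n_selected must equal the number of genes")


def _resolve_mask(adata: ad.AnnData, selector) -> np.ndarray:
    if isinstance(selector, str):
        mask = adata.obs.eval(selector)
    else:
        mask = selector
    mask = np.asarray(mask)
    if mask.dtype != bool or mask.shape != (adata.n_obs,):
        raise DEError("cell selector must resolve to a boolean mask over cells")
    return mask


def _exact_p_from_samples(a: np.ndarray, b: np.ndarray) -> float:
    # exact null distribution of U (tie-free small samples)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return float(res.pvalue)


def rank_sum_de(adata: ad.AnnData, group_a, group_b) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of group A vs group B.

    Returns a DataFrame indexed by gene with columns ``U`` (statistic for
    group A), ``z`` (tie/continuity-corrected normal deviate), ``p_value``,
    ``p_adjusted`` (BH), ``direction`` (sign of mean(A) - mean(B) on the
    normalized layer) and ``neg_log10_p``, sorted by ascending p (ties broken
    by gene symbol).
    """
    if "normalized" not in adata.layers:
        raise DEError("normalized layer required; run normalize_log first")
    mask_a = _resolve_mask(adata, group_a)
    mask_b = _resolve_mask(adata, group_b)
    if (mask_a & mask_b).any():
        raise DEError("groups overlap")
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < 2 or nb < 2:
        raise DEError("each group needs at least 2 cells")

    layer = adata.layers["normalized"]
    dense = layer.toarray() if sp.issparse(layer) else np.asarray(layer)
    xa = dense[mask_a]
    xb = dense[mask_b]
    n = na + nb
    combined = np.vstack([xa, xb])
    ranks = stats.rankdata(combined, axis=0)
    r_a = ranks[:na].sum(axis=0)
    u = r_a - na * (na + 1) / 2.0

    # tie correction per gene
    tie_term = np.empty(dense.shape[1])
    for j in range(dense.shape[1]):
        _, counts = np.unique(combined[:, j], return_counts=True)
        tie_term[j] = float((counts.astype(float) ** 3 - counts).sum())
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    mu = na * nb / 2.0
    diff = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (diff - 0.5 * np.sign(diff)) / np.where(sigma > 0, sigma, 1.0), 0.0)
    z = np.where(diff == 0, 0.0, z)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    if min(na, nb) <= _EXACT_MAX_N:
        for j in np.nonzero(tie_term == 0)[0]:
            p[j] = _exact_p_from_samples(xa[:, j], xb[:, j])

    p_adj = multipletests(p, method="fdr_bh")[1]
    p_adj = np.maximum(p_adj, p)
    direction = np.sign(xa.mean(axis=0) - xb.mean(axis=0)).astype(int)

    table = pd.DataFrame(
        {
            "U": u,
            "z": z,
            "p_value": p,
            "p_adjusted": p_adj,
            "direction": direction,
            "neg_log10_p": -np.log10(p),
        },
        index=pd.Index(adata.var_names, name="gene"),
    )
    table = table.sort_values(["p_value", "gene"], kind="stable")
    return table


def select_nodes(deg: pd.DataFrame, mode: str = "fixed_n", n: int = 600) -> NodeSet:
    """Select the hypergraph node genes from a DE table.

    ``fixed_n`` takes the ``n`` smallest-p genes (clamped to table size);
    ``inflection`` cuts the descending ranked -log10(p) curve at the point of
    maximal vertical deviation below the first-to-last chord.
    """
    if deg.empty:
        raise DEError("DE table is empty")
    ordered = deg.sort_values(["p_value", "gene"], kind="stable")
    if mode == "fixed_n":
        if n <= 0:
            raise DEError("n must be > 0")
        genes = list(ordered.index[: min(n, len(ordered))])
        return NodeSet(genes=genes, selection_rule="fixed_n", n_selected=len(genes))
    if mode == "inflection":
        y = ordered["neg_log10_p"].to_numpy(dtype=float)
        m = len(y)
        if m == 1:
            return NodeSet(genes=list(ordered.index), selection_rule="inflection", n_selected=1)
        ranks = np.arange(1, m + 1, dtype=float)
        chord = y[0] + (y[-1] - y[0]) * (ranks - 1.0) / (m - 1.0)
        deviation = chord - y
        cut = int(np.argmax(deviation)) + 1
        genes = list(ordered.index[:cut])
        return NodeSet(genes=genes, selection_rule="inflection", n_selected=cut)
    raise DEError(f"unknown selection mode {mode!r}")
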