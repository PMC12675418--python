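"""Default renderings: clique-reduction heatmap and ranked p-value knee."""

from __future__ import annotations

import numpy as np

from .hypergraph import CliqueReduction

__all__ = ["plot_clique_heatmap", "plot_rank_curve"]


def _ordered(M: np.ndarray) -> np.ndarray:
    from scipy.cluster.hierarchy import leaves_list, linkage

    order = leaves_list(linkage(M.astype(float), method="ward"))
    return M[np.ix_(order, order)]


def plot_clique_heatmap(clique: CliqueReduction, path=None, order: bool = True):
    """Heatmap of shared-hyperedge counts, rows/cols in dendrogram order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = _ordered(clique.M) if order and len(clique.nodes) > 2 else clique.M
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="shared hyperedges")
    ax.set_xlabel("node genes")
    ax.set_ylabel("node genes")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_rank_curve(deg_table, node_set=None, path=None):
    """Descending ranked -log10(p) with the selection cut marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = deg_table.sort_values(["p_value", "gene"], kind="stable")["neg_log10_p"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(y) + 1), y, lw=1)
    if node_set is not None:
        ax.axvline(node_set.n_selected, color="crimson", ls="--", label=f"n={node_set.n_selected}")
        ax.legend()
    ax.set_xlabel("gene rank")
    ax.set_ylabel(r"$-\log_{10} p$")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
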