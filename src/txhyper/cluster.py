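"""Central-cluster detection and cross-tissue Venn comparison.

The central cluster is the hierarchically clustered block of node genes
with the highest connectivity: Ward linkage on the rows of the
clique-reduction matrix (Euclidean distance), tree cut into k clusters, and
the cluster with the highest mean off-diagonal row sum returned.  When all
clusters tie (e.g. a constant matrix) the largest cluster is returned with
a degenerate flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .hypergraph import CliqueReduction, HypergraphError

__all__ = ["CentralCluster", "VennSummary", "find_central_cluster", "venn_compare"]


@dataclass
class CentralCluster:
    members: list[str]
    linkage: str
    k: int
    mean_member_rowsum: float
    mean_nonmember_rowsum: float
    degenerate: bool = False
    labels: np.ndarray | None = None  # per-node cluster label, node order

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


def find_central_cluster(clique: CliqueReduction, k: int | str = 2) -> CentralCluster:
    """Ward-cluster the clique-reduction rows and return the densest cluster.

    ``k="auto"`` picks k in 2..6 maximizing the silhouette score on the rows.
    """
    n = len(clique.nodes)
    if n < 2:
        raise HypergraphError("need at least 2 nodes to cluster")
    rows = clique.M.astype(float)
    with warnings.catch_warnings():
        # rows of the symmetric hollow M are observations here, not distances
        warnings.filterwarnings("ignore", message=".*uncondensed distance matrix.*")
        Z = linkage(rows, method="ward")

    if k == "auto":
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            lab = fcluster(Z, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(rows, lab, metric="euclidean")
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        k = best_k
    k = int(k)
    if k > n:
        raise HypergraphError(f"k ({k}) exceeds number of nodes ({n})")
    labels = fcluster(Z, k, criterion="maxclust")

    rowsums = clique.offdiag_rowsums().astype(float)
    uniq = np.unique(labels)
    means = np.array([rowsums[labels == u].mean() for u in uniq])
    sizes = np.array([(labels == u).sum() for u in uniq])

    if np.allclose(means, means[0]):
        # every cut has the same mean connectivity: fail soft, flag it
        chosen = uniq[int(np.argmax(sizes))]
        degenerate = True
    else:
        chosen = uniq[int(np.argmax(means))]
        degenerate = False

    member_mask = labels == chosen
    nodes = np.asarray(clique.nodes)
    mean_in = float(rowsums[member_mask].mean())
    mean_out = float(rowsums[~member_mask].mean()) if (~member_mask).any() else mean_in
    return CentralCluster(
        members=nodes[member_mask].tolist(),
        linkage="ward",
        k=k,
        mean_member_rowsum=mean_in,
        mean_nonmember_rowsum=mean_out,
        degenerate=degenerate,
        labels=labels,
    )


@dataclass
class VennSummary:
    labels: list[str]
    set_sizes: dict[str, int]
    regions: dict[str, int]  # keyed by "+"-joined member labels
    union_size: int
    shared_all: int
    shared_all_pct: float
    unique_counts: dict[str, int]
    unique_pcts: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "set_sizes": dict(self.set_sizes),
            "regions": dict(self.regions),
            "union_size": self.union_size,
            "shared_all": self.shared_all,
            "shared_all_pct": self.shared_all_pct,
            "unique_counts": dict(self.unique_counts),
            "unique_pcts": dict(self.unique_pcts),
        }


def venn_compare(sets: dict[str, set]) -> VennSummary:
    """Exact region sizes and union percentages for 2 or 3 labelled sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if len(sets) > 3:
        raise ValueError("at most 3 sets are supported")
    sets = {label: set(s) for label, s in sets.items()}
    for label, s in sets.items():
        if not s:
            raise ValueError(f"set {label!r} is empty")
    labels = list(sets)
    union = set().union(*sets.values())
    n_union = len(union)

    regions: dict[str, int] = {}
    for element_pattern in _patterns(labels):
        inside = [label for label, flag in zip(labels, element_pattern) if flag]
        outside = [label for label, flag in zip(labels, element_pattern) if not flag]
        if not inside:
            continue
        region = set.intersection(*(sets[t] for t in inside))
        for t in outside:
            region -= sets[t]
        regions["+".join(inside)] = len(region)

    shared = len(set.intersection(*sets.values()))
    pct = lambda c: round(100.0 * c / n_union, 1)
    uniques = {t: regions[t] for t in labels}
    return VennSummary(
        labels=labels,
        set_sizes={t: len(s) for t, s in sets.items()},
        regions=regions,
        union_size=n_union,
        shared_all=shared,
        shared_all_pct=pct(shared),
        unique_counts=uniques,
        unique_pcts={t: pct(c) for t, c in uniques.items()},
    )


def _patterns(labels):
    m = len(labels)
    for bits in range(1, 2**m):
        yield [bool(bits >> i & 1) for i in range(m)]
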