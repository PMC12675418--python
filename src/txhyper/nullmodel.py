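"""Randomized-network null for clique-reduction connectivity.

The null preserves the global weight distribution while destroying node
identity: the multiset of strictly-upper-triangle entries of the
clique-reduction matrix is uniformly permuted and mirrored to the lower
triangle; the diagonal (per-node incidence degree) is held fixed since row
sums are defined off-diagonal.  Per-gene Z-scores compare the observed
off-diagonal row sum with the empirical mean/SD over iterations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .hypergraph import CliqueReduction, HypergraphError

__all__ = ["randomize_clique", "null_z", "SCHEME"]

SCHEME = "upper-triangle-entry-shuffle"


def randomize_clique(clique: CliqueReduction, rng: np.random.Generator) -> CliqueReduction:
    """One uniformly permuted copy of the clique reduction (diagonal fixed)."""
    M = clique.M
    if not np.array_equal(M, M.T):
        raise HypergraphError("clique reduction matrix must be symmetric")
    n = M.shape[0]
    iu = np.triu_indices(n, 1)
    out = np.diag(np.diag(M)).astype(M.dtype)
    perm = rng.permutation(M[iu])
    out[iu] = perm
    out.T[iu] = perm
    return CliqueReduction(M=out, nodes=list(clique.nodes))


def _null_rowsums(M: np.ndarray, iterations: int, rng: np.random.Generator) -> np.ndarray:
    """(iterations x n) off-diagonal row sums under entry shuffling."""
    n = M.shape[0]
    rows, cols = np.triu_indices(n, 1)
    vals = M[rows, cols].astype(float)
    out = np.empty((iterations, n))
    for t in range(iterations):
        p = rng.permutation(vals)
        out[t] = np.bincount(rows, weights=p, minlength=n) + np.bincount(
            cols, weights=p, minlength=n
        )
    return out


def null_z(
    clique: CliqueReduction,
    genes: list[str] | None = None,
    iterations: int = 1000,
    seed: int = 0,
    stream: str = "",
) -> pd.DataFrame:
    """Empirical null mean/SD and Z for each queried gene's row sum.

    Returns a DataFrame indexed by gene with columns ``observed``,
    ``null_mean``, ``null_sd``, ``z`` and ``undefined`` (True where the null
    SD is zero, in which case ``z`` is NaN).  Deterministic per seed;
    ``stream`` names an independent substream (e.g. a tissue label) so that
    several nulls can be drawn from one global seed.
    """
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    M = clique.M
    if not np.array_equal(M, M.T):
        raise HypergraphError("clique reduction matrix must be symmetric")
    node_index = {g: i for i, g in enumerate(clique.nodes)}
    if genes is None:
        genes = list(clique.nodes)
    missing = [g for g in genes if g not in node_index]
    if missing:
        raise HypergraphError(f"queried gene(s) not in node set: {missing[:5]}")

    rng = stage_rng(seed, f"null_model:{stream}" if stream else "null_model")
    null = _null_rowsums(M, iterations, rng)
    observed = clique.offdiag_rowsums().astype(float)

    idx = np.array([node_index[g] for g in genes])
    mean = null[:, idx].mean(axis=0)
    sd = null[:, idx].std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(undefined, np.nan, (observed[idx] - mean) / np.where(undefined, 1.0, sd))

    table = pd.DataFrame(
        {
            "observed": observed[idx],
            "null_mean": mean,
            "null_sd": sd,
            "z": z,
            "undefined": undefined,
        },
        index=pd.Index(genes, name="gene"),
    )
    table.attrs.update({"iterations": iterations, "seed": seed, "scheme": SCHEME})
    return table
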