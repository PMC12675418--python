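"""Per-cell velocity magnitude and confidence summaries.

Velocity vectors are an input (from any estimator or the simulator).
Magnitude is the Euclidean norm of a cell's velocity vector ("differentiation
speed"); confidence is the mean cosine similarity between the cell's velocity
and those of its k nearest neighbours in the embedding (agreement with the
local flow).  A fast, low-confidence population is the progenitor signature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .simulate import VelocityDataset

__all__ = ["compute_metrics", "cluster_summary"]


def compute_metrics(vel: VelocityDataset, k: int = 30) -> pd.DataFrame:
    """Per-cell magnitude and k-NN cosine confidence.

    Neighbours are the k nearest cells by Euclidean distance in the embedding
    (self excluded); cells with a zero velocity vector get confidence 0 and
    are flagged.  Returns a DataFrame with columns ``magnitude``,
    ``confidence``, ``cluster``, ``zero_velocity``.
    """
    n = vel.embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be > 0")
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of cells ({n})")

    v = np.asarray(vel.velocity, dtype=float)
    mag = np.linalg.norm(v, axis=1)
    zero = mag == 0
    unit = np.zeros_like(v)
    unit[~zero] = v[~zero] / mag[~zero, None]

    nn = NearestNeighbors(n_neighbors=k + 1).fit(vel.embedding)
    _, idx = nn.kneighbors(vel.embedding)
    # drop self wherever it appears in the neighbour list (always nearest at
    # distance 0 barring exact duplicates)
    neigh = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        if len(row) < k:  # exact-duplicate corner: self not in list
            row = idx[i][:k]
        neigh[i] = row

    cos = np.einsum("ij,ikj->ik", unit, unit[neigh])
    confidence = np.where(zero, 0.0, cos.mean(axis=1))

    return pd.DataFrame(
        {
            "magnitude": mag,
            "confidence": confidence,
            "cluster": vel.labels,
            "zero_velocity": zero,
        }
    )


def cluster_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean magnitude/confidence and cell count per cluster."""
    if metrics["cluster"].isna().any():
        raise ValueError("every cell must carry a cluster label")
    out = (
        metrics.groupby("cluster", observed=True)
        .agg(
            n_cells=("magnitude", "size"),
            mean_magnitude=("magnitude", "mean"),
            mean_confidence=("confidence", "mean"),
        )
        .sort_index()
    )
    return out
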