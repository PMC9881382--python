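"""k-nearest-neighbour imputation of missing abundance values (k = 3 by
default, the validation-stage setting)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["knn_impute"]


def knn_impute(table: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Impute each missing cell with the mean of its column over the k
    nearest rows.

    Distances are Euclidean over the mutually observed columns after
    z-scoring each column on its observed values; only rows with the target
    column observed are neighbour candidates.  Observed cells are returned
    untouched.

    Raises ``ValueError`` for an all-missing row, an all-missing column, or
    a column with fewer than ``k`` observed rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    obs = np.isfinite(X)
    if not obs.any(axis=1).all():
        bad = table.index[~obs.any(axis=1)][0]
        raise ValueError(f"row {bad!r} has no observed values")
    col_counts = obs.sum(axis=0)
    if (col_counts < k).any():
        bad = table.columns[col_counts < k][0]
        raise ValueError(f"column {bad!r} has fewer than {k} observed values")
    if np.isinf(X).any():
        raise ValueError("non-finite abundance value encountered")
    if obs.all():
        return table.copy()

    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd

    out = X.copy()
    for i in range(n):
        miss_cols = np.flatnonzero(~obs[i])
        if miss_cols.size == 0:
            continue
        # squared distance to every other row over shared observed columns
        shared = obs[i][None, :] & obs  # (n, p)
        diff2 = np.where(shared, (Z[i][None, :] - np.where(obs, Z, 0.0)) ** 2, 0.0)
        dist2 = diff2.sum(axis=1)
        n_shared = shared.sum(axis=1)
        for c in miss_cols:
            cand = np.flatnonzero(obs[:, c] & (n_shared > 0))
            cand = cand[cand != i]
            if cand.size == 0:
                raise ValueError(f"no neighbour shares observed columns for row {i}")
            kk = min(k, cand.size)
            nearest = cand[np.argsort(dist2[cand], kind="stable")[:kk]]
            out[i, c] = X[nearest, c].mean()
    return pd.DataFrame(out, index=table.index, columns=table.columns)
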