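"""Distance-weighted k-nearest-neighbour imputation.

Default orientation treats metabolites (rows) as the items among which
neighbours are found, matching the row-wise expression-matrix tool the
emulated study used; ``knn_orientation="subjects"`` transposes the search
so neighbours are subjects instead.  Distance between two items is the
root-mean-square difference over their mutually observed coordinates (a
per-coordinate normalisation, so pairs with different overlap sizes are
comparable).  A missing cell is filled with the inverse-distance-weighted
mean of the k nearest items observed at that coordinate; exact
zero-distance neighbours are copied (averaged if tied).  Items missing more
than ``knn_max_missing_frac`` of their coordinates — and cells with no
usable neighbour — fall back to the coordinate's observed mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ImputerSettings


def impute_knn(matrix: pd.DataFrame, settings: ImputerSettings | None = None) -> pd.DataFrame:
    settings = settings or ImputerSettings()
    x = matrix.to_numpy(dtype=float, copy=True)
    if settings.knn_orientation == "subjects":
        imputed = _knn_rows(x.T, settings)
        out = imputed.T
    else:
        out = _knn_rows(x, settings)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _knn_rows(x: np.ndarray, settings: ImputerSettings) -> np.ndarray:
    """Impute treating rows as items and columns as coordinates."""
    m, n = x.shape
    out = x.copy()
    missing = np.isnan(x)
    if not missing.any():
        return out
    observed = ~missing
    if missing.all(axis=0).any():
        raise ValueError("a coordinate with no observed values cannot anchor imputation")
    col_means = np.nanmean(x, axis=0)

    # Items past the missingness cap skip the neighbour search entirely.
    frac_missing = missing.mean(axis=1)
    capped = frac_missing > settings.knn_max_missing_frac
    for i in np.flatnonzero(capped):
        out[i, missing[i]] = col_means[missing[i]]

    x0 = np.where(observed, x, 0.0)
    obs_f = observed.astype(float)

    for i in np.flatnonzero(missing.any(axis=1) & ~capped):
        shared = obs_f @ obs_f[i]  # mutually observed coordinate counts
        diff_sq = (x0 - x0[i]) ** 2 * (obs_f * obs_f[i])
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(diff_sq.sum(axis=1) / shared)
        dist[i] = np.nan  # never self
        for j in np.flatnonzero(missing[i]):
            cand = observed[:, j] & ~np.isnan(dist)
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                out[i, j] = col_means[j]
                continue
            k = min(settings.knn_k, idx.size)
            nearest = idx[np.argsort(dist[idx], kind="stable")[:k]]
            d = dist[nearest]
            if (d == 0).any():
                out[i, j] = x[nearest[d == 0], j].mean()
            else:
                w = 1.0 / d
                out[i, j] = float(np.dot(w, x[nearest, j]) / w.sum())
    return out
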