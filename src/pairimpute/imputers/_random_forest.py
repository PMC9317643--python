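"""Iterative random-forest imputation (missForest-style).

Variables are metabolites, observations are subjects (the input
metabolite x subject matrix is transposed internally).  Missing entries are
initialised with per-variable means; then, sweeping variables in ascending
order of missingness, each variable with missing values is regressed on all
others with a random forest trained on the subjects where it is observed,
and its missing entries are replaced by forest predictions.  Sweeps repeat
until the normalised change

    delta = sum((X_new - X_old)^2) / sum(X_new^2)

first increases — the returned matrix is the one from the sweep *before*
the increase — or until ``rf_max_iter`` sweeps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import ImputerSettings


def impute_random_forest(
    matrix: pd.DataFrame, settings: ImputerSettings | None = None
) -> pd.DataFrame:
    settings = settings or ImputerSettings()
    x = matrix.to_numpy(dtype=float).T  # subjects x variables
    n, p = x.shape
    if p < 2:
        raise ValueError("random-forest imputation needs at least 2 variables")
    miss = np.isnan(x)
    if not miss.any():
        return matrix.copy()
    if miss.all(axis=0).any():
        raise ValueError("every variable needs at least one observed value")

    cur = x.copy()
    col_mean = np.nanmean(x, axis=0)
    cur[miss] = np.broadcast_to(col_mean, x.shape)[miss]

    targets = np.flatnonzero(miss.any(axis=0))
    targets = targets[np.argsort(miss[:, targets].sum(axis=0), kind="stable")]
    seeds = np.random.SeedSequence(settings.seed).generate_state(
        settings.rf_max_iter * targets.size
    ) % (2**31)

    prev_delta = np.inf
    k = 0
    for _ in range(settings.rf_max_iter):
        before = cur.copy()
        for v in targets:
            rows = ~miss[:, v]
            other = np.delete(np.arange(p), v)
            rf = RandomForestRegressor(
                n_estimators=settings.rf_trees,
                max_features=settings.rf_max_features,
                random_state=int(seeds[k]),
            )
            k += 1
            rf.fit(cur[np.ix_(rows, other)], cur[rows, v])
            cur[np.ix_(~rows, [v])] = rf.predict(cur[np.ix_(~rows, other)])[:, None]
        delta = float(np.sum((cur - before) ** 2) / np.sum(cur**2))
        if delta >= prev_delta:
            cur = before  # change grew: keep the previous sweep's matrix
            break
        prev_delta = delta
    cur[~miss] = x[~miss]  # exact preservation of observed cells
    return pd.DataFrame(cur.T, index=matrix.index, columns=matrix.columns)
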