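"""Quantile-regression imputation of left-censored data (QRILC).

Each subject (column) is treated as a sample whose log-abundances are
normally distributed and left-censored at an unknown detection limit.  With
missing fraction q, the observed values are the upper 1-q of the
distribution, so the column's normal parameters can be read off the upper
quantiles: for a grid of probability levels l > max(q, 0.05), the empirical
quantile of the full distribution at level l is the observed-data quantile
at level (l - q)/(1 - q), and regressing those empirical quantiles on the
standard-normal quantiles Phi^-1(l) gives intercept mu-hat and slope
sigma-hat (an ordinary least-squares fit of the Q-Q line over the
uncensored range).  Missing values are then drawn from
N(mu-hat, (tune * sigma-hat)^2) truncated above at the censoring threshold
mu-hat + sigma-hat * Phi^-1(q).

Columns with fewer than 5 observed values (or a non-positive fitted slope)
fall back to half-minimum imputation for their missing cells, with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import ImputerSettings

_LOG2 = float(np.log(2.0))
_LEVEL_STEP = 0.01


@dataclass
class CensoredColumnFit:
    """Estimated normal parameters of one left-censored column."""

    mu: float
    sigma: float
    missing_fraction: float

    @property
    def censoring_threshold(self) -> float:
        return self.mu + self.sigma * stats.norm.ppf(self.missing_fraction)


def fit_censored_column(observed: np.ndarray, missing_fraction: float) -> CensoredColumnFit:
    """Fit N(mu, sigma) to a column from its observed (uncensored) values."""
    observed = np.sort(np.asarray(observed, dtype=float))
    q = float(missing_fraction)
    if not 0.0 <= q < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    lo = max(q, 0.05)
    levels = np.arange(lo + _LEVEL_STEP, 1.0, _LEVEL_STEP)
    emp = np.quantile(observed, (levels - q) / (1.0 - q))
    theo = stats.norm.ppf(levels)
    sigma, mu = np.polyfit(theo, emp, 1)
    return CensoredColumnFit(mu=float(mu), sigma=float(sigma), missing_fraction=q)


def impute_qrilc(
    matrix: pd.DataFrame, settings: ImputerSettings | None = None
) -> pd.DataFrame:
    settings = settings or ImputerSettings()
    x = matrix.to_numpy(dtype=float, copy=True)
    miss = np.isnan(x)
    if not miss.any():
        return matrix.copy()
    if miss.all(axis=0).any():
        raise ValueError("a column with every value missing cannot be imputed")

    with np.errstate(all="ignore"):
        row_min = np.nanmin(x, axis=1)  # half-minimum fallback values (log scale)

    for j in range(x.shape[1]):
        mj = miss[:, j]
        if not mj.any():
            continue
        obs = x[~mj, j]
        q = mj.mean()
        fit = None
        if obs.size >= 5:
            fit = fit_censored_column(obs, q)
            if fit.sigma <= 0:
                fit = None
        if fit is None:
            warnings.warn(
                f"QRILC: column {j} unfit for quantile regression; "
                "falling back to half-minimum", RuntimeWarning)
            x[mj, j] = row_min[mj] - _LOG2
            continue
        scale = settings.qr_tune_sigma * fit.sigma
        upper = (fit.censoring_threshold - fit.mu) / scale
        rng = np.random.default_rng([settings.seed, 0x9C, j])
        x[mj, j] = stats.truncnorm.rvs(
            a=-np.inf, b=upper, loc=fit.mu, scale=scale,
            size=int(mj.sum()), random_state=rng)
    return pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
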