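"""Imputation methods for metabolite x subject matrices with missing cells.

All imputers operate on the natural-log scale (the pipeline masks raw data,
log-transforms, then imputes) and share a uniform surface:

>>> complete = impute_matrix(matrix, "RF", ImputerSettings(seed=1))

Methods: ``HM`` (half-minimum), ``KNN`` (weighted k-nearest-neighbour rows),
``RF`` (iterative random-forest, missForest-style), ``EMB``
(bootstrap-EM multivariate-normal draws), ``QRILC`` (quantile-regression
imputation of left-censored data).  Every method leaves observed cells
bit-identical, returns a complete matrix, and is deterministic given
(input, settings, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = ["ImputerSettings", "impute_matrix", "IMPUTATION_METHODS"]


@dataclass(frozen=True)
class ImputerSettings:
    """Tunable parameters shared by the imputation methods.

    Defaults follow the software settings of the study the pipeline
    emulates: 10 neighbours with an 80% row-missingness cap for kNN, 100
    trees and at most 10 sweeps for random forest, and an EM empirical
    prior of 1% of the rows (0.005 suits low-correlation, wider matrices).
    """

    knn_k: int = 10
    knn_max_missing_frac: float = 0.80
    knn_orientation: str = "metabolites"  # or "subjects"
    rf_trees: int = 100
    rf_max_iter: int = 10
    rf_max_features: object = "sqrt"
    emb_prior_frac: float = 0.01
    emb_block_size: int = 50
    emb_m: int = 1
    emb_max_iter: int = 200
    qr_tune_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0.0 < self.knn_max_missing_frac <= 1.0:
            raise ValueError("knn_max_missing_frac must be in (0, 1]")
        if self.knn_orientation not in ("metabolites", "subjects"):
            raise ValueError("knn_orientation must be 'metabolites' or 'subjects'")
        if self.rf_trees < 1 or self.rf_max_iter < 1:
            raise ValueError("rf_trees and rf_max_iter must be >= 1")
        if self.emb_prior_frac < 0:
            raise ValueError("emb_prior_frac must be non-negative")
        if self.emb_block_size < 2 or self.emb_m < 1:
            raise ValueError("emb_block_size >= 2 and emb_m >= 1 required")
        if self.emb_max_iter < 1:
            raise ValueError("emb_max_iter must be >= 1")
        if self.qr_tune_sigma <= 0:
            raise ValueError("qr_tune_sigma must be positive")

    def with_seed(self, seed: int) -> "ImputerSettings":
        return replace(self, seed=seed)


from ._half_minimum import impute_half_minimum  # noqa: E402
from ._knn import impute_knn  # noqa: E402
from ._random_forest import impute_random_forest  # noqa: E402
from ._em import NormalModelFit, fit_em_normal, impute_emb  # noqa: E402
from ._qrilc import CensoredColumnFit, fit_censored_column, impute_qrilc  # noqa: E402

IMPUTATION_METHODS = {
    "HM": lambda m, s: impute_half_minimum(m),
    "KNN": impute_knn,
    "RF": impute_random_forest,
    "EMB": impute_emb,
    "QRILC": impute_qrilc,
}

__all__ += [
    "impute_half_minimum",
    "impute_knn",
    "impute_random_forest",
    "fit_em_normal",
    "impute_emb",
    "impute_qrilc",
    "fit_censored_column",
    "NormalModelFit",
    "CensoredColumnFit",
]


def impute_matrix(
    matrix: pd.DataFrame, method: str, settings: ImputerSettings | None = None
) -> pd.DataFrame:
    """Apply one imputation method by name; see module docstring."""
    key = method.upper()
    if key not in IMPUTATION_METHODS:
        raise ValueError(
            f"unknown imputation method {method!r}; choose from {sorted(IMPUTATION_METHODS)}"
        )
    return IMPUTATION_METHODS[key](matrix, settings or ImputerSettings())
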