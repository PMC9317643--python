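"""Detection-limit-weighted missingness simulation.

Mass-spectrometry missingness is predominantly left-censoring at the limit
of detection, with a missing-at-random component from technical error.  The
simulator reproduces this blend by restricted random sampling: to reach an
overall missing rate of p%, cells are drawn uniformly without replacement
from the pool of values at or below the q-th quantile, with (p, q) fixed by
:data:`MISSINGNESS_SCHEDULE`.  Because q > p, not every low cell goes
missing — low abundances are missing with high probability, higher
abundances can still drop out at random, and there is no hard threshold.

The eligibility quantile is computed per metabolite (row) by default:
detection limits are compound-specific, and per-row pools reproduce the
real-data feature that some metabolites end up with no missing values at
low p.  A pooled-matrix variant is available via ``per_metabolite=False``.

Masking happens on the raw abundance scale; the masked study is then
log-transformed before imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PairedStudy

__all__ = [
    "MISSINGNESS_SCHEDULE",
    "MissingMask",
    "quantile_for_rate",
    "induce_missingness",
    "apply_mask",
    "mask_study",
    "log_transform",
]

#: target overall missing percentage p -> eligibility percentile q (p < q always)
MISSINGNESS_SCHEDULE: dict[int, int] = {
    1: 2,
    5: 10,
    10: 20,
    20: 40,
    30: 50,
    40: 60,
    50: 70,
    60: 80,
}


def quantile_for_rate(p: int) -> int:
    """Eligibility percentile q for a target missing percentage p."""
    try:
        return MISSINGNESS_SCHEDULE[p]
    except KeyError:
        raise ValueError(
            f"unsupported missingness rate {p}%; supported rates: "
            f"{sorted(MISSINGNESS_SCHEDULE)}"
        ) from None


@dataclass
class MissingMask:
    """Boolean metabolite x subject mask (True = missing) for one biospecimen."""

    values: pd.DataFrame
    target_p: int
    quantile: int
    seed: object = None

    @property
    def n_masked(self) -> int:
        return int(self.values.values.sum())

    def to_frame(self) -> pd.DataFrame:
        """0/1 integer frame, convenient for TSV export."""
        return self.values.astype(int)


def induce_missingness(
    matrix: pd.DataFrame,
    p: int,
    seed,
    per_metabolite: bool = True,
) -> MissingMask:
    """Draw a mask with exactly ``round(p% * M * N)`` missing cells.

    Eligible cells are those at or below the scheduled q-th empirical
    percentile (linear-interpolation quantile, ties eligible) of their own
    metabolite's values — or of the pooled matrix when
    ``per_metabolite=False``.  The required number of cells is sampled
    uniformly without replacement from the pooled eligible set, so the
    overall rate is exact while per-metabolite missing counts vary.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("input matrix must be complete (no missing values)")
    q = quantile_for_rate(p)
    n_mask = round(p / 100.0 * x.size)

    if per_metabolite:
        thresholds = np.quantile(x, q / 100.0, axis=1)
        eligible = x <= thresholds[:, None]
    else:
        eligible = x <= np.quantile(x, q / 100.0)

    pool = np.flatnonzero(eligible.ravel())
    if pool.size < n_mask:
        raise ValueError(
            f"eligible pool ({pool.size}) smaller than required mask count ({n_mask})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_mask, replace=False)
    flat = np.zeros(x.size, dtype=bool)
    flat[chosen] = True
    mask = pd.DataFrame(
        flat.reshape(x.shape), index=matrix.index, columns=matrix.columns
    )
    return MissingMask(values=mask, target_p=p, quantile=q, seed=seed)


def apply_mask(matrix: pd.DataFrame, mask: MissingMask | pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``matrix`` with masked cells set to NaN."""
    values = mask.values if isinstance(mask, MissingMask) else mask
    out = matrix.copy()
    out[np.asarray(values, dtype=bool)] = np.nan
    return out


def mask_study(
    study: PairedStudy, p: int, seed, per_metabolite: bool = True
) -> tuple[PairedStudy, MissingMask, MissingMask]:
    """Mask both biospecimen matrices independently at overall rate p.

    The two masks use independent streams derived from ``seed`` (each
    biospecimen is simulated as its own data set).  ``p == 0`` returns the
    study unchanged with empty masks.
    """
    if study.scale != "raw":
        raise ValueError("missingness is induced on the raw abundance scale")
    if p == 0:
        empty_a = MissingMask(
            pd.DataFrame(False, index=study.specimen_a.index, columns=study.specimen_a.columns),
            0, 0, seed)
        empty_b = MissingMask(empty_a.values.copy(), 0, 0, seed)
        return study.copy(), empty_a, empty_b
    seed_a, seed_b = _child_seeds(seed)
    mask_a = induce_missingness(study.specimen_a, p, seed_a, per_metabolite)
    mask_b = induce_missingness(study.specimen_b, p, seed_b, per_metabolite)
    masked = study.with_matrices(
        apply_mask(study.specimen_a, mask_a), apply_mask(study.specimen_b, mask_b)
    )
    return masked, mask_a, mask_b


def _child_seeds(seed) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    if isinstance(seed, np.random.SeedSequence):
        return tuple(seed.spawn(2))
    return tuple(np.random.SeedSequence(seed).spawn(2))


def log_transform(study: PairedStudy) -> PairedStudy:
    """Natural-log transform observed cells; missing cells stay missing."""
    if study.scale == "log":
        raise ValueError("study is already on the log scale")

    def _log(df: pd.DataFrame) -> pd.DataFrame:
        x = df.to_numpy(dtype=float)
        observed = ~np.isnan(x)
        if (x[observed] <= 0).any():
            raise ValueError("non-positive observed abundance; cannot log-transform")
        out = np.full_like(x, np.nan)
        out[observed] = np.log(x[observed])
        return pd.DataFrame(out, index=df.index, columns=df.columns)

    return study.with_matrices(_log(study.specimen_a), _log(study.specimen_b), scale="log")
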