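"""Half-minimum imputation.

On the raw scale a metabolite's missing values are replaced by half its
smallest observed value; on the working log scale that is
``min(observed log values) - log 2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_LOG2 = float(np.log(2.0))


def impute_half_minimum(matrix: pd.DataFrame) -> pd.DataFrame:
    x = matrix.to_numpy(dtype=float, copy=True)
    missing = np.isnan(x)
    if not missing.any():
        return matrix.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = matrix.index[all_missing][0]
        raise ValueError(f"metabolite {bad!r} has no observed values")
    with np.errstate(all="ignore"):
        row_min = np.nanmin(x, axis=1)
    fill = np.broadcast_to((row_min - _LOG2)[:, None], x.shape)
    x[missing] = fill[missing]
    return pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
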