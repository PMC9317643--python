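"""Canonical scaled-down benchmark grids.

The full published-scale experiment (176/327 metabolites, 100 replicates,
100-tree forests) costs CPU-hours; these grids reproduce its qualitative
contrasts at desk scale and are what the test-suite and the reproduction
script run.  Problem sizes are fixed here, once:

* 48 metabolites per profile (group designs and correlation profiles are
  the full ones: 48+31 subjects high-correlation, 38+40 low-correlation);
* 20 replicates with masks shared across methods and approaches;
* random forest scaled to 12 trees / 3 sweeps and bootstrap-EM capped at
  60 EM iterations — the package defaults remain the published settings
  (100 trees / 10 sweeps, 200 iterations).

Three grids cover the benchmark's contrasts:

* ``high_combined`` — high-correlation profile at 5/20/40/60% missingness,
  combined-matrix imputation (where cross-biospecimen borrowing is
  possible): correlation attenuation and method bias ordering.
* ``high_separate`` — the same profile at 20% under separate imputation:
  sensitivity/specificity ordering of the methods.
* ``low_combined`` — low-correlation profile at 40%: the profile contrast
  in correlation bias.
"""

from __future__ import annotations

import pandas as pd

from .imputers import ImputerSettings
from .pipeline import ProfileSpec, StudyConfig, run_study
from .simulate import (
    GCTOF_DESIGN,
    HILIC_DESIGN,
    HIGH_CORRELATION,
    LOW_CORRELATION,
)

__all__ = ["BENCH_N_METABOLITES", "BENCH_REPLICATES", "bench_settings",
           "HIGH_BENCH", "LOW_BENCH", "benchmark_grids"]

BENCH_N_METABOLITES = 48
BENCH_REPLICATES = 20

HIGH_BENCH = ProfileSpec("high", GCTOF_DESIGN, HIGH_CORRELATION, BENCH_N_METABOLITES)
LOW_BENCH = ProfileSpec("low", HILIC_DESIGN, LOW_CORRELATION, BENCH_N_METABOLITES)


def bench_settings(seed: int = 0) -> ImputerSettings:
    """Imputer settings for the benchmark grids (see module docstring)."""
    return ImputerSettings(rf_trees=12, rf_max_iter=3, emb_max_iter=60, seed=seed)


def benchmark_grids(seed: int, n_replicates: int = BENCH_REPLICATES,
                    progress: bool = False) -> dict[str, pd.DataFrame]:
    """Run the three canonical grids; returns results tables keyed by name."""
    common = dict(n_replicates=n_replicates, seed=seed, settings=bench_settings())
    grids = {
        "high_combined": StudyConfig(
            profiles=(HIGH_BENCH,), levels=(5, 20, 40, 60),
            approaches=("combined",), **common),
        "high_separate": StudyConfig(
            profiles=(HIGH_BENCH,), levels=(20,),
            approaches=("separate",), **common),
        "low_combined": StudyConfig(
            profiles=(LOW_BENCH,), levels=(40,),
            approaches=("combined",), **common),
    }
    return {name: run_study(cfg, progress=progress) for name, cfg in grids.items()}
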