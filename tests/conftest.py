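import numpy as np
import pandas as pd
import pytest

from pairimpute import (
    GCTOF_DESIGN,
    HIGH_CORRELATION,
    ImputerSettings,
    generate_paired_study,
    log_transform,
    mask_study,
)


@pytest.fixture(scope="session")
def gctof_study():
    """A complete high-correlation study at the GC-TOF-like dimensions."""
    return generate_paired_study(GCTOF_DESIGN, HIGH_CORRELATION, 176, seed=11)


@pytest.fixture(scope="session")
def small_masked_matrix():
    """A 50x30 log-scale matrix with ~20% detection-limit-weighted missingness."""
    study = generate_paired_study(GCTOF_DESIGN, HIGH_CORRELATION, 50, seed=5)
    study.specimen_a.drop(columns=study.specimen_a.columns[30:], inplace=True)
    study.specimen_b.drop(columns=study.specimen_b.columns[30:], inplace=True)
    groups = study.groups.iloc[:30]
    from pairimpute import PairedStudy, induce_missingness, apply_mask

    trimmed = PairedStudy(study.specimen_a, study.specimen_b, groups, scale="raw")
    mask = induce_missingness(trimmed.specimen_a, 20, seed=9)
    masked = apply_mask(trimmed.specimen_a, mask)
    return np.log(masked)


@pytest.fixture
def fast_settings():
    """Imputer settings small enough for unit tests."""
    return ImputerSettings(rf_trees=10, rf_max_iter=3, knn_k=5, seed=21)


@pytest.fixture(scope="session")
def small_masked_study():
    """A 40-metabolite, 20-subject masked study on the log scale."""
    from pairimpute import GroupDesign

    design = GroupDesign(12, 8, de_fraction=0.25, effect_size=1.5)
    study = generate_paired_study(design, HIGH_CORRELATION, 40, seed=13)
    masked, mask_a, mask_b = mask_study(study, 20, seed=17)
    return log_transform(masked), log_transform(study), mask_a, mask_b
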