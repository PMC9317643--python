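"""Synthetic paired-biospecimen metabolomics studies.

Real multi-biospecimen studies measure each metabolite once per biospecimen
(e.g. serum and plasma) on the same subjects, so the data arrive as two
aligned metabolite x subject abundance matrices.  The generator here emulates
the statistical skeleton of two such lung-cancer studies: a "high
correlation" design (GC-TOF-like: 48 cases vs 31 controls, 176 metabolites,
between-biospecimen correlations on [-0.2, 0.98] with a mode near 0.5, ~23%
truly differential) and a "low correlation" design (HILIC-like: 38 vs 40
subjects, 327 metabolites, correlations on [-0.3, 0.3] with a mode near 0,
~21% differential).

Per metabolite, log-abundances of the two biospecimens are bivariate normal
with a metabolite-specific correlation drawn from a unimodal distribution on
the profile's range; group effects shift the case-group mean of both
biospecimens by ``effect_size`` log-SD units.  Metabolites are mutually
independent: the generator makes no attempt to model metabolite-metabolite
correlation networks, batch effects or run-day drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroupDesign",
    "CorrelationProfile",
    "PairedStudy",
    "generate_paired_study",
    "GCTOF_DESIGN",
    "HILIC_DESIGN",
    "HIGH_CORRELATION",
    "LOW_CORRELATION",
]

Seed = "int | np.random.SeedSequence | list[int] | None"


@dataclass(frozen=True)
class GroupDesign:
    """Two-group subject design with a controlled differential fraction.

    Parameters
    ----------
    n_group1, n_group2
        Subjects per group (group 1 = cases, group 2 = controls); each >= 3.
    de_fraction
        Proportion of metabolites carrying a true group effect, in [0, 1].
        Exactly ``round(de_fraction * n_metabolites)`` metabolites are made
        differential, so truth counts are deterministic.
    effect_size
        Standardized mean shift (log-scale SD units) added to the group-1
        mean of differential metabolites.
    """

    n_group1: int
    n_group2: int
    de_fraction: float = 0.0
    effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.n_group1 < 3 or self.n_group2 < 3:
            raise ValueError("each group needs at least 3 subjects")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2


@dataclass(frozen=True)
class CorrelationProfile:
    """Distribution of per-metabolite between-biospecimen correlations.

    Correlations are drawn from a beta distribution rescaled to
    ``[r_min, r_max]`` with its mode placed at ``r_mode``.  With
    concentration ``c`` (= alpha + beta, default 8) the shape parameters are
    ``alpha = 1 + m*(c-2)``, ``beta = 1 + (1-m)*(c-2)`` where ``m`` is the
    mode mapped to [0, 1]; both exceed 1, so the density is unimodal and
    every draw lies inside the open interval.
    """

    name: str
    r_min: float
    r_max: float
    r_mode: float
    concentration: float = 8.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.r_min < self.r_mode < self.r_max < 1.0):
            raise ValueError(
                f"require -1 < r_min < r_mode < r_max < 1, got "
                f"({self.r_min}, {self.r_mode}, {self.r_max})"
            )
        if self.concentration <= 2.0:
            raise ValueError("concentration must exceed 2 for a unimodal density")

    @property
    def _shape(self) -> tuple[float, float]:
        m = (self.r_mode - self.r_min) / (self.r_max - self.r_min)
        c = self.concentration
        return 1.0 + m * (c - 2.0), 1.0 + (1.0 - m) * (c - 2.0)

    @property
    def mean(self) -> float:
        """Analytic mean of the sampler's distribution."""
        a, b = self._shape
        return self.r_min + (self.r_max - self.r_min) * a / (a + b)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self._shape
        return self.r_min + (self.r_max - self.r_min) * rng.beta(a, b, size)


#: Presets mirroring the two study designs described in the module docstring.
GCTOF_DESIGN = GroupDesign(48, 31, de_fraction=0.23, effect_size=1.0)
HILIC_DESIGN = GroupDesign(38, 40, de_fraction=0.21, effect_size=1.0)
HIGH_CORRELATION = CorrelationProfile("high", -0.2, 0.98, 0.5)
LOW_CORRELATION = CorrelationProfile("low", -0.3, 0.3, 0.0)


@dataclass
class PairedStudy:
    """Two aligned metabolite x subject matrices plus per-subject labels.

    ``specimen_a`` and ``specimen_b`` share index (metabolite IDs) and
    columns (subject IDs).  ``scale`` tracks whether values are raw
    (strictly positive) abundances or natural-log abundances; missing cells
    are NaN.  ``true_r``/``true_de`` carry generator truth and are ``None``
    for user-supplied data.
    """

    specimen_a: pd.DataFrame
    specimen_b: pd.DataFrame
    groups: pd.Series
    true_r: pd.Series | None = None
    true_de: pd.Series | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.specimen_a.shape != self.specimen_b.shape:
            raise ValueError("specimen matrices must share dimensions")
        if not self.specimen_a.index.equals(self.specimen_b.index):
            raise ValueError("specimen matrices must share metabolite IDs")
        if not self.specimen_a.columns.equals(self.specimen_b.columns):
            raise ValueError("specimen matrices must share subject IDs")
        if len(self.groups) != self.specimen_a.shape[1]:
            raise ValueError("one group label per subject required")
        if self.scale not in ("raw", "log"):
            raise ValueError("scale must be 'raw' or 'log'")

    @property
    def n_metabolites(self) -> int:
        return self.specimen_a.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.specimen_a.shape[1]

    @property
    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def copy(self) -> "PairedStudy":
        return PairedStudy(
            self.specimen_a.copy(),
            self.specimen_b.copy(),
            self.groups.copy(),
            None if self.true_r is None else self.true_r.copy(),
            None if self.true_de is None else self.true_de.copy(),
            self.scale,
        )

    def with_matrices(self, a: pd.DataFrame, b: pd.DataFrame, scale: str | None = None) -> "PairedStudy":
        """Same metadata, new abundance matrices."""
        return PairedStudy(a, b, self.groups.copy(),
                           None if self.true_r is None else self.true_r.copy(),
                           None if self.true_de is None else self.true_de.copy(),
                           self.scale if scale is None else scale)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_paired_study(
    design: GroupDesign,
    profile: CorrelationProfile,
    n_metabolites: int,
    seed,
    log_mean_range: tuple[float, float] = (3.0, 10.0),
    log_sd_range: tuple[float, float] = (0.3, 1.2),
    shared_shift: bool = True,
) -> PairedStudy:
    """Draw a complete (no-missing) paired-biospecimen study.

    Per metabolite *i* a correlation ``r_i`` is drawn from ``profile``; each
    subject's log-abundance pair is bivariate normal with correlation
    ``r_i`` and metabolite- and biospecimen-specific mean (uniform on
    ``log_mean_range``) and SD (uniform on ``log_sd_range``).  Exactly
    ``round(de_fraction * n_metabolites)`` metabolites receive a
    ``effect_size``-SD shift of the group-1 mean — in both biospecimens with
    the same sign when ``shared_shift`` (the default, consistent with a
    shared biological driver), otherwise in biospecimen A only.  Values are
    exponentiated to the raw scale, so all abundances are strictly positive.
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    rng = _rng(seed)
    m, n = n_metabolites, design.n_subjects
    n1 = design.n_group1

    r = profile.sample(m, rng)
    mu_a = rng.uniform(*log_mean_range, m)
    mu_b = rng.uniform(*log_mean_range, m)
    sd_a = rng.uniform(*log_sd_range, m)
    sd_b = rng.uniform(*log_sd_range, m)

    z1 = rng.standard_normal((m, n))
    z2 = rng.standard_normal((m, n))
    log_a = mu_a[:, None] + sd_a[:, None] * z1
    log_b = mu_b[:, None] + sd_b[:, None] * (
        r[:, None] * z1 + np.sqrt(1.0 - r[:, None] ** 2) * z2
    )

    n_de = round(design.de_fraction * m)
    de = np.zeros(m, dtype=bool)
    if n_de:
        de[rng.choice(m, size=n_de, replace=False)] = True
    if n_de and design.effect_size > 0:
        log_a[de, :n1] += design.effect_size * sd_a[de, None]
        if shared_shift:
            log_b[de, :n1] += design.effect_size * sd_b[de, None]

    metabolites = pd.Index([f"met{i + 1:04d}" for i in range(m)], name="metabolite_id")
    subjects = pd.Index([f"subj{j + 1:03d}" for j in range(n)], name="subject_id")
    groups = pd.Series(
        ["group1"] * n1 + ["group2"] * design.n_group2, index=subjects, name="group"
    )

    return PairedStudy(
        specimen_a=pd.DataFrame(np.exp(log_a), index=metabolites, columns=subjects),
        specimen_b=pd.DataFrame(np.exp(log_b), index=metabolites, columns=subjects),
        groups=groups,
        true_r=pd.Series(r, index=metabolites, name="true_r"),
        true_de=pd.Series(de, index=metabolites, name="true_de"),
        scale="raw",
    )
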