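"""Full factorial benchmark: profiles x levels x methods x approaches x replicates.

Each replicate generates a fresh complete paired study, establishes the
"truth" (complete-data correlations and MANOVA calls), then for every
missingness level draws one pair of masks that is *shared* by all methods
and approaches (so method contrasts are not confounded by mask draws),
log-transforms, imputes, and scores correlation bias and validity metrics
against the complete data.  Every random draw is derived from the master
seed and the cell's grid coordinates, never from execution order, so the
results table is bit-identical across runs and execution orders.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .approaches import IMPUTATION_APPROACHES
from .evaluation import (
    bias_summary,
    correlation_records,
    manova_calls,
    validity_metrics,
)
from .imputers import IMPUTATION_METHODS, ImputerSettings
from .missingness import MISSINGNESS_SCHEDULE, log_transform, mask_study
from .simulate import (
    GCTOF_DESIGN,
    HILIC_DESIGN,
    HIGH_CORRELATION,
    LOW_CORRELATION,
    CorrelationProfile,
    GroupDesign,
    generate_paired_study,
)

__all__ = ["ProfileSpec", "PROFILES", "StudyConfig", "run_study", "summarize"]

logger = logging.getLogger("pairimpute")


@dataclass(frozen=True)
class ProfileSpec:
    """A named synthetic study condition."""

    name: str
    design: GroupDesign
    correlation: CorrelationProfile
    n_metabolites: int


#: The two emulated study conditions: high-correlation (GC-TOF-like) and
#: low-correlation (HILIC-like).
PROFILES: dict[str, ProfileSpec] = {
    "high": ProfileSpec("high", GCTOF_DESIGN, HIGH_CORRELATION, 176),
    "low": ProfileSpec("low", HILIC_DESIGN, LOW_CORRELATION, 327),
}


@dataclass
class StudyConfig:
    profiles: tuple = ("high",)
    levels: tuple = (5, 20, 40, 60)
    methods: tuple = ("HM", "KNN", "RF", "EMB", "QRILC")
    approaches: tuple = ("separate", "combined")
    n_replicates: int = 20
    seed: int = 0
    settings: ImputerSettings = field(default_factory=ImputerSettings)
    per_metabolite_quantile: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for p in self.levels:
            if p != 0 and p not in MISSINGNESS_SCHEDULE:
                raise ValueError(
                    f"level {p} not in the missingness schedule "
                    f"{sorted(MISSINGNESS_SCHEDULE)} (0 allowed as control)")
        for m in self.methods:
            if m.upper() not in IMPUTATION_METHODS:
                raise ValueError(f"unknown method {m!r}")
        for a in self.approaches:
            if a not in IMPUTATION_APPROACHES:
                raise ValueError(f"unknown approach {a!r}")

    def resolve_profiles(self) -> list[ProfileSpec]:
        out = []
        for prof in self.profiles:
            if isinstance(prof, ProfileSpec):
                out.append(prof)
            elif prof in PROFILES:
                out.append(PROFILES[prof])
            else:
                raise ValueError(f"unknown profile {prof!r}")
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        settings = ImputerSettings(**raw.pop("settings", {}))
        profiles = []
        for prof in raw.pop("profiles", ["high"]):
            if isinstance(prof, str):
                profiles.append(prof)
            else:  # nested custom profile definition
                profiles.append(ProfileSpec(
                    name=prof["name"],
                    design=GroupDesign(**prof["design"]),
                    correlation=CorrelationProfile(**prof["correlation"]),
                    n_metabolites=prof["n_metabolites"],
                ))
        for key in ("levels", "methods", "approaches"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(profiles=tuple(profiles), settings=settings, **raw)


def _cell_seed(*coords: int) -> int:
    """Deterministic sub-2^31 integer seed from grid coordinates."""
    return int(np.random.SeedSequence(list(coords)).generate_state(1)[0] % (2**31))


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full grid; one row per (profile, method, approach, p, replicate)."""
    rows = []
    methods = tuple(m.upper() for m in config.methods)
    for pidx, prof in enumerate(config.resolve_profiles()):
        for rep in range(config.n_replicates):
            study = generate_paired_study(
                prof.design, prof.correlation, prof.n_metabolites,
                seed=[config.seed, pidx, rep, 1])
            complete_log = log_transform(study)
            truth = manova_calls(complete_log)
            for p in config.levels:
                masked, mask_a, mask_b = mask_study(
                    study, p, np.random.SeedSequence([config.seed, pidx, rep, 2, p]),
                    per_metabolite=config.per_metabolite_quantile)
                masked_log = log_transform(masked) if p else complete_log
                for approach in config.approaches:
                    for midx, method in enumerate(methods):
                        seed = _cell_seed(config.seed, pidx, rep, 3, p, midx)
                        try:
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore", RuntimeWarning)
                                imputed = IMPUTATION_APPROACHES[approach](
                                    masked_log, method,
                                    replace(config.settings, seed=seed))
                            records = correlation_records(
                                complete_log, imputed, mask_a.values, mask_b.values)
                            calls = manova_calls(imputed)
                            vm = validity_metrics(truth["call"], calls["call"])
                            summ = bias_summary(records).iloc[0]
                        except Exception as exc:  # one failed cell never kills the grid
                            logger.warning(
                                "cell failed: profile=%s rep=%d p=%d %s/%s: %s",
                                prof.name, rep, p, approach, method, exc)
                            continue
                        defined = records["r_imputed"].notna()
                        rows.append({
                            "profile": prof.name, "method": method,
                            "approach": approach, "p": p, "replicate": rep,
                            "sensitivity": vm.sensitivity,
                            "specificity": vm.specificity,
                            "accuracy": vm.accuracy,
                            "tp": vm.tp, "fp": vm.fp, "tn": vm.tn, "fn": vm.fn,
                            "mean_bias": summ["mean_bias"],
                            "mean_abs_bias": summ["mean_abs_bias"],
                            "sd_bias": summ["sd_bias"],
                            "mean_r_true": records["r_true"].mean(),
                            "mean_r_imputed": records.loc[defined, "r_imputed"].mean(),
                            "mean_abs_r_imputed": records.loc[defined, "r_imputed"].abs().mean(),
                            "n_undefined": int((~defined).sum()),
                        })
            if progress:
                print(f"profile {prof.name}: replicate {rep + 1}/{config.n_replicates} done")
    results = pd.DataFrame(rows)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
    return results


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SD of every metric across replicates."""
    if results.empty:
        raise ValueError("results table is empty")
    metrics = ["sensitivity", "specificity", "accuracy",
               "mean_bias", "mean_abs_bias", "mean_abs_r_imputed"]
    grouped = results.groupby(["profile", "method", "approach", "p"])[metrics]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).add_suffix("_sd")
    out = pd.concat([mean, sd], axis=1).reset_index()
    out["n_replicates"] = grouped.size().to_numpy()
    return out
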