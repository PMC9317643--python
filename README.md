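# pairimpute

Benchmarking missing-value imputation for **paired-biospecimen metabolomics
studies** — mass-spectrometry experiments that measure the same metabolites
in two sample types (e.g. serum and plasma, or tissue and serum) from the
same subjects.

## The problem

MS metabolomics data are plagued by missing values, most of them
left-censoring at the limit of detection (LOD). Imputing them is routine,
but in multi-biospecimen studies imputation can also destroy the quantity
that makes the design valuable: the **between-biospecimen correlation** —
for each metabolite *i*, the Pearson correlation across subjects of its
abundance in biospecimen A vs biospecimen B,

```
r_i = corr( log A_i· , log B_i· ).
```

Attenuated correlation estimates then distort multivariate differential
abundance tests. `pairimpute` quantifies this: it simulates paired studies
with controlled correlation structure, induces LOD-weighted missingness at
exact overall rates, imputes under two strategies — each M×N matrix
**separately**, or both **combined** into one 2M×N matrix — with five
methods, and scores the damage.

**Methods:** half-minimum (HM), distance-weighted k-nearest neighbours
(kNN), iterative random forest (RF, missForest-style), bootstrap-EM
multivariate-normal draws (EMB), and quantile-regression imputation of
left-censored data (QRILC).

**Scoring:** per-metabolite correlation bias `r_imputed − r_true`, and the
validity of significance calls from a bivariate two-group MANOVA
(Hotelling's T², raw p < 0.05) — sensitivity, specificity and accuracy of
imputed-data calls against the complete-data calls:

```
T² = (n1·n2)/(n1+n2) · d' S⁻¹ d,     F = (n1+n2−3)/(2(n1+n2−2)) · T² ~ F(2, n1+n2−3)
```

with `d` the bivariate group mean difference and `S` the pooled covariance.

## Worked example

```python
import pairimpute as pi

# a GC-TOF-like study: 48 cases vs 31 controls, high between-biospecimen
# correlation (mode ~0.5), 23% truly differential metabolites
study = pi.generate_paired_study(pi.GCTOF_DESIGN, pi.HIGH_CORRELATION,
                                 n_metabolites=176, seed=1)

# mask 20% of each matrix, weighted below the per-metabolite 40th percentile
masked, mask_a, mask_b = pi.mask_study(study, p=20, seed=7)
print(mask_a.n_masked)                      # 2781  (= round(0.20*176*79))

# log-transform, impute the stacked 2M x N matrix with random forest
masked_log = pi.log_transform(masked)
imputed = pi.impute_combined(masked_log, "RF",
                             pi.ImputerSettings(rf_trees=12, rf_max_iter=3, seed=3))

# score against the complete data
complete_log = pi.log_transform(study)
records = pi.correlation_records(complete_log, imputed, mask_a.values, mask_b.values)
vm = pi.validity_metrics(pi.manova_calls(complete_log)["call"],
                         pi.manova_calls(imputed)["call"])
print(round(records["bias"].abs().mean(), 3))   # 0.151
print(round(vm.sensitivity, 2), round(vm.specificity, 2))   # 0.96 0.96
```

The mean absolute correlation bias of ~0.15 at 20% missingness says the
imputed data understate the true between-biospecimen correlation noticeably,
even while the MANOVA calls remain largely correct (96% of truly significant
metabolites are still called significant).

The same stages are scriptable from the shell:

```sh
pairimpute simulate --profile high --out study/
pairimpute mask study/specimen_A.tsv -p 20 --seed 5 --out masked_A.tsv
pairimpute run config.yaml --out results.csv
pairimpute summarize results.csv --out summary.csv
pairimpute plot results.csv --metric sensitivity --out sens.png
```

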