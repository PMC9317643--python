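# Methods

## Scope and model

`pairimpute` studies how missing-value imputation degrades the
between-biospecimen correlation structure of paired metabolomics matrices,
and how that degradation propagates into multivariate differential
abundance calls. Everything runs on synthetic data whose statistical
skeleton matches two archetypal lung-cancer study designs:

| profile | subjects | metabolites | correlation range (mode) | differential |
|---|---|---|---|---|
| `high` (GC-TOF-like) | 48 + 31 | 176 | −0.2 … 0.98 (≈0.5) | 23% |
| `low` (HILIC-like) | 38 + 40 | 327 | −0.3 … 0.3 (≈0) | 21% |

## Synthetic data generator

Per metabolite *i*, a between-biospecimen correlation `r_i` is drawn from a
beta distribution rescaled to the profile's range with its mode at the
profile's modal value (concentration α+β = 8; the published sources state
only range and mode, so any unimodal family on the interval is admissible —
the beta is the natural minimal choice). Subject log-abundances are
bivariate normal with correlation `r_i`; metabolite- and
biospecimen-specific means are uniform on [3, 10] log units and SDs uniform
on [0.3, 1.2] (no marginal scales are published; these give a realistic
MS dynamic range of ~e³–e¹⁰ intensity units). Exactly
`round(de_fraction·M)` metabolites carry a group effect — a shift of
`effect_size` (default 1.0) SD units added to the case-group mean in *both*
biospecimens with the same sign, consistent with a shared biological driver
(a one-biospecimen variant is configurable). Values are exponentiated to a
strictly positive raw scale.

The generator deliberately omits metabolite–metabolite correlation
networks, batch effects and run-day drift. The omission matters for
interpretation: methods that exploit cross-metabolite correlation in real
data (random forest above all) can only borrow strength here from the
group effect and — under combined imputation — from the paired biospecimen
row. Passing grids therefore demonstrate the pipeline's internal
consistency and the direction of its contrasts, not field performance on
real matrices.

## Missingness simulation

LOD-censoring-with-MAR-admixture is simulated by restricted random
sampling: for a target overall rate p%, exactly `round(p%·M·N)` cells are
drawn uniformly without replacement from the pool of cells at or below the
q-th empirical percentile of their own metabolite, with the fixed schedule

| p | 1 | 5 | 10 | 20 | 30 | 40 | 50 | 60 |
|---|---|---|----|----|----|----|----|----|
| q | 2 | 10 | 20 | 40 | 50 | 60 | 70 | 80 |

Since q > p, low values are missing with high probability but not
certainty, and there is no hard threshold. The eligibility quantile is
computed **per metabolite** (linear-interpolation quantile, ties eligible):
detection limits are compound-specific, and per-row pools reproduce the
real-data feature that some metabolites escape missingness entirely at low
p. A pooled-matrix variant is available (`per_metabolite=False`); with the
wide dynamic range of these profiles it concentrates all missingness in the
lowest-abundance metabolites and empties entire rows at high p, which is
why it is not the default. Masking happens on the raw scale; the masked
study is then natural-log transformed, and all imputers work on the log
scale.

## Imputation methods

All methods preserve observed cells bit-identically, return complete
matrices, and are deterministic given (input, settings, seed).

* **HM** — missing cells of metabolite *i* get half its smallest observed
  raw value: `min(observed log) − log 2` on the working scale.
* **kNN** — neighbours are metabolites (rows), matching the row-oriented
  expression-matrix tool used in the emulated benchmark; distance is the
  RMS difference over mutually observed columns; the k=10 nearest rows
  observed at the target column contribute inverse-distance weights
  (zero-distance rows are copied). Rows more than 80% missing fall back to
  the column's observed mean. A subject-oriented variant
  (`knn_orientation="subjects"`) implements the alternative reading in
  which neighbours are subjects.
* **RF** — the missForest iteration: mean-initialise, sweep variables
  (metabolites) in ascending missingness regressing each on all others
  with a random forest (default 100 trees, `sqrt` feature sampling),
  stop when the normalised change in imputed values first increases and
  return the previous sweep's matrix, or at 10 sweeps.
* **EMB** — bootstrap subjects once, fit a multivariate normal by EM on
  the resample, then draw each subject's missing block from its
  conditional normal given its observed block. Because M ≥ N in these
  designs, the EM fit runs on consecutive metabolite blocks of 50
  variables with a conjugate-style diagonal prior of strength
  `emb_prior_frac·n` (default 1% of subjects; 0.5% suits the wider
  low-correlation matrices). One consequence of consecutive blocks under
  A-then-B stacking: a metabolite and its biospecimen twin rarely share a
  block, so combined EMB behaves much like separate EMB.
* **QRILC** — per subject column, the observed values are taken as the
  upper (1−q) of a normal distribution (q = column missing fraction);
  an OLS fit of empirical quantiles against standard-normal quantiles over
  levels above max(q, 0.05) (0.01 spacing) yields (μ̂, σ̂), and missing
  cells are drawn from N(μ̂, (tune·σ̂)²) truncated above at
  μ̂ + σ̂·Φ⁻¹(q). Columns with <5 observed values fall back to HM.

EM details: E-step conditional moments per missingness pattern, M-step
with ridge update `Σ ← (nΣ + λD₀)/(n + λ)` (D₀ = initial observed-data
variances), convergence at relative parameter change < 1e-4 or 200
iterations, observed-data log-likelihood tracked and non-decreasing (exact
EM when λ = 0; with complete data the fit equals the closed-form 1/n MLE).
The covariance is initialised from the pairwise-complete covariance with
eigenvalues clipped positive, which cuts the iteration count severely
relative to a diagonal start.

## Evaluation

Correlations and MANOVA run on the log scale for complete and imputed data
alike. The two-group bivariate MANOVA is computed as Hotelling's T²
(exactly equivalent to Wilks/Pillai/Roy for two groups, so the choice of
statistic is moot); calls use raw p < 0.05 with no multiplicity
correction. Bias is signed `r_imputed − r_true`, so attenuation appears as
bias opposing the sign of the true correlation. Zero-variance rows and
zero-denominator rates are reported as undefined and excluded from
summaries rather than coerced to 0 or 1. For metabolites with no masked
cell in either matrix, `r_imputed` is copied from `r_true` (observed-cell
preservation makes the rows identical; recomputing would only inject
last-bit summation noise).

## Benchmark grids and problem sizes

The full published-scale experiment (two profiles × 8 levels × 5 methods ×
2 approaches × 100 replicates, 100-tree forests, 176–327 metabolites) is a
CPU-hour-scale computation. The package's canonical grids
(`pairimpute.benchmark`) keep the full subject designs, correlation
profiles, differential fractions, replicate pairing and mask-sharing, and
scale the rest once:

* 48 metabolites per profile, 20 replicates;
* random forest at 12 trees / ≤3 sweeps, EM capped at 60 iterations for
  the bootstrap fits (package defaults remain 100/10 and 200);
* combined-approach grid at 5/20/40/60% for the attenuation and bias
  contrasts, separate-approach grid at 20% for the validity ordering, and
  a low-correlation grid at 40% for the profile contrast.

Masks are shared across methods and approaches within a replicate, so
method contrasts are paired. Seeds derive from the master seed and grid
coordinates only — results are independent of execution order and
bit-identical across reruns.

## Known limitations

* Metabolite independence in the generator (above) is the binding
  limitation: it removes most of the predictive signal that distinguishes
  regression-based imputers on real data, and it makes HM unusually strong
  — the masked cells are genuinely low values, so a per-metabolite low
  constant is often close to the withheld truth. Method rankings on these
  grids are conservative for RF relative to real data.
* Single imputation only: EMB draws one bootstrap imputation by default
  (`emb_m` > 1 averages draws); Rubin's-rules pooling of multiple
  imputations is out of scope.
* Two biospecimens exactly; the stacking machinery would generalise but is
  untested beyond pairs.
* MANOVA assumes a common within-group covariance and normality on the
  log scale; both hold by construction in the generator but are untested
  diagnostics for user-supplied data.
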