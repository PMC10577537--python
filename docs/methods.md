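# Methods

## Model and procedure

The clock is a penalized linear model of chronological age (years) on CpG
methylation percentages (0-100 scale):

    age_i = β₀ + Σ_j β_j · m_ij + ε_i

fit with the elastic-net penalty `λ · (α‖β‖₁ + (1−α)/2 ‖β‖₂²)`, α fixed at
0.5. The distinguishing feature is that the model is retrained **per test
sample** on exactly the CpG sites shared between the training cohort and that
sample, so prediction never encounters a missing feature and nothing is ever
imputed.

Per test sample the workflow is:

1. **Intersection.** Sites present in both the training feature table and the
   (coverage-filtered) test call set, sorted by chromosome then position. If
   fewer than `min_intersection` (default 10,000) sites remain, the sample is
   flagged not-admitted and receives no prediction.
2. **Restriction.** The training matrix is cut down to the intersected
   columns; rows (samples) and ages are unchanged.
3. **Outer fivefold CV.** Training samples are randomly partitioned (seeded)
   into five near-equal folds. For each fold, a model is fit on the other
   four fifths with λ selected by inner 10-fold cross-validation minimizing
   mean squared prediction error over a 100-point λ path (path and selection
   rule are the glmnet-style defaults: geometric path down to
   `eps = 1e-3 · λ_max`, minimum-CV-error rule, not one-standard-error).
4. **Ensemble prediction.** Each of the five clocks predicts the test sample
   from its own methylation percentages; the reported epigenetic age is their
   arithmetic mean. The five held-out fold predictions, pooled (each training
   sample predicted exactly once), give the per-sample CV performance:
   Pearson r and median absolute error (MedAE, years).

Assumptions: age enters untransformed (no juvenile log-linear warp);
methylation percentages are taken at face value from each sample's own read
counts, with no renormalization to the training distribution; negative
predicted ages are reported as-is, because group contrasts depend on relative
values and clipping would bias group means.

## Input handling

CpG sites are keyed 1-based by the plus-strand cytosine of the dinucleotide.
Bismark-style CpG reports are strand-collapsed on read: a minus-strand record
at position p+1 is summed into the plus-strand record at p; an unpaired
minus-strand record is re-keyed to p on its own. The ≥ `min_coverage` read
filter (default 5) is applied to the **summed** coverage, because the filtered
entities are strand-collapsed CpG sites. Processed tables that report a
methylation fraction and coverage are converted to counts by half-up rounding
of `fraction × coverage`; dialects that carry explicit counts use them
directly. 0-based inputs are shifted by +1 at the reader boundary (or via
`shift_basis` before an assembly lift), so a single coordinate convention
holds everywhere downstream.

Assembly lifting is a pluggable interface: an identity map and an explicit
lookup-table map (TSV of source/target coordinates) are provided; chain-file
parsing is deliberately out of scope. Unmapped sites are dropped with a
count by default (strict mode raises); many-to-one lifts raise, since they
signal a defective map.

## Randomness and determinism

All randomness flows from `ClockConfig.rng_seed` through
`numpy.random.SeedSequence`. The outer fold partition for a test sample is
drawn from a stream keyed by `(rng_seed, crc32(sample_id))`, so results are
independent of cohort order and of training-table row order (rows are
canonically sorted by sample id before fold assignment, making the fit
invariant to input permutations). A config switch
(`share_fold_partition=True`) reuses one partition, keyed by `rng_seed` alone,
for every test sample; besides being the alternative reading of "fivefold
CV", it lets the cohort runner cache the five fitted clocks across test
samples whose intersections coincide, which makes large replicate simulations
cheap. Inner-CV fold shuffles get their own derived seeds. Two runs with the
same seed produce byte-identical prediction tables.

Predictors are standardized (mean 0, variance 1 on the fold's training
portion; zero-variance columns are left centered at zero) before the
penalized fit, and coefficients are transformed back to the
methylation-percent scale, so reported weights are years per percentage
point. Solver: coordinate descent, tolerance 1e-4, `max_iter` 1000; at the
smallest path penalties with p ≫ n the solver can stop at the iteration cap,
which is expected and harmless for λ selection.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | L1/L2 mixing of the elastic net |
| `inner_splits` | 10 | folds of the inner λ-selection CV |
| `outer_folds` | 5 | clocks in the ensemble, one per outer fold |
| `min_intersection` | 10,000 sites | admission threshold for a test sample |
| `min_coverage` (readers) | 5 reads | per-site coverage filter, after strand collapse |
| `n_lambdas` | 100 | λ-path resolution |

## The synthetic-data generator

`GeneratorSpec` emulates an RRBS blood cohort: 182 samples with ages uniform
on 4-40 years; 20,000 CpG sites of which 300 are informative, each with a
baseline percent uniform on [20, 80] (keeping age trajectories inside the
valid range) and a signed slope of 0.1-0.5 percent/year; biological noise of
2 percentage points (Gaussian, added to the latent percent before clipping to
[0, 100]); read depth negative-binomial with mean 30 and size 5, capped at
200 — deep enough to be realistic, shallow enough that the ≥ 5-read filter
occasionally bites (training cohorts force depth ≥ 5 so the assembled table
keeps all columns; test samples do not). Methylated counts are a binomial
draw of the depth at the latent percent, so sampling noise scales correctly
with depth. Test-sample missingness is site-wise independent by default, with
a contiguous-block mode approximating RRBS fragment structure. Setting
`depth_dispersion=inf` gives constant depth (the infinite-depth limit used to
verify the latent model).

What the generator does **not** emulate: genome-wide CpG density and
co-methylation of neighboring sites, cell-composition shifts with age,
nonlinear (saturating) age trajectories, batch effects, and SNP-at-CpG
artifacts. Passing tests therefore demonstrate that the workflow is
implemented correctly and behaves as designed under its own assumptions, not
that it attains any particular accuracy on real cohorts.

## Problem sizes used in tests and the acceptance script

Workflow fidelity is checked at the full design size (182 × 20,000, 300
informative sites, noise sd 2): pooled out-of-fold r ≥ 0.9 and MedAE ≤ 3 y.
The admission boundary is checked on a 20-sample × 10,000-site table with a
shortened λ path (8 points, 4 inner splits), since admission is decided
before any fitting. The group-comparison operating characteristics use a
scaled cohort (80 × 600, 120 informative, `min_intersection` 300) with the
shared-fold-partition switch so clocks are cached across replicates: power is
estimated from 100 replicates of 8-vs-8 groups 10 latent years apart, and the
null rejection rate from 400 equal-age replicates. Replicate seeds are drawn
from a single `SeedSequence` per experiment.

## Known limitations

* The per-sample retraining costs one full cross-validated elastic-net run
  per test sample (minutes at 182 × 20,000 on one CPU); cohorts of test
  samples with identical coverage can share clocks only under
  `share_fold_partition`.
* Chain-file liftover must be supplied externally as a lookup table.
* Group comparisons assume approximately normal predicted ages within groups
  (reasonable: each prediction is a weighted sum over thousands of sites) and
  report raw p-values without multiple-testing correction.
* `cv_r`/`cv_medae` describe training-cohort self-prediction on the
  intersected sites — a quality certificate for the site set, not a direct
  error bar on the test prediction.
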