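# Methods

## Data model and conventions

All genomic coordinates are 0-based, half-open (BED convention). A CpG site
is identified by (chromosome, position of the cytosine); methylation
frequency at a site in a sample is modified reads / valid reads, carried on
the [0, 1] scale internally and as a percent in bedMethyl files. Input
bedMethyl follows the modkit pileup layout: columns 1–6 plus the
valid-coverage / percent-modified / count-modified block; extra columns are
ignored, records are filtered to one modification code (default `m`, 5mC).
Strand merging — combining a `+` record at p with a `-` record at p+1 into
one dinucleotide record with summed counts — is on by default and conserves
total coverage and modified counts exactly; both merged and per-strand modes
are supported because pileups in the wild come both ways.

Covariates are age in years (the outcome), sex coded {0, 1} by sorted label
order with the mapping recorded, and postmortem interval (PMI) in hours.
Missing PMI is imputed with the cohort median and flagged rather than
dropping samples; missing age is an error.

## Promoter features

Core promoters are expanded to a symmetric window of `window` bp
(default 2,000) centered on the TSS, clipped at coordinate 0 (strand does
not change the interval). A CpG site must be covered by at least `min_cov`
reads (default 5) in at least `min_frac` of samples (default 0.95, inclusive
comparison on the exact fraction) to remain. A promoter becomes a feature
when at least `min_cpgs` (default 10) surviving CpGs fall in its window —
the count is of CpGs that passed the coverage filter, since aggregation
follows filtering. The feature value is the unweighted mean frequency over
the sample's covered member CpGs; when a sample covers none of them the
promoter's cohort mean is substituted and the cell flagged imputed (with the
95% coverage rule such cells are rare). Overlapping windows get independent
columns; a site in two windows contributes to both.

## Selection cascade

1. **Methylation PCs.** PCA of the column-standardized (center, unit
   variance) promoter matrix, computed before pruning so the components
   summarize the full methylome. `k_pcs` defaults to 20 and is reduced on
   small cohorts to preserve at least a handful of residual degrees of
   freedom in the screen (k ≤ n − 10). Constant columns are dropped with a
   warning.
2. **Correlation pruning.** Promoters are ordered genomically and split
   into batches of `batch_size` (default 1,000) consecutive promoters.
   Within a batch, scanning in order, a promoter is dropped iff an earlier
   *still-kept* promoter correlates with it at Pearson r strictly above
   `r_max` (default 0.9); a dropped promoter can never cause later drops,
   and cross-batch pairs are never compared. Correlations use
   pairwise-complete non-imputed values; zero-variance promoters and pairs
   with fewer than 3 complete observations get r = 0 (never pruned on that
   evidence). Batching trades completeness for locality: some correlated
   cross-batch pairs survive by design.
3. **Age screen.** For each surviving promoter, OLS of
   age ~ intercept + promoter + sex + PMI + PC1..PCk; the two-sided t-test
   on the promoter coefficient decides retention at `alpha` (default 0.05,
   no multiple-testing correction at this stage — the raw threshold is the
   screen's definition). Implemented by residualizing age and all promoter
   columns on the adjustment design once (Frisch–Waugh–Lovell), which is
   algebraically identical to the per-promoter fits and vectorizes over
   promoters; agreement with a general-purpose OLS implementation is tested
   to < 1e−8. Promoters numerically inside the span of the adjustment
   design are flagged rank-deficient and excluded.

By default the cascade runs on the full cohort, matching the published
procedure; a leakage-safe mode restricts the statistics driving selection
to the training samples (`fit_sample_ids` / `leakage_safe`), for users who
prefer strict train/test hygiene at the cost of comparability.

## Clock

Features are the selected promoter means plus sex and PMI as ordinary
penalized columns. The munge step standardizes every column by training-set
mean and SD (constant columns standardize to zero and so receive zero
coefficients). The elastic net minimizes
(1/2n)‖y − β₀ − Zβ‖² + λ(α‖β‖₁ + ½(1−α)‖β‖₂²); the grid is
α ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 1.0} × 50 log-spaced λ values spanning three
decades down from the smallest all-zero λ, scored by 5-fold CV MSE with a
seeded shuffle. Ties are broken toward larger λ, then larger α — the
sparser model. The final model is refit on all training samples at the
selected pair (coordinate descent, tol 1e−8). Coefficients of exactly zero
are reported; features with |β| > 0 are the "contributing" set.

Evaluation reports squared Pearson correlation of predicted vs reported age
(the headline R², matching scatter-plot regression fits), the coefficient
of determination 1 − SSres/SStot, and MAE in years. Attribution uses the
exact Shapley value for a linear model with the independent-features
convention and the training means as background: φᵢⱼ = βⱼ(xᵢⱼ − x̄ⱼ)/sⱼ,
base value = intercept, so attributions satisfy local accuracy to machine
precision and identical columns receive identical attributions. Coefficient
export writes both standardized-scale and raw-scale betas with the scaling
statistics; import reconstructs a bit-equivalent predictor.

Age-gene extraction keeps promoters with |β| > 0 and screen p below a
configurable threshold, maps them to gene symbols and keeps each gene once,
ordered by its most significant promoter. The published per-cohort
thresholds are presets, not derivations.

## Legacy-clock mapping

Requested clock CpGs match an exact site when present; otherwise the
nearest same-chromosome site substitutes (absolute distance, ties to the
lower coordinate). Cross-chromosome substitution is refused — the entry is
flagged unmappable — because a CpG on another chromosome is not a
meaningful surrogate. Promoter mapping assigns each clock CpG the promoter
with the nearest TSS (distance 0 when the CpG lies inside the window) and
deduplicates the resulting promoter set. Benchmarks restrict the feature
matrix to the mapped features and reuse the ordinary fitting path with the
same seed and split, so representations are compared on identical samples.

## Synthetic cohorts

The generator emulates, per sample s and promoter p, a logit-scale latent

  logit m_sp = b_p + β_p·(age_s − mean age) + g_p·sex_s + h_p·pmi_z_s
               + (factor loadings)·factors_s + u_sp,

with inverse-logit keeping methylation in (0, 1). Components:

* **Ages** — truncated normal (default N(65, 15) on (18, 100)) or a
  two-component mixture (defaults 30/80, SD 5) reproducing the
  bimodal-vs-unimodal contrast between the two cohorts the design mirrors;
  presets `nabec_like()` (n = 187, bimodal) and `hbcc_like()` (n = 130,
  unimodal) carry the two cohort sizes.
* **Causal effects** — `n_causal` promoters get slopes of random sign and
  magnitude uniform in [0.75, 1.25] × `effect_sd` (logit units per year),
  so every causal promoter has comparable screen power. The default
  `effect_sd` = 0.03 was calibrated once so that the pipeline's own
  adjusted screen retains essentially all planted effects at the reference
  scale (200 samples, 1,000 promoters, 50 causal) while keeping each
  individual effect small (≈ 0.03 logit/year ≈ 0.7% methylation per decade
  at 50% methylation).
* **Global nuisance factors** — `n_factors` (default 25) latent factors
  with log-spaced eigenvalues (`factor_strength`, default 80 down to 15 in
  promoter-variance × promoter units) load on all promoters. They emulate
  the cell-composition and technical variation that dominates the top
  principal components of real methylation matrices — the very structure
  the screen's 20-PC adjustment exists to remove. Without them the
  strongest direction in the data is the planted age factor itself, the
  PCs absorb it, and the adjusted screen is powerless; with them the PC
  adjustment removes shared noise, as in real data.
* **Redundancy blocks** — `n_corr_blocks` blocks of `block_size` promoters
  share a latent component giving within-block correlation ≈ `block_r` and
  share their baseline (without a shared baseline the inverse logit maps
  the common latent through different nonlinear regions and the planted
  correlation attenuates below the pruning threshold).
* **Reads** — coverage per (sample, site) is negative binomial
  (mean 30, dispersion 10; at that mean ≥ 99% of sites clear the 5-read
  filter); modified counts are binomial at the inverse-logit of the site
  latent (promoter latent + site noise, SD `site_noise_sd`, default 1.5 —
  three times the promoter-level noise SD of 0.5, which is what makes
  single-CpG features markedly noisier than promoter means and drives the
  promoter-over-CpG benchmark result).
* **Determinism** — one seed drives everything; regenerating with the same
  config is byte-identical, and emitted bedMethyl files round-trip through
  the parser losslessly (frequencies carry the format's two-decimal percent
  precision).

What the simulator does *not* model: genome-realistic CpG density and
island structure, haplotype or allele-specific methylation, chemistry
differences between flowcells, nonlinear age trajectories, and spatial
correlation decay within promoters. Passing recovery tests therefore shows
the pipeline recovers the planted linear structure under realistic noise,
coverage and confounding — not that any particular biological claim holds
in real brain data.

## Validation experiments and problem sizes

* Null calibration: 20 replicate null cohorts of 100 samples × 500
  promoters; the adjusted screen's mean retention sits within ±0.01 of
  α = 0.05.
* Recovery: one cohort of 200 samples × 1,000 promoters with 50 causal
  promoters; measured quantities are causal retention through the cascade,
  withheld-set R² and MAE, and the count of causal promoters among the
  top-10 mean-|attribution| features.
* Promoter vs CpG: 20 replicates of 120 samples × 200 promoters with 40
  causal promoters; a synthetic legacy clock (one catalogued CpG per causal
  promoter) is mapped both ways and the two clocks compared on a shared
  split.

These sizes keep the full suite and the acceptance script in the
minutes range on a single CPU while leaving the conclusions stable across
seeds.

## Numerical choices and edge cases

* Exact-fraction, inclusive comparisons at the coverage (≥ 95%) and
  correlation (strictly > 0.9) boundaries.
* Zero-variance features: dropped from PCA with a warning; treated as
  r = 0 in pruning; flagged rank-deficient in the screen; standardized to
  zero (hence zero beta) in the clock.
* Train/test split takes floor(n × 0.7) training samples from a seeded
  permutation; n < 10 is refused.
* One run seed derives all stage seeds (split, CV) via a fixed integer
  derivation, so partial reruns and full reruns agree; manifests exclude
  wall-clock timings so identical runs are bit-identical.
* Matrix persistence writes floats at 17 significant digits and reads them
  back with round-trip float parsing.

## Known limitations

* The default cascade uses the full cohort before splitting; its
  selection is therefore mildly optimistic on the test set. The
  leakage-safe mode exists but is not the default, by design.
* Batched pruning leaves cross-batch redundancy in place (faithful to the
  described procedure).
* The hyperparameter grid is an explicit choice where the original
  workflow deferred to an external AutoML tool's defaults; only the elastic
  net is implemented, since it was the selected algorithm for every
  reported clock, though the fitting entry point is the natural place to
  register competitors.
* Age-gene screen thresholds are free parameters; the published per-cohort
  values are provided as presets without a derivation.
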