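# promclock

Promoter-level DNA-methylation epigenetic clocks from long-read (nanopore)
bedMethyl data.

## The problem

Epigenetic clocks predict chronological age from CpG methylation. Array-based
clocks rely on fixed probe sets; long-read sequencing instead measures
methylation at essentially every CpG, but individual long-read CpG calls are
noisy at typical coverage. Averaging methylation frequency over all CpGs in a
2 kb window centered on each promoter's transcription start site (TSS) pools
that noise away and yields features tied to regulatory elements. `promclock`
implements this workflow end to end for postmortem-brain-style cohorts:

1. **Ingestion** — parse modkit-pileup bedMethyl files (per-CpG valid
   coverage, percent modified, modified-read count), optionally merging
   per-strand records at CpG dinucleotides.
2. **Promoter features** — drop CpGs covered by < 5 reads in more than 5% of
   samples, expand EPD-style 60 bp core promoters to 2 kb TSS-centered
   windows, and average methylation over windows with ≥ 10 qualifying CpGs.
3. **Feature selection** — compute the first 20 methylation principal
   components; greedily prune promoter pairs with Pearson r > 0.9 within
   batches of 1,000 consecutive promoters (keep-first); regress age on each
   survivor (OLS, adjusted for sex, postmortem interval and the 20 PCs) and
   keep promoters with p < 0.05.
4. **Clock** — elastic net on standardized promoter means plus sex and PMI,

   min over (β₀, β) of (1/2n)·‖y − β₀ − Zβ‖² + λ·(α‖β‖₁ + ½(1−α)‖β‖₂²),

   with (α, λ) tuned by 5-fold CV on a 70/30 train/test split; evaluation by
   squared Pearson R² (and coefficient of determination and MAE) on the
   withheld 30%; per-feature Shapley attributions (exact for a linear model:
   βⱼ·(xᵢⱼ − x̄ⱼ)/sⱼ); coefficient export/import; deduplicated age-gene
   extraction (|β| > 0 and screen p below a threshold).
5. **Legacy-clock benchmarks** — map published clock CpG lists onto the
   dataset via nearest-CpG substitution, and onto deduplicated nearest
   promoters, then train clocks on each restricted feature set with a shared
   split for a like-for-like comparison.
6. **Synthetic cohorts** — because the real cohorts are controlled-access,
   a generator emulates their structure (negative-binomial coverage,
   logit-scale promoter age effects, sex/PMI nuisance, correlated promoter
   blocks, global nuisance factors, bimodal or unimodal age distributions)
   and records the planted ground truth for recovery tests.

It is aimed at researchers analysing long-read methylation cohorts and at
anyone who wants a transparent, tested reference implementation of the
promoter-aggregation clock workflow.

## Worked example

Simulate a cohort, write it in the pipeline's external formats, and run the
whole pipeline from one config:

```python
from promclock.simulate import (SimulationConfig, simulate_cohort,
                                simulate_annotation, simulate_methylation,
                                write_cohort_files)
from promclock.pipeline import RunConfig, run_all

cfg = SimulationConfig(n_samples=150, n_promoters=300, n_causal=40, seed=7)
cohort = simulate_cohort(cfg)
promoters, catalogue = simulate_annotation(cfg)
simulate_methylation(cohort, promoters, catalogue, cfg, "demo")
write_cohort_files(cohort, promoters, "demo")

manifest = run_all(RunConfig(
    bedmethyl_glob="demo/*.bedmethyl.tsv",
    promoters="demo/promoters.tsv",
    covariates="demo/covariates.tsv",
    outdir="demo_run",
    seed=7,
))
print(manifest["counts"])
print(manifest["metrics"])
```

Output:

```
{'samples': 150, 'sites_read': 7417, 'sites_kept': 7417,
 'promoters_annotated': 300, 'promoters_aggregated': 300,
 'promoters_after_prune': 300, 'promoters_after_screen': 59,
 'features_contributing': 59}
{'r2_pearson_sq': 0.662, 'r2_cod': 0.652, 'mae_years': 5.828}
```

Reading: all 7,417 simulated CpG sites clear the coverage filter (coverage
was drawn with mean 30 reads); all 300 promoters have ≥ 10 CpGs; no pair
correlates above 0.9 (windows are disjoint here), and the adjusted screen
keeps 59 promoters — the 40 planted age effects plus a near-α share of false
positives. The fitted clock predicts withheld-sample age with squared
Pearson R² 0.662 and a mean absolute error of 5.8 years. The run directory
contains the selection report, the model JSON, the re-importable coefficient
table, per-sample predictions and the Shapley importance ranking.

The same pipeline is available from the shell:

```bash
promclock simulate --seed 7 --out demo
promclock run-all --config config.yaml
```

## Analysis scripts

`analysis/01…06` run the full study narrative at desk scale: simulate a
bimodal-age and a unimodal-age cohort, build their promoter matrices, run
the selection cascade against the planted truth, train and explain the
clocks, benchmark synthetic legacy-clock CpG lists (promoter-level vs
single-CpG features), and run the statistical validation experiments.
Tables land in `results/`, bulky intermediates in `scratch/`.

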