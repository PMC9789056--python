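# gutdyn

Time-scale analysis of longitudinal human gut-microbiota profiles.

Monthly 16S profiling of the same individuals over several years raises
questions that cross-sectional beta-diversity tools do not answer
directly: do individual communities fluctuate or drift? does the
difference between two stool samples from the same person grow with the
time between them? and what fraction of the community observed at one
time point is still there months or years later?  `gutdyn` implements
the full analysis chain for such cohorts:

- **Short-term bloom detection** — a sample is a *short-term bloom* for
  a taxon when its relative abundance exceeds 5× that taxon's mean over
  all of the same individual's samples (`bloom`).
- **Interval-binned Bray–Curtis comparison** — every unordered sample
  pair gets BC(u,v) = Σᵢ|uᵢ−vᵢ| / Σᵢ(uᵢ+vᵢ); same-individual pairs are
  binned by calendar-month interval into M1 (1 month), Y1 (2–12), Y2
  (13–24) and Y3 (>24), different-individual pairs into D
  (`dissimilarity`).
- **Permutation-Wilcoxon inference** — pairwise dissimilarities within
  an individual share samples and are not independent, so the usual
  Wilcoxon critical values are invalid.  The test permutes the *time
  labels* of an individual's samples, re-bins the pairs by the permuted
  intervals, and recomputes the rank-sum statistic W to build a valid
  null (1000 replicates by default) (`longitudinal_stats`).
- **Gibbs source attribution** — for each ordered same-individual pair,
  a collapsed Gibbs sampler estimates the fraction of the later "sink"
  sample attributable to the earlier "source" sample versus an Unknown
  component, under a Bayesian mixture with Dirichlet priors
  (`source_attribution`); group means by interval quantify community
  retention over time.
- **PCoA** (classical scaling of the BC matrix) and a **Mantel screen**
  of nine per-sample covariates against community distances
  (`ordination`, `longitudinal_stats`).
- A **synthetic cohort generator** with individual-specific baselines,
  log-scale random-walk drift, sporadic transient blooms, tunable
  community turnover and multinomial sequencing noise, with ground
  truth returned for every injected effect (`synthetic_data`).
- Read-level QC (trailing <Q20 trim, ≥200 bp filter), TSV/BIOM-JSON
  table I/O, and a pipeline runner with a reproducibility manifest
  (`core_io`, `pipeline`).

## Worked example

```python
from gutdyn import (SimConfig, simulate_cohort, bray_curtis, enumerate_pairs,
                    detect_blooms, permute_timepoint_test,
                    retained_fraction_by_interval)
from gutdyn.bloom import summarize_blooms
from gutdyn.dissimilarity import group_values

months = [[24202 + m for m in (0, 1, 2, 3, 9, 15, 21, 27, 33)],
          [24202 + m for m in (0, 1, 2, 8, 14, 20, 26, 32, 38)]]
cfg = SimConfig(n_individuals=2, n_taxa=40, months=months,
                drift_sd=0.15, bloom_prob=0.2, retention_decay=0.03,
                seq_depth=5000, rng_seed=7)
table, metadata, truth = simulate_cohort(cfg)

rel = table.to_relative()
calls = detect_blooms(rel, metadata, fold_threshold=5.0)
s = summarize_blooms(calls, metadata, "genus")
print(f"blooms: {s.n_samples_with_bloom}/{s.n_samples_total} samples "
      f"({100*s.fraction_samples_with_bloom:.1f}%), {s.n_taxa_blooming} genera")

dm = bray_curtis(rel)
gv = group_values(enumerate_pairs(dm, metadata))
print("mean Bray-Curtis:",
      ", ".join(f"{g}={gv[g].mean():.3f}" for g in ("M1","Y1","Y2","Y3","D")))

res = permute_timepoint_test(dm, metadata, "P1", ("M1","Y3"),
                             reps=1000, rng_seed=1)
print(f"P1 M1-vs-Y3: W={res.observed_W:.1f}, p={res.p_value:.4f}")

means, pairs = retained_fraction_by_interval(table, metadata, rng_seed=2)
print("retained source proportion:",
      ", ".join(f"{g}={100*means[g]:.1f}%" for g in ("M1","Y1","Y2","Y3")))
```

prints

```
blooms: 3/18 samples (16.7%), 2 genera
mean Bray-Curtis: M1=0.189, Y1=0.251, Y2=0.379, Y3=0.513, D=0.588
P1 M1-vs-Y3: W=49.0, p=0.0240
retained source proportion: M1=79.8%, Y1=71.8%, Y2=51.3%, Y3=43.9%
```

Mean dissimilarity rises monotonically from one-month pairs (0.189) to
>24-month pairs (0.513) and is highest between individuals (0.588); the
permutation test confirms the M1-vs-Y3 increase for individual P1
(p ≈ 0.02 despite the dependence between pairs); and the estimated
proportion of the community retained from an earlier sample decays from
~80% after one month to ~44% after more than two years — the injected
turnover was 3% per month, i.e. an expected retention of
0.97^Δ (≈ 74% at 10 months, 42% at 28).

## Command line

Each stage is also a subcommand of the `gutdyn` console script:

```sh
gutdyn simulate --out data/ --seed 1
gutdyn run --table data/counts.tsv --metadata data/metadata.tsv \
           --out results/ --seed 1
gutdyn report --out results/
```

`run` executes qc (if FASTQ given) → blooms → distances → permutation
tests → source attribution → PCoA → Mantel → report, writes every
stage's table as TSV, and records a `manifest.json` with the config
snapshot, input/output SHA-256 digests, seed and stage timings; two
runs with the same seed are byte-identical.

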