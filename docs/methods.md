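# Methods

This note records the statistical models implemented in `gutdyn`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer would
want written down.

## Data model and time handling

All statistics operate on a taxon × sample `AbundanceTable` at one
taxonomic level plus per-sample metadata (individual, calendar
year-month, nine survey covariates).  Time is an absolute month index
(`year*12 + month`), and the sampling interval of a pair is the
calendar-month difference — *not* the difference of ordinal time-point
labels, because longitudinal schedules have gaps and the interval
groups are defined in months.  Interval groups for same-individual
pairs: M1 = 1 month, Y1 = 2–12, Y2 = 13–24, Y3 = >24; pairs from
different individuals form group D.  Same-individual pairs collected
in the same calendar month (interval 0) are excluded rather than
folded into M1, since the short-interval group means *consecutive*
months.

Relative-abundance columns must sum to 1 (tolerance 1e-9); counts
tables hold non-negative integers.  The bloom and dissimilarity stages
operate on relative abundance; the Gibbs stage needs raw counts
(read-level resampling is meaningless on closed data).

## Read-level QC

Reads are truncated at the start of their maximal trailing run of
bases below Q20 (a suffix scan — interior low-quality bases are left
alone, since only the degraded read ends are targeted), then reads
shorter than 200 bp are dropped.  The filter is idempotent.  Per-file
Q30 fraction and kept-read counts are recorded in the `QCReport` as
dataset properties but are not themselves enforced as filters.

## Short-term blooms

A (sample, taxon) is called when the taxon's relative abundance is
strictly greater than `fold_threshold` (default 5) times the taxon's
arithmetic-mean abundance over **all** of that individual's samples —
the candidate sample included, zeros included.  The inclusive mean is
the literal reading of the rule and keeps detection a deterministic
single pass; a leave-one-out variant (`exclude_self=True`) is exposed
because the two can disagree near the threshold when an individual has
few samples.  Ties at exactly the threshold are not blooms; taxa
absent from all of an individual's samples never yield calls (no 0/0).
A consequence of the inclusive mean worth knowing: a single spike's
fold is bounded by the number of samples n (the mean absorbs the spike
at weight 1/n), so the >5× rule can only fire when an individual has
more than five samples — which is also true of the rule as stated.

## Dissimilarity and the permutation-Wilcoxon test

Bray–Curtis, BC(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ), is computed on relative
abundance via `scipy.spatial.distance.pdist`.  Counts input is
rejected so that depth differences can never leak into the metric.

Within an individual, the C(n,2) pairwise dissimilarities share
samples, so they are dependent and the tabulated Wilcoxon null does
not apply.  Under the null hypothesis that composition does not depend
on collection time, the month labels of an individual's samples are
exchangeable; the test therefore permutes those labels uniformly at
random (holding the distance matrix fixed), re-bins all pairs by the
permuted intervals, and recomputes the rank-sum statistic.  Details:

- **Statistic.** W is the midrank rank-sum of the *later* interval
  group over the pooled two-group values, so large W means
  longer-interval pairs are more dissimilar and the one-sided p-value
  is the upper tail.  One-sided is the default because the scientific
  alternative is directional (dissimilarity grows with interval);
  `alternative="two-sided"` is available.
- **Replicates.** 1000 by default.  Permutations that leave either
  group empty are discarded and redrawn up to 10× the requested count
  (sparse schedules can empty M1); the achieved count is reported.
- **p-value.** Add-one estimator (1 + #{W_null ≥ W_obs}) / (1 + R),
  so p is never exactly 0.
- **Critical values.** The 90th/95th/99th percentiles of the null are
  reported alongside p; the choice of percentiles is configurable
  since no canonical set exists for this construction.
- **Pooled test.** `individual_id=None` permutes labels independently
  within every individual and pools the group values across
  individuals.

Calibration is verified by simulation: with drift switched off the
samples are exchangeable and the measured type-I error at α=0.05 over
200 simulated individuals sits inside the binomial 95% band; with
strong drift power exceeds 80% (see `tests/test_acceptance.py`).

## Gibbs source attribution

For every ordered same-individual pair the earlier sample is the sole
known source and the later sample the sink; a two-component mixture
(source + Unknown) is the model actually needed for "how much of the
earlier community remains", and keeps each pair's estimate
interpretable.  The collapsed Gibbs sampler assigns each sink read i
(taxon tᵢ) to an environment z ∈ {source₁..source_V, Unknown} with

    P(zᵢ = v | z₋ᵢ) ∝ P(tᵢ | v) · (n_v^{−i} + β)

where n_v^{−i} is the number of other sink reads currently assigned to
v (Dirichlet(β) prior on mixing proportions, β = 10), and

- known source: P(t|v) = (m_vt + α₁) / (depth_v + α₁T), fixed from the
  source counts, α₁ = 0.001;
- Unknown: P(t|U) = (u_t + α₂n) / (n_U + α₂nT), learned from the reads
  currently assigned to Unknown, with the prior scaled by the sink
  depth n (α₂ = 0.1) so the Unknown starts near-uniform and cannot
  simply memorize the sink's sampling noise.

Defaults follow the published defaults of the SourceTracker family:
burn-in 100 sweeps, 10 independent restarts, 1 draw per restart;
reported proportions are posterior means across draws (restarts
averaged), with their SD.  Sink and sources are rarefied to a common
depth — the minimum available depth capped at 1000 by default — which
bounds runtime at cohort scale without depth artifacts; an explicit
`rarefaction_depth` larger than the available counts is an error, not
a silent resample-with-replacement.  The inner loop is compiled with
numba (pure-Python fallback if unavailable); chains are seeded per
restart from a `SeedSequence`, so identical seeds give bit-identical
estimates.

Validation: a sink identical in composition to its source recovers
>0.9 source proportion at depth 1000; a sink disjoint from the source
goes >0.9 Unknown; 70/30 two-source mixtures at depth 2000 are
recovered with mean absolute error ≤0.05 and the estimate is monotone
in the true weight.

## PCoA

Classical scaling: B = −½·J·D²·J with J = I − 11′/n, eigendecomposed;
coordinates are eigenvectors scaled by √λ for positive eigenvalues
(relative tolerance 1e-9 on the leading eigenvalue).  Bray–Curtis is
non-Euclidean, so negative eigenvalues occur; they are dropped and
their total magnitude reported, with no Cailliez/Lingoes correction —
the convention of reporting the uncorrected embedding.  Variance
explained is λ / Σλ₊ over positive eigenvalues.  Axis signs are fixed
by forcing each axis's largest-magnitude loading positive, making
output deterministic.

## Mantel screen

Factor distances are |difference| for numeric covariates (date, blood
pressure, blood sugar) and 0/1 mismatch for categorical ones
(participant, workspace/office, drug use, yogurt, fruit, travel).  r
is the Pearson correlation of the vectorized upper triangles (Spearman
available); p is the upper-tail proportion over random row/column
relabelings of the factor matrix, add-one estimated, or exact
enumeration over all n! relabelings for tiny n (used as the oracle in
tests).  A constant factor returns a result flagged `undefined` rather
than dividing by zero.  The nine factors are reported raw, without
multiplicity correction, as an association screen.

## Synthetic cohort generator

Per individual: a baseline log-abundance vector (cohort-level taxon
means ~N(0, `taxon_sd`²), default 2.0, giving the realistic few-dominant/
many-rare profile, plus individual offsets ~N(0, `baseline_sd`²),
default 1.0); between consecutive samples Δ months apart the
composition drifts by exp(N(0, Δ·`drift_sd`²)) per taxon and is
re-closed, then a fraction 1−(1−`retention_decay`)^Δ is replaced by a
fresh sparse Dirichlet(0.2) pool (so the expected retention over an
interval Δ is (1−r)^Δ, recorded as ground truth).  Each emitted sample
independently receives, with probability `bloom_prob`, a transient
50-fold spike of one uniformly chosen taxon (applied to the observed
composition only, not the latent state — blooms do not propagate).
Counts are multinomial at `seq_depth` (default 30 000), so columns sum
to the depth exactly.

The default design mirrors a 7-individual cohort sampled monthly over
a 44-calendar-month window (Oct 2016–May 2020): 37 candidate months,
each individual observed at 15–31 of them.  Default dynamics
(`drift_sd` 0.15/month, `bloom_prob` 0.1, `retention_decay`
0.02/month) were chosen once to produce the qualitative structure of
real longitudinal gut data — within-individual dissimilarity below
between-individual, growing with interval, retention decaying from
~80–90% at one month to ~40–50% beyond two years.

What the generator does **not** emulate: phylogenetic correlation
between taxa, strain-level dynamics, compositional overdispersion
beyond multinomial, covariate effects on composition (covariates other
than the designated linked factor are independent of the community),
and seasonal or episodic (diet, travel, antibiotic) structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under a plausible generating process, not the field accuracy
of any biological conclusion.

## Problem sizes in the test and acceptance runs

The test suite calibrates the permutation test on 200 simulated
individuals (200 replicates each), measures power on 100, checks Gibbs
recovery on 10 mixture seeds and retention decay on 10 two-individual
cohorts, sizes chosen as the smallest giving stable Monte-Carlo
verdicts.  `scripts/acceptance.py` runs the full default-scale cohort
(≈160–170 samples, ≈1900 ordered pairs through the Gibbs sampler at
rarefaction depth 1000, 1000-replicate tests, 999-replicate Mantel).

## Known limitations

- The permutation null assumes exchangeability of samples within an
  individual under H₀; trends other than interval-dependent
  dissimilarity (e.g. batch drift aligned with time) also violate it
  and will be detected as "time" signal.
- The two-component source model attributes any taxon shared by chance
  between source and sink to the source; retention estimates are upper
  bounds in that sense.
- BIOM support covers the JSON (1.0) format only.
- The bloom rule is scale-free but depends on the number of samples
  per individual (fold capped near n); cross-individual comparisons of
  bloom counts should keep schedules comparable.
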