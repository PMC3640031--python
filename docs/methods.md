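# Methods

This note records the models, numerical conventions and design choices
behind `brulechip`, and what the synthetic-data tests do and do not
establish about real data.

## The experimental design being modelled

Two niches are compared: inside a truffle brûlé (`IN`) and the
surrounding soil (`OUT`). The array arm follows a single-site design
with three replicate soil-DNA pools per niche hybridised to a
phylogenetic microarray; the fingerprint arm follows a four-site design
with four replicate gel lanes per niche per site. Group labels,
replicate counts and site structure are all configurable; the defaults
are these study shapes.

## OTU calling

### Response scores and probe-set quantiles

The chip represents each OTU by a probe set of PM/MM pairs. The
per-pair response score is

    r = max(0, (PM − MM) / (PM + MM)),

bounded in [0, 1], monotone in the PM excess, and undefined (pair not
scorable) when PM + MM = 0. A pair is **usable** when its PM exceeds
the array's background level and, when a saturation ceiling is
configured, sits below it. `pairs_counted` counts usable pairs,
`pairs_scored` usable pairs with a defined score, and q1/q2/q3 are the
25/50/75th percentiles (linear interpolation) of the usable scores.
Published PhyloChip analyses state the q-cutoffs but defer the score
and quantile definitions to supplementary material; the definitions
above are this package's explicit instantiation, kept behind one
scoring function so an alternative can be swapped in.

The **background level** is the 2nd percentile (configurable) of all
probe intensities on the array; no published rule exists, and a low
per-array quantile is scale-invariant under array-level rescaling.

### Cutoffs

Bacterial Stage 1: present iff pairs_counted ≥ 7 ∧ pairs_scored ≥ 7 ∧
q1 ≥ 0.5 ∧ q2 ≥ 0.93 ∧ q3 ≥ 0.98. Archaeal OTUs use the loosened
q2 ≥ 0.8 ∧ q3 ≥ 0.9, applied only to OTUs with a trimmed-mean
intensity ≥ 1000 units in at least one sample — an OTU-level
eligibility gate evaluated before the per-sample q-cutoffs, on
**post-spike-scaling** intensities (the pre/post choice is unstated in
the source analyses; post-scaling keeps the gate comparable across
arrays). All boundary comparisons are inclusive (≥). Stage 2 flags
pairs shared with cross-hybridising neighbour OTUs that are themselves
Stage-1-present in the same sample, recomputes q3 on the unflagged
usable pairs (0 if none remain), and retains the call iff the adjusted
q3 ≥ 0.1. Removal-and-recompute (rather than down-weighting) is the
simplest penalty consistent with "new q3 values"; every removal is
logged.

### Spike rescaling and trimmed means

Each sample's intensities are multiplied by (grand mean of per-sample
spike means)/(that sample's spike mean). The operation is idempotent
and equalises spike means across arrays to numerical precision. OTU
intensity per sample is the trimmed mean of the probe set's PM
intensities — arithmetic mean after removing exactly one maximum and
one minimum occurrence; probe sets with fewer than three pairs fall
back to the plain mean (logged).

## Differential analysis

Intensities (trimmed means of detected OTUs) are log10-transformed,
then each OTU row is centred and scaled to SD 1 (sample SD, n−1)
across all samples. Rows with nonpositive values or zero variance are
excluded and logged. The per-OTU test is a **pooled-variance two-sided
t-test** with unadjusted p-values; the t statistic is invariant to the
per-row affine standardisation, so this equals testing the log
intensities directly.

The pooled default is a deliberate choice: at three replicates per
group, Welch's unequal-variance test is markedly conservative (measured
rejection ≈ 0.033 at a nominal 0.05 on clean lognormal nulls), whereas
the pooled test is exact under the null at the balanced design, where
the two variants coincide in their statistic and differ only in degrees
of freedom. Welch remains available (`welch=True`), as does
Benjamini–Hochberg adjustment (`adjust="fdr_bh"`); both are off by
default to match the unadjusted-p presentation style of the analyses
being reproduced.

Heatmap OTUs must satisfy p < α (strict) **and** a ≥ 1.8-fold
difference (inclusive, direction-agnostic) of untransformed group
means; the fold filter is evaluated two-sidedly (fold ≥ 1.8 or
fold ≤ 1/1.8) so the inclusive boundary is exact in floating point.
The 1.8 default is configurable (some presentations describe the same
filter as "nearly 2-fold"). Discriminative-taxon percentages are
rounded half-up to integers.

## Structure test

For one taxon's standardised submatrix (OTUs × samples), samples are
the PCA observations. With sample scores on the first
K = min(3, rank) components and variance fractions wₖ, the statistic
is

    T = Σₖ wₖ · (mean scoreₖ(IN) − mean scoreₖ(OUT))².

The null distribution enumerates **all** relabellings of the samples
into groups of the observed sizes, with the component scores held
fixed; p is the fraction of relabellings with T at least the observed
value (observed included). At 3v3 this gives C(6,3) = 20 assignments =
10 distinct splits and a smallest attainable p of 0.1 — at this design
the test can flag a taxon at the 10% level but never at 5%. The
statistic is one concrete instantiation of a first-three-PC group
test (the original method's exact statistic is not published in the
reproduced analyses) and is isolated behind a single function. Taxa
with fewer than 10 OTUs (configurable) are reported untested.

## Fingerprint analysis

Lane profiles are normalised to unit total intensity (Pearson r is
affine-invariant per lane, so this is numerical hygiene, not a model
choice; background subtraction is out of scope and profiles are assumed
pre-aligned to a common grid). Similarity is 100·Pearson r. UPGMA
merges the pair of clusters with the largest average similarity; node
heights equal the merge dissimilarity (100 − similarity), ties break
toward the lexicographically smallest member label (logged), and
dendrograms are written as newick.

"Percent dissimilarity" of two groups is defined here as

    d = mean within-group similarity − mean between-group similarity,

in percent points — consistent with published tables where small d
values (≈1–21) coexist with within-group similarities above 83%. The
null permutes group labels over lanes, within site strata for pooled
tests; p = (#{d* ≥ d} + 1)/(n_perm + 1) with 1000 permutations by
default, switching to exact enumeration (observed included) whenever
the design admits fewer distinct labellings than requested — per-site
4v4 tests are therefore always exact with 70 labellings and a minimum
attainable p of 1/35. The original PERMTEST statistic is not published;
d is documented in all output headers.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture.

**Array arm.** Presence is i.i.d. Bernoulli per (OTU, sample) with
`presence_prob` (default 0.85, giving the high-but-incomplete niche
overlap characteristic of deep soil surveys). A present OTU's PM
intensity per pair is `background·exp(σZ) + S·fold^g·exp(σZ′)` with
`S = pm_signal_mean` (default 10 000), background 25, σ = 0.3
(`lognormal_sigma`; fluorescence is positive and right-skewed, hence
multiplicative lognormal noise), and g = 1 for IN samples. MM sees its
own background plus `mm_leak_fraction` (default 0.002) of the PM target
signal — the leak sets the response-score ceiling, so Stage-1 cutoffs
are exercisable from both sides. Cross-hybridising neighbour pairs
(adjacent OTUs within a phylum, rate `crosshyb_rate`) leak each other's
signal, which is what makes Stage 2 consequential. Spike probes carry a
fixed mean; every probe is finally multiplied by a per-array factor
`exp(N(0, array_scale_jitter))`. The default taxonomy is desk-scale
(10 phyla × 50 OTUs, one archaeal phylum) rather than a ~59 000-OTU
chip; the full scale is reachable through the same fields. Fold-change
effects are planted per OTU or per taxon via the `effects` map.

**Fingerprint arm.** Each lane is a sum of Gaussian band profiles
(positions, lognormal amplitudes and per-(site, band) multipliers drawn
once) plus half-normal noise; each band enters a lane with its group's
presence probability, and `n_shifted_bands` bands get niche-specific
probabilities — the planted community difference. Site-level amplitude
multipliers create genuine among-site differences, so the among-sites
test has signal.

**What the simulations do not capture.** Technical replicate structure
beyond one scale factor per array (no probe-specific affinities, no
spatial artefacts); biological replicate variation is folded into the
per-pair lognormal term rather than modelled hierarchically; gel bands
are independent Bernoulli draws (no co-migrating species, no smile
distortion or band-calling error). Passing tests therefore establish
that the *procedures* are implemented correctly and calibrated under
their stated assumptions — not that real arrays or gels satisfy those
assumptions.

## Test-condition choices

Simulation conditions for the headline checks were fixed a priori:

* **Noise-free recovery** uses σ = 0, zero MM leak, no cross-hyb and a
  signal-to-background ratio (10 000 : 20) whose closed-form score
  0.996 clears every cutoff, so calling must reproduce planted presence
  exactly; random presence probabilities, probe-set sizes and array
  jitter vary across 100 configurations.
* **Type-I calibration** of the per-OTU test uses fully present OTUs
  (clean lognormal nulls) and a dense spike set (2 000 probes). With
  the default 24 spikes, the spike-mean estimation error
  (σ/√24 ≈ 0.06 log-units) is a per-sample shift *shared by every
  OTU*, which turns 1 000 "independent" nulls into one correlated
  family and makes the flag rate swing far outside binomial bounds —
  an instructive property of spike normalisation itself, but not what
  a marginal-level measurement wants. Fingerprint calibration uses the
  pooled four-site design with 999 random stratified permutations
  (attainable rejection rate 49/1000), because a single 4v4 site is
  exact with only 35 distinct splits and its attainable rate at
  α = 0.05 is 1/35 ≈ 0.029 by discreteness alone.
* **Planted recovery** uses σ = 0.1 with a 4-fold effect on 50 fully
  present OTUs (array arm), and 12 niche-exclusive bands on a
  deterministic band backbone (`band_presence_prob = 1`) with default
  profile noise (fingerprint arm) — the "highly reproducible
  replicate profiles" regime of real gels.

## Numerical conventions and degenerate inputs

* Quantiles: `numpy.percentile` linear interpolation throughout; the
  Stage-2 adjusted q3 of an emptied pair set is 0.
* Probe sets with zero usable pairs yield metrics with
  pairs_counted = 0 and NaN quantiles — never an exception — and are
  called absent.
* Two-group t on counts with zero variance in both groups: p = 1 when
  the means agree (logged), p = 0 otherwise.
* Degenerate per-OTU variance gives an undefined p and direction
  `none` (logged); zero-variance or nonpositive intensity rows are
  excluded from standardisation (logged).
* Permutation ties are handled with a 1e-12 slack on the ≥ comparison
  so the observed labelling always counts itself.
* Zero-variance fingerprint lanes raise an error naming the lane.
* Seeds: every stochastic routine takes an explicit seed or derives
  child seeds from one `numpy` Generator; fixed seeds give
  byte-identical generator output.

## Known limitations

* The Stage-1 score/quantile definitions and the exact PERMTEST and
  PC-test statistics are this package's documented instantiations of
  procedures whose originals are not fully published; all four sit
  behind single functions for substitution.
* The structure test cannot reach p < 0.1 at 3v3 by construction.
* Binary array formats (CEL) and gel images are out of scope; the
  package ingests text matrices and digitised lane profiles.
* Percent dissimilarity values are comparable within this package but
  not necessarily to published tables computed with other statistics.
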