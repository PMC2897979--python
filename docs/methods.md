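# Methods

## The measurement model

A rifampicin chase blocks transcription initiation at *t* = 0; each
transcript's subsequent signal *E*(*t*) reflects degradation only. Signals
are linear hybridization intensities sampled on the fixed grid
{0, 2.5, 5, 10, 20, 40, 60} minutes in three biological replicates. All
fitting is ordinary least squares of log2 *E* on *t*: on the log2 scale an
exponential decay is a line whose negative slope *k* is "twofolds per
minute", and 1/*k* is the time per twofold change in minutes — the natural
unit for both estimators. Any fixed log base gives identical fits and MSE
rankings; log2 makes the twofold step literal.

Replicates are averaged per timepoint before fitting, which yields the one
half-life per gene that a chase study reports; each replicate is also refit
separately and the standard error of those per-replicate estimates is
attached to the mean-fit value. Non-positive or missing intensities are
masked pointwise (a log fit cannot consume them); a gene stays fittable while
at least four unmasked points remain.

## Half-life: the twofold decay step

Find the earliest sampled *t_j* > 0 within the 60-minute horizon with
*E*(*t_j*) ≤ *E*(0)/2 and fit the exponential through the two points
(0, *E*(0)) and (*t_j*, *E*(*t_j*)); the half-life is that segment's time per
twofold, `(t_j − 0)/log2(E(0)/E(t_j))`. Restricting the fit to the first
twofold step makes the estimate robust to late-time flattening. If no
twofold decrease occurs, the fallback is a single fit over all timepoints,
whose time-per-twofold can be arbitrarily large or negative (rising
profiles); such transcripts are flagged stable. The stability rule is:
stable ⇔ half-life > 60 min (the chase horizon) or negative.

## Decay rate: the relative two-phase model

Many profiles show two regimes — fast-then-slow decay, or a delay (flat or
rising) followed by decay. The two-phase model:

1. **Onset.** *t*<sub>on</sub> is the last sampled timepoint attaining the
   profile maximum. Decline is measured relative to it, which separates
   degradation speed from onset lag.
2. **Breakpoint search.** For every sampled candidate *x* strictly between
   *t*<sub>on</sub> and 60 min that leaves ≥ 2 points per segment, fit one
   exponential on [*t*<sub>on</sub>, *x*] and one on [*x*, 60]. The
   breakpoint belongs to both segments; the pooled MSE is the sum of both
   segments' squared log2 residuals divided by the total residual count
   (the breakpoint counted twice). The *x* with minimal pooled MSE wins;
   exact ties (a pure exponential makes every candidate perfect) break to
   the earliest *x*, applied with a 1e-12 relative floating tolerance.
3. **Reported rate.** The decay rate is the first phase's time per twofold.
   The first phase is the decline immediately after onset, which is the
   quantity a delayed-onset transcript's "degradation speed" refers to; a
   flag on `polymerase_velocity` (and the stored second-phase fit) exposes
   the alternative readings.

At least four usable points at or after the onset are required; otherwise
the gene is reported with the twofold method only and flagged.

Two known behaviours are inherent to the estimator pair, not defects: a
delayed-onset transcript has half-life > decay rate (the gap measures onset
lag), and on noisy plateaus the unique maximum can land early, letting the
first phase span plateau points and inflating the decay rate — the same
inversion (decay rate exceeding half-life) seen in saturated, highly
expressed transcripts in real chase data.

## Genome-wide summaries

Medians and the 10th/90th percentile interval of half-life are computed over
genes with positive finite estimates: a negative fallback value means "no
measurable decay" and would corrupt a central-tendency statistic, while
positive stable values (> 60 min) are included. The stable fraction counts
all fitted genes. Subset medians (e.g. an ncRNA/asRNA panel) follow the
reporting-cap convention: rates above the cap (default 20 min, rendered
">20") are excluded from the subset median.

## Preprocessing

Genes whose mean *t* = 0 signal falls below the expression threshold
(default 100 intensity units, the same floor used for single probes) are
excluded before fitting; the threshold is the one deliberately free
parameter of the pipeline and is recorded in the run manifest. Four scaling
schemes are available — none, all-genes median, spike-control median,
stable-RNA-gene median — each multiplying every array (one replicate at one
timepoint) by a single constant so the reference set's median matches the
grand median across arrays. "Median" interprets the ambiguous "medium
intensity" of array-scaling practice; it is robust and preserves
within-array ratios exactly. The default is no scaling: in a chase
experiment *every* transcript falls, so the equal-distribution assumption
behind global scaling is violated, and scheme choice is meant to be ranked
empirically by concordance (mean per-gene Spearman correlation) against a
qPCR standard computed as 2^−(dCt_gene − dCt_ref) per timepoint.

## Operon analysis

Distances are start-codon to start-codon, strand-aware (a minus-strand
gene's start codon is its upper coordinate), anchored at the operon's first
gene — the same anchor used for probe positions. Predicted operons are
excluded as `weak_expression` when the median member *t* = 0 signal is
below the expression threshold (or fewer than two members are present), and
as `inconsistent_profiles` when any adjacent member pair's Spearman
correlation of *t*0-normalized mean profiles falls below ρ_min = 0.7;
both thresholds are configurable and every exclusion reason is logged.
Seven-point Spearman is coarse, so ρ_min = 0.7 is deliberately tolerant;
genuinely unrelated profiles score far lower.

Typing normalizes each member's mean profile to *t* = 0. Type II requires a
member at operon position ≥ 2 whose normalized signal rises to at least
1 + δ (δ = 0.2) at some *t* > 0 and declines afterwards; otherwise type I.
δ = 0.2 sits well below the up-to-twofold rises of genuine distal inductions
and well above the ≈ ±5 % excursions of replicate noise at σ = 0.05, giving
a wide separation margin.

## Polymerase velocity

For each eligible gene (monocistronic or first in its operon, ≥ 2000 nt,
probes every 80 nt passing the *t* = 0 filter), each probe *i* > 1
contributes *s_i* = *p_i* − *p_1* nt and *t_i* = estimate_i − estimate_1
min, giving *v_i* = *s_i*/(60 *t_i*) nt/s. Pairs with *t_i* ≤ 0 are excluded
and counted — a non-positive lag carries no elongation information. Global
mean ± SE and median pool all retained pairs (per-gene aggregates are also
reported), separately for the half-life and decay-rate metrics, plus an
optional onset-time variant. The pair distribution is right-skewed (small
lags inflate single velocities), so the median is the robust headline
number — means run higher.

## The synthetic generator

Each transcript follows a continuous piecewise curve: a linear ramp on
[0, *d*] to (1 + *a*)·*E*0 (flat when the rise amplitude *a* = 0), decay
with half-life *h*1 until the phase break *b*, then *h*2, joined
continuously. Replicate noise is multiplicative log-normal (intensity data
have roughly constant CV; default σ = 0.1, with σ = 0.05 for the
probe/typing benchmarks where the study's own validation showed tight
replicates), and signals clip at a saturation cap, reproducing the
inflated array half-lives of very abundant transcripts. Per-gene RNG
streams are split from the fixture seed by stable id hashing, so adding
genes never perturbs existing draws.

Operon fixtures impose the 5'→3' wave: gene *g* at distance *s* gets onset
delay *s*/(60*v*) and a half-life growing 30 % per kb by default; type II
members additionally get rise amplitudes growing with distance up to 1.0
(a twofold distal peak). Genome fixtures mix monocistrons (log-normal
half-lives, median 2.4 min, log-sd 0.8, matching a fast-turnover
transcriptome with 80 % of values spanning roughly one decade), 3 % stable
RNA-gene-like transcripts, and 50 operons with a 41:9 type I:II split.

**Probe-level fixtures and velocity identifiability.** The wave reaching
position *p* at *p*/(60*v*) minutes can be encoded as a delayed onset, as
increased persistence (the probe's measured half-life exceeds the first
probe's by the lag), or both; distal segments of real transcripts show both
delay and slower decay. The canonical velocity benchmark uses the
persistence encoding. The reason is identifiability, not convenience: a
pure onset plateau is only observable through which sampled timepoint first
shows a twofold drop, so on the coarse chase grid the twofold estimate of a
delayed probe is `t_j·h/(t_j − d)` with `t_j` the first grid point past
`d + h` — the estimated lag is exact only when `d + h` lands on the grid
and is otherwise compressed by up to the local grid gap (2.5–20 min),
which no realistic half-life can dominate. A persistence shift, by
contrast, is measured exactly by the twofold fit at any grid point (with
`d = 0` the two-point fit returns *h* identically), so the fixture tests
the velocity arithmetic *v* = *s*/*t* rather than the grid's rounding.
Under this encoding both paper metrics (half-life and decay-rate
differences) are exact at zero noise and agree, and doubling the generator
velocity exactly halves every lag.

What passing on these fixtures does *not* show: recovery under probe-level
affinity differences, cross-hybridization, mismatch-probe effects, or onset
quantization on real tiled arrays — the generator has no probe-sequence
model, and onset-dominated waves remain grid-limited as analysed above.

## Clustering and enrichment

Profiles are the replicate-mean log2 series, centered and scaled to unit SD
per gene (constant profiles are excluded); standardization makes Euclidean
fuzzy c-means compare shapes, not levels. FCM uses fuzzifier *m* = 2,
seeded random membership initialization, best of 5 restarts by objective,
and stops when the largest membership change drops below 1e-6 (cap 300
iterations); the objective is non-increasing across iterations and runs are
bit-reproducible for a fixed seed. Hard labels are membership argmax;
"well supported" means max membership ≥ 0.5.

Enrichment of a category (K of N universe genes) in a cluster of size n
containing k members is the hypergeometric upper tail P(X ≥ k) (k = 0 gives
p = 1), Bonferroni-adjusted over all cluster × category tests — chosen over
FDR because single extreme categories, not a discovery list, are the object;
reported p-values floor at 1e-16. The cluster number is chosen to maximize
the count of significantly enriched (cluster, category) pairs, ties to the
smallest c. That score only has an interior maximum when categories are
informative but not trivially so: with large pure categories, merged
clusters stay significant (the score plateaus) and split clusters can stay
significant (the score keeps rising), so the planted-structure test fixture
uses small labeled subsets (6 of 20 per group) and α = 1e-4, making merges
lose significance and splits lose power — the score then peaks exactly at
the planted group count. Real category tables sit between these regimes;
the per-c score table is always returned for inspection.

## Numerical conventions and edge cases

* Two-point segments fit exactly (MSE 0); flat segments report k = 0 and an
  infinite time-per-twofold rather than dividing by zero.
* Breakpoint ties break to the earliest candidate within 1e-12 relative MSE.
* Spearman p-values use the large-sample t approximation and are floored at
  1e-16 for reporting ("≤ 1e-16"), matching how extreme genome-scale
  correlations are printed.
* Scaling factors are one constant per array; within-array ratios are
  preserved to machine precision.
* All TSV output is written with 10 significant digits; manifest digests
  are SHA-256 over bytes, so determinism checks are exact.

## Problem sizes

The test suite and acceptance script run on desk-scale fixtures chosen to
exercise every code path with comfortable statistical margins: 500-gene
recovery panels, a 1,000-gene genome fixture with 50 operons for the
summary statistics, a 20-gene (≈ 700-pair) probe fixture for velocity, and
1,000 random profiles for the breakpoint-oracle comparison. Larger inputs
are read from TSV/GEO files rather than shipped.

## Known limitations

* The two-phase model fits exactly two segments on the sampled grid; it
  does not optimize continuous breakpoints or more phases, and onset
  detection inherits the grid's resolution.
* Decay rates of noisy plateau genes can be inflated (see above); the
  half-life column is the robust companion in that regime.
* The generator's saturation is a hard clip and its type II rise a linear
  ramp — simple shapes that produce the observed phenomenology without
  modelling polymerase queues or nuclease processivity.
* Velocity estimation assumes the first probe is the 5' reference; genes
  with internal promoters violate that silently.
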