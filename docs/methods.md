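# Methods

This note documents the models behind each analysis stage, the
parameters that matter with their defaults and rationale, what the
synthetic generator does and does not emulate, the numerical choices,
and known limitations.

## Contact maps and conventions

Coordinates are 0-based half-open everywhere, including BED output.
Bin ids are genome-wide consecutive (chromosomes concatenated), which
lets a single integer pair address cis and trans interactions alike;
on disk the HiC-Pro triplet dialect uses 1-based ids and upper-triangle
storage. Lower-triangle input records are folded onto the upper
triangle; duplicate keys are summed with a warning (tolerant dialect).
Bin marginals — used by the maximal-resolution rule — include trans
contacts by default and count the diagonal once; a cis-only mode is
exposed because read-level bookkeeping of "valid interactions per bin"
could be defined either way upstream.

## ICE balancing

Per chromosome, multiplicative per-bin biases are estimated by
marginal-equalization iteration: bins below the 2% coverage quantile
(and zero-marginal bins) are masked, marginals are iteratively divided
out until their relative coefficient of variation falls below 1e-5
(≤200 iterations), and biases are rescaled to geometric mean 1 so the
normalized map is `raw / (bias_i · bias_j)`. The filtering quantile is
a free choice: the masked fraction only needs to remove bins whose
near-zero coverage would otherwise absorb the iteration. Balancing is
idempotent and recovers planted biases on a pre-balanced kernel to
r > 0.999.

## Cyclic loess

Cross-sample normalization for count tables (and boundary IS matrices)
follows the pairwise MA construction: for every sample pair, the lowess
trend of M = log-ratio against A = average log abundance (prior count
0.5, span 0.3) is split evenly between the two samples' offsets. All
fits of one cycle are taken from the same offset state and averaged
over the n−1 pairs each sample participates in, then offsets are
re-centered per feature; two cycles are run. The batch update makes
the result exactly invariant to sample order. Offsets are on the
natural-log scale with the GLM convention `log E[y] = Xβ + offset`: a
sample with doubled counts receives an offset difference of ln 2.

## SCC replicability

The replicability index between two maps is the stratum-adjusted
correlation: both cis matrices are smoothed with a (2h+1)² mean filter
(h = 1 bin), Pearson correlations are computed per genomic-distance
stratum from 1 bin up to 5 Mb, pooled across chromosomes, and combined
with Cochran weights N_d·sd(X_d)·sd(Y_d). The diagonal stratum is
excluded (self-contacts are dominated by coverage, not structure).
Parameters of the original index are not published for this design, so
SCC is validated by its properties (1 on identical maps, ≈0 on
independent noise, monotone in shared structure), not by printed
values.

## A/B compartment calling

The classic eigenvector recipe: ICE-balance the cis matrix, divide each
diagonal by its unmasked mean (observed/expected), take the Pearson
correlation matrix of the O/E columns, and use the leading eigenvector
E1. Masked bins are NA. The eigenvector sign is arbitrary, so it is
oriented by an external covariate — gene density by default — such
that positive-E1 bins have the higher mean covariate; A = E1 > 0.
Calling is invariant to scaling the input map. Residual NaN cells in
the O/E submatrix (empty diagonals) are set to the neutral value 1
before correlation.

Segment counting merges maximal same-label runs; NA runs flanked by
the same label are bridged by default (missing data should not create
boundaries), exposed as a flag since the alternative convention is
defensible.

**Fragmentation test.** Segment counts per chromosome/sample are
modelled as Poisson with log link: `log E[y] = α·c + β·group`, with c
the chromosome's total valid interactions rescaled to millions (for
conditioning) and the group effect tested by Wald z. On the 3-chromosome
toy genome this test is underpowered (the report still shows the d110
count excess); calibration and power are demonstrated at the realistic
18-chromosome scale in the test suite (type-I within [0.02, 0.08] over
500 null runs; ≥90% power for a 30% count increase).

**Switches and consistency.** A bin switches A→B when all three d90
replicates call A and all three d110 replicates call B (symmetrically
B→A); bins unassigned in any sample are excluded. The consistency
statistic is the fraction of fully-assigned bins with one label 6/6;
its null shuffles the order of each sample's label segments per
chromosome (preserving run lengths and A/B totals), a stricter null
than bin-shuffling because it keeps the autocorrelation structure.
Empirical p-values use add-one smoothing: p ≥ 1/(n_perm+1).

## TAD comparison and boundary insulation

TAD calling is upstream; this package consumes call sets. Identity is
reciprocal overlap ≥ 90% of both intervals. Identity is not
transitive, so the stable set (identical in all six samples) anchors on
sample 1's intervals as representatives, and group-specific sets pool
candidates over the group's replicates, require a match in all three
own-group sets and none in the other group, then collapse duplicates
greedily by identity.

The interaction score of a boundary is the proportion of contacts
crossing it among all contacts within ±500 kb (both bins inside the
window; denominator includes same-side pairs and the diagonal), from
50 kb maps. Boundaries whose window leaves the chromosome are NA and
excluded. IS values are loess-normalized across samples on the log
scale (prior 0.01) and ΔIS = mean(d110) − mean(d90), so negative ΔIS
means contacts were lost across the boundary between stages — the
signature of a boundary that strengthens or appears by d110. The
recovery harness evaluates ΔIS at the planted group-specific boundary
classes (~58 per class on the toy genome); the pipeline report also
scores the called (recovered) boundaries.

## Differential interactions

The count table unions bin-pair keys across the six samples at 500 kb,
zero-filling absent keys; keys with fewer than 30 reads total are
discarded; cyclic-loess offsets absorb library-size and trend effects.
Each key is tested with a negative-binomial GLM — log link, group
fixed effect, per-observation offsets, variance μ + φμ² — fitted by
IRLS (the group-saturated design reduces each update to weighted group
means; ≤100 iterations, relative log-likelihood tolerance 1e-8,
coefficients clipped to ±50). The likelihood-ratio statistic against
the intercept-only null is referred to χ²(1); non-converged keys get
NA p-values and are excluded from FDR. logFC is log2 with d90 as
reference, so positive means stronger contact at d110.

Dispersion is estimated by Cox–Reid adjusted profile likelihood
(subtracting 0.5·Σ_g log Σ_{i∈g} w_i from the profile), alternating
three rounds of fitting and 1-D bounded optimization of φ. The
adjustment matters: plain profile ML with 2 parameters in 6
observations underestimates φ by ~40% and inflates the type-I error to
~0.12; with the adjustment the null rejection rate at 0.05 is ~0.05.
A tagwise mode shrinks per-key grid MLEs toward the common value on the
log scale with prior_df = 10. The estimator approximates, and does not
replicate, the empirical-Bayes machinery of the established count-GLM
packages; one of those packages serves as an independent oracle in the
Poisson limit (LRT agreement to <1e-3).

BH FDR is applied genome-wide across cis and trans jointly, threshold
0.05 (the upstream choice is not published; 0.05 is configurable).

## BODIs

Each significant cis DI increments both endpoint bins with its logFC
sign. A bin is positive (negative) when the majority sign outnumbers
the minority at least 10:1 — the operative reading of the "90% same
sign" rule, with ties undefined and untouched bins none. Adjacent
same-sign bins merge into blocks; none terminates a run; blocks never
span chromosomes. The permutation null shuffles logFC values over the
fixed DI keys (100 permutations) and compares, per sign, the count of
blocks of size ≥ s (the cumulative reading of "at least as frequent
for a given size"); add-one smoothing bounds p at 1/101. Composition
against A/B segments is measured in bp and tested as a 2×2 Fisher exact
on covered space in bin units (to keep counts integral).

## Telomeres and FISH

A trans DI is subtelomeric when either endpoint bin lies within 2 Mb of
a chromosome end (the window is a modelling choice — "extremity" has
no published definition — and is configurable). Enrichment is a
one-sided binomial test of the observed subtelomeric fraction against
the exact fraction of all possible trans pairs touching a terminal
window, split by logFC sign.

FISH nuclei are analyzable with exactly 4 signals, 2 per probe.
Distances are Euclidean in µm after scaling pixel offsets by the voxel
size (0.06, 0.06, 0.3 µm); a nucleus is associated when **any**
heterologous pair lies ≤ 1 µm apart (homologous pairs never count —
the nucleus-level rule for multiple signals is our choice, the natural
reading of pair-association). The condition effect is a grouped
binomial GLM (logit) on associated/total counts with the telomeric
pair as fixed covariate; the likelihood-ratio (deviance) χ²(1)
compares models with and without the condition. Perfect-separation
cells trigger a flagged 0.5 continuity correction. On the published
counts of the three probed combinations the test gives χ² = 4.38,
p = 0.036 with higher association at d90; the originally reported 0.02
plausibly comes from a slightly different χ² variant, so significance
and direction — not the digit — are the validated claims.

## The synthetic generator

Cis counts follow
`μ_ij = depth · K_ij / Z`, `K_ij = (|i−j|+1)^(−α) · exp(γ e_i e_j) · τ_ij · δ_ij`
with α = 1 (a generic contact decay), e = ±1 the planted compartment
state, γ = 0.6 (strong enough for clean eigenvector recovery on 60-bin
chromosomes), τ = 2 within-TAD enrichment, and δ the block effect. Z
normalizes the kernel genome-wide so the expected cis total equals the
replicate depth (1.7–2.2 M, deliberately unequal to exercise the
normalization). Trans pairs have flat mean `depth · π₀` (π₀ = 1e-5,
~10% trans) with a 4-fold boost on subtelomeric pairs (terminal 4
bins per arm) in d90 only. Counts are gamma-Poisson with φ = 0.05
(variance μ + φμ²).

Two resolution-dependent choices:

* τ is expressed only in 50 kb mode: at 500 kb the ~1.2 Mb domains are
  a near-diagonal sub-bin effect, and injecting them at analysis
  resolution would make every group-specific TAD a differential signal
  that confounds block recovery. Fine-resolution maps (cis-only) exist
  for the insulation-score analyses.
* δ multiplies **every** cis pair touching a block bin, matching the
  block concept — a compacting region gains contacts with the whole
  chromosome, so its bins accrue many same-sign DIs. A within-block-only
  effect gives each bin at most 5 signed DIs, which the 10:1 rule
  cannot classify once any other differential signal exists.

The d110 segmentation derives from d90 by flipping short interior runs:
each flip fragments a segment into three (driving the ~30% segment
count increase via `split_factor` = 1.3) and its bins are the planted
consistent switches (`switch_fraction` = 0.03, matching the ~3% scale
of consistent switching this developmental window shows). Blocks (6
bins = 3 Mb, one positive and one negative per chromosome) avoid switch
bins and chromosome ends so the planted truth classes stay orthogonal.
TAD calls are truth with N(0, 1 bin) boundary jitter and 5% dropout.
Expression: genes placed with 2:1 preference for A bins (gene density
doubles as the orientation covariate), per-stage log2 levels
N(6, 1)/N(4, 1) in A/B by that stage's labels, and logFC N(0, 0.5)
shifted ±1 for switch genes. FISH nuclei are placed in a 10 µm box
with the per-combination association rates and nucleus counts of the
three probed telomere combinations as defaults.

All randomness derives from one root seed split per stage
(SeedSequence), so outputs are byte-reproducible.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: realistic karyotypes and chromosome-length
heterogeneity, distance-dependent dispersion and cross-replicate
correlation of Hi-C noise, nested/overlapping TADs and caller-specific
artifacts, partial or gradual compartment shifts (switches are planted
as clean consistent flips), mapping biases beyond a multiplicative
per-bin factor, and image-segmentation noise in FISH coordinates.
Recovery results certify the pipeline's correctness on its own model
class, not field performance.

## Problem sizes and runtime

The default toy genome (3 × 30 Mb; 180 analysis bins, 1,800 fine bins)
keeps every stage interactive: the full pipeline runs in ~10 s and the
complete test suite — including 5,000-key GLM calibration, 200
permutation-null simulations and 500 Poisson-GLM null runs — in about
two minutes on one CPU. These sizes were chosen so the statistical
checks (not the arithmetic) dominate the budget.

## Known limitations

* The NB dispersion estimator is a deliberate approximation of the
  established empirical-Bayes implementations; tagwise shrinkage uses a
  fixed grid and prior_df rather than profiled prior degrees of freedom.
* Identity-based TAD comparison inherits the non-transitivity of
  reciprocal overlap; counts depend mildly on the anchor sample.
* The segment-shuffling consistency null treats samples as independent,
  ignoring shared replicate structure; it is conservative for the
  planted data.
* At three replicates per group, single-pair DI power at a 2-fold
  effect is ~0.75–0.8; block-level inference (the permutation test) is
  the robust readout, as in the motivating design.
* IS operates on binned counts; a read-level definition would differ
  within one bin of the boundary.
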