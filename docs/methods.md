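# Methods

`driftscan` detects and characterises recent positive selection in a
two-line livestock breeding design sampled at two time points: an ancestral
sample taken before the lines diverged, and one modern sample from each of a
dam-type (LWD) and a sire-type (LWS) line.  Two complementary signals are
scanned: *differentiation* between the modern lines beyond neutral
expectation (FLK / hapFLK against a drift tree rooted on the ancestral
sample) and *temporal change* of each line away from the ancestral sample
(a Wright–Fisher hidden Markov model per SNP, aggregated along the genome
by a local-score process).  Candidate regions are merged across tests,
named, classified into selection scenarios (convergent, divergent,
line-specific) and annotated with genes, QTL-category enrichments and
candidate causal variants.

## Models and procedures

### Population tree and FLK

Neutral allele-frequency evolution is modelled by a rooted population tree
with branch lengths in drift units (`F_i ≈ t_i / 2N_e,i`).  Pairwise drift
distances are ratio-of-sums Reynolds estimates scaled so that the distance
between two populations estimates `F_i + F_j` (numerator `(p_i − p_j)²`,
denominator `(1 − p_i p_j − q_i q_j)/2`); under pure drift
`E[(p_i − p_j)²] = (F_i + F_j) p₀q₀` and the denominator has expectation
`2p₀q₀`, so neighbour-joining branch lengths come out per-population.  The
heterozygosity-based small-sample corrections of the full Reynolds
estimator are omitted (the branch-recovery simulation shows the bias is
negligible at the scales used here).  The tree is estimated genome-wide on
variants with MAF > 10 % in the ancestral sample, rooted where the outgroup
attaches, and the outgroup is removed; the kinship matrix `F` collects
shared root-to-population drift.  Negative NJ branch estimates are
truncated to zero, and a ridge of `1e-6·mean(diag F)` is added if that
makes `F` singular.

Per SNP, `p̂₀ = (1ᵀF⁻¹p)/(1ᵀF⁻¹1)` and
`FLK = (p − p̂₀1)ᵀ [p̂₀(1−p̂₀)F]⁻¹ (p − p̂₀1)`, compared to χ² with
(#populations − 1) degrees of freedom.  Calibration (mean = df, uniform
p-values) is exact in the model's Gaussian-drift world and holds to ~10 %
on discrete Wright–Fisher drift at `Ne ≈ 80`, `t = 20–25`.  SNPs with
`p̂₀ ∈ {0,1}` or missing frequencies are flagged NaN.

### Haplotype-cluster model and hapFLK

Unphased genotypes follow a fastPHASE-style HMM: each haplotype is a mosaic
over K latent clusters with site-specific cluster allele frequencies
`θ[l,k]`, site-specific cluster weights `α[l,k]`, and a single genome-wide
jump probability ρ per marker interval.  The diploid chain over ordered
cluster pairs factorises, so forward–backward stays K×K.  EM updates use
exact expected counts (jump-destination events for α and ρ, posterior
allele attribution for θ); the log-likelihood trace is monotone.
Convergence: relative change < 1e-6 or 100 iterations (the paper-default of
the published software is 10 restarts; restarts are controlled by `nfit`).
θ is clipped to [1e-4, 1 − 1e-4] to keep emissions proper.

hapFLK sums the FLK quadratic form over cluster frequencies
`Σ_k (p_k − p̂₀k1)ᵀ[p̂₀k(1−p̂₀k)F]⁻¹(p_k − p̂₀k1)` at every site, skipping
clusters whose estimated ancestral frequency hits 0 or 1, and averages over
`nfit` independently seeded EM fits (default 10).  P-values come from a
scaled chi-square fitted robustly to the genome-wide empirical distribution
by matching the median and upper quartile (robust to the selected tail);
significance is a Storey q-value below the FDR target (default 0.2).  The
π₀ smoother only uses λ values with a populated right tail and falls back
to π₀ = 1 (Benjamini–Hochberg behaviour) below 100 p-values — without this
guard a bounded test statistic can push π₀ to 0 and flag everything.

### Temporal Wright–Fisher HMM test

The hidden population frequency evolves per generation by genic selection
`f* = f(1+s)/(1+fs)` for `s ≥ 0` — negative `s` gives the *other* allele
the advantage `|s|`, which makes the model exactly equivariant under allele
relabelling — followed by binomial resampling with `2Ne` draws.  The state
grid is the exact Wright–Fisher grid `{0, 1/2Ne, …, 1}` when `2Ne ≤ 400`
(the regime of this design) and a 201-point grid with moment-matched normal
transitions otherwise.  The prior over the initial frequency is uniform on
the interior grid points, updated by the first sample's binomial emission;
the second sample's emission closes the likelihood.  Per SNP the test
maximises the likelihood over a 41-point signed-log s-grid in [−1, 1] with
one refinement pass, against the drift-only null.

**P-values are exact, not asymptotic.**  The likelihood-ratio statistic
depends on the data only through the discrete pair of allele counts, so its
exact finite-sample null distribution is obtained by enumerating all count
pairs with their drift-only probabilities.  The χ²(1) reference (available
as `p_method="chi2"`) is noticeably miscalibrated for a single two-point
series (type-I ≈ 7 % at nominal 5 % after MAF filtering; KS rejects
uniformity decisively), which is what motivated the exact default.  Exact
p-values are conservative at their discrete atoms; `randomize=True` adds a
`p_rand` column drawn uniformly within each atom's probability band
(classical randomised-test construction), exactly Uniform(0,1) under the
null.  The local-score stage consumes `p_rand`, because its Monte-Carlo
threshold calibration assumes uniform null p-values; reported per-SNP
p-values stay exact (conservative).

The estimate `s_hat` is the grid argmax, signed for the counted allele.  It
is only *bounded below* once the favoured allele is fixed in the second
sample — from `f₀ = 0.2` with `s = 0.3` over 25 generations most loci fix
and `s_hat` saturates at the grid edge; over 10 generations the median
`s_hat` recovers the truth within a factor of ~1.1.  This is a property of
two-time-point data, not of the implementation.

Drift-only effective population size: the total log-likelihood at `s = 0`
is profiled over an Ne grid (default 25 log-spaced points in [20, 500])
and the argmax refined by a parabolic fit in log Ne.  Duplicate count pairs
are collapsed before likelihood evaluation, which makes 10⁴-locus profiles
take ~1 s.  The product over loci is a composite likelihood: unbiased in
the median but with effective degrees of freedom set by the number of
independent linkage blocks, hence very noisy on short, high-LD simulated
genomes (see limitations).

### Local score

Per SNP, `X_i = −log10(p_i) − ξ` with ξ = 2 by default (SNPs with
p > 10⁻² count against a region); the Lindley process
`h_i = max(0, h_{i−1} + X_i)` accumulates runs of small p-values.
Per-chromosome thresholds are the (1 − FPR) quantile of the maximal h over
Monte-Carlo null chromosomes of independent uniform p-values (default
FPR = 1 %; ≥ 5000 replicates recommended — the 99th-percentile order
statistic from 1000 draws is visibly noisy).  A circular-shift mode of the
observed p-values is available for autocorrelation-robust thresholds.
Segments are maximal above-threshold excursions extended back to the SNP
following the last zero of h.

### Regions and scenario classification

Within a test, segments closer than 1 Mb (strict) are merged; across
tests, merging requires ≥ 1 bp overlap.  Regions are named `SSC<chrom>:<Mb>`
with Mb the integer part of the start position.

Each region is re-scanned with all available variants (no MAF filter):
FLK, hapFLK, both temporal tests, and per-population allele frequencies.
Classification evidence:

- `shift_d`, `shift_s` — absolute allele-frequency changes of each line
  from the ancestral sample at the *focal SNP*, the variant with the
  strongest combined temporal evidence.  (Choosing the focal SNP by raw
  frequency shifts would bias toward sites where the unselected line also
  drifted far.)
- `same_target` — whether both lines moved the focal SNP in the same
  direction (both changes above a 0.02 noise floor).
- significant / suggestive temporal flags — the region was called by that
  line's genome scan / shows a local-score excursion `h ≥ 1` inside the
  region.  The excursion criterion captures coherent multi-SNP support
  that single-SNP minima cannot separate from drift.

Rules, in order: both shifts ≥ τ_shift → `div` if different targets, else
`conv` (refined to `conv(LWD)`/`conv(LWS)` when the shifts differ by
≥ τ_hi = 0.2); one shift ≥ τ_shift → line-specific; otherwise a
test-pattern fallback mirroring the published qualitative typology
(significant hapFLK with different targets → `div`; one-sided temporal
significance → line-specific; two-sided suggestive with the same target →
`conv`; else `unresolved` — reported explicitly, never dropped).
τ_shift = 0.35 ≈ 1.5 × the null standard deviation of a focal-SNP shift at
`Ne ≈ 80`, 25 generations and 13 sampled diploids (drift sd ≈ 0.2 plus
sampling sd ≈ 0.1).  An earlier design classified on region-maximum
haplotype-cluster frequency shifts; it was abandoned because the maximum
over sites × clusters of a drifting quantity exceeds any useful threshold
in unselected lines, and because the identity of the top-gaining cluster in
an unselected line is essentially arbitrary.  Cluster-frequency tracks are
still produced for visual inspection.

### Downstream characterisation

Genes come from a GFF3/GTF gene map (any bp overlap); gene-empty regions
receive up to two flanking genes per side — the closest if within 1 Mb of
the region, the second if within 50 kb of the first.  QTL within 2 Mb
(strict, interval gap) contribute weight 5 (trait directly in a selection
index) or 1 (indirectly affected); cumulated scores per trait × region
category are compared by adjusted standardised residuals
`(O − E)/sqrt(E(1 − row/N)(1 − col/N))`.  The same contingency layer
serves the gene-function association on a user-supplied gene→function
table (database retrieval is out of scope).  Candidate variants: a variant
is *invalid* below a call-rate threshold (default 0.8) or when its
frequency shift contradicts the region's selection pattern (different sign
or less than half the peak shift in a selected line); *statistical*
candidates are valid variants within 95 % of the region's maximum of the
category-relevant statistic (FLK for `div`, the relevant temporal test
otherwise), capped at 3; *functional* candidates reach 80 % of the maximum
and carry a HIGH/MODERATE/LOW SnpEff impact (worst impact across
transcripts of the ANN field).

## The simulator and what a green test establishes

`simdata` is a forward Wright–Fisher simulator of the design: a
linkage-equilibrium ancestral pool with exact per-site allele counts drawn
from a truncated 1/x frequency spectrum, a neutral burn-in (default 10
generations; the scenario-recovery harness uses 120 to build realistic
linkage blocks), the first sample, an optional pre-split phase, the split
into two lines of configurable size, post-split evolution under genic
selection with Poisson-crossover recombination, and the two modern
samples.  No mutation occurs during the simulated decades (negligible over
~25 generations).  Output panels are ascertained to sites segregating in
the sampled union, as a called SNP panel would be.  Defaults mirror the
study design: samples of 10/13/13 diploids, `Ne` = 80 (dam) and 74 (sire),
~25 generations between samples.

Selected loci snap to an existing segregating SNP near the requested
position whose post-burn-in frequency is closest to the scenario's `f0`
(default 0.2; 0.5 for divergent scenarios, which presuppose
intermediate-frequency standing variation), preserving the linkage
structure around the target.  The scenario-recovery harness redraws
replicates in which the favoured allele failed to establish, as in
standard sweep-power studies: the measured quantity is the power to detect
a selection signature that exists, not the probability that an attempted
sweep succeeds.

Features of real data the simulator does not emulate: mutation,
gene conversion, variable recombination and SNP density, sequencing and
calling error (missingness is uniform, not coverage-driven), overlapping
generations and unequal sex contributions.  A green scenario-recovery test
therefore establishes that the statistical machinery detects and labels
clean sweeps of the stated strength in a drift-realistic world — not that
real-data regions would be recovered at the same rate.

## Numerical choices

- Frequency grids: exact WF states for `2Ne ≤ 400`; 201-point
  normal-approximated grid above.  Transition matrices are cached per
  `(Ne, gens, s)`.
- Temporal likelihoods collapse duplicate count/sample-size tuples; exact
  null enumeration is skipped (χ² fallback) above ~20 000 pairs.
- EM: θ clip 1e-4, α floor 1e-8, ρ clipped to [1e-6, 0.999]; `nfit`
  restarts differ only by seed; likelihood ties in restarts resolved by the
  last best.
- q-values: Storey smoothed-λ with tail guard; π₀ clipped to [0.05, 1].
- All randomness flows from explicit integer seeds; identical seeds give
  byte-identical outputs.

## Known limitations

- Temporal Ne estimation on few, strongly linked loci is noisy (composite
  likelihood); on whole-genome data with many independent blocks it
  recovers the truth to a few percent (the acceptance run reports the mean
  over 20 × 10⁴-locus replicates).
- Sweeps on a large fraction of a small simulated genome contaminate both
  the Ne estimate and the hapFLK empirical-null scaling; the analysis
  drivers estimate Ne on the neutral chromosome for this reason.
- hapFLK significance via q < 0.2 is weak on tiny genomes; region
  classification therefore does not depend on it except as a fallback.
- The classifier is an automated approximation of a judgment the original
  analysis made by eye; `unresolved` is a first-class outcome.
- Exact temporal p-values are conditional on the model's uniform prior
  over initial frequencies; panel ascertainment (sample-MAF filtering)
  makes them mildly anticonservative in the filtered set (~7 % at nominal
  5 % for the χ² variant, less for the exact one).
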