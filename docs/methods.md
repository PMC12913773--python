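# Methods

## Scope and model

`apobecsig` starts from called somatic variants, not reads. The implicit
generative model is the standard one for single-base-substitution (SBS)
signature analysis: each sample's mutations are i.i.d. draws from a
mixture over the 96 substitution-in-trinucleotide-context channels,
`p = S e / |e|₁`, where the columns of the 96 × K matrix *S* are signature
profiles (probability vectors) and *e* ≥ 0 are exposures. Everything the
package estimates — background profiles, exposures, APOBEC fractions —
is a functional of per-sample channel counts under this model.

Channel order is fixed to the COSMIC convention (substitution blocks
C>A, C>G, C>T, T>A, T>C, T>G; within a block, 5' flank then 3' flank in
A, C, G, T order) so that files exchange stably; purine-reference calls
are reverse-complemented onto the pyrimidine strand before
classification. The classification is a bijection between the 96
pyrimidine-stranded (ref, alt, context) triples and channels, verified
exhaustively in the test suite.

## Variant filtering

Somatic calls are kept when caller status equals `PASS`, the variant
allele frequency lies in [0.3, 0.7], and the call is absent from the
parental clone (matched by exact (chrom, pos, ref, alt)). Rationale: in
a clonally expanded, diploid setting a true heterozygous somatic variant
has VAF ≈ 0.5; sub-threshold VAFs are dominated by subclonal noise and
artifacts, supra-threshold ones by LOH and germline leakage.

Decisions that were genuinely open and how they were fixed:

- **Bounds inclusivity.** "Between 0.3 and 0.7" is ambiguous; bounds are
  inclusive by default and exposed in `FilterConfig` so either reading
  is testable.
- **Missing VAF.** Records without a VAF field are dropped (conservative)
  and tallied under their own reason; every drop reason is counted and
  the retained + dropped totals must reconcile with the input count.
- **Filter order.** VAF/status filtering and parental subtraction
  commute (both are per-record predicates); the property is tested.

## Background correction

Control samples (in the emulated design: three early-timepoint samples
carrying a safe-harbor control sgRNA) define the background. The
procedure:

1. `draw_size` = floor of the smallest control total; every control row
   is scaled to that total (outlier damping).
2. For each control, `n_boot` = 10,000 multinomial draws of size
   `draw_size` with the control's channel proportions as weights
   (30,000 draws for three controls).
3. The background profile is the element-wise mean over all draws; it
   sums to `draw_size` exactly.
4. Correction is `max(count − background, 0)` per cell, applied to raw
   experimental catalogs.

The bootstrap mean has the closed form `draw_size × mean_i(p_i)` over
control proportion vectors `p_i`; the Monte-Carlo error of the estimate
shrinks as 1/√n_boot, and at n_boot = 10,000 the realized relative L1
distance to the closed form is well under 2% (measured in the acceptance
checks). The mean-of-multinomials formulation makes the two readings of
"down-scaled proportional to the lowest count" (scale-then-resample vs
resample-at-common-size) expectation-equivalent; the common-size reading
is implemented because the averaging step presupposes draws of equal
size. Random-number consumption is fixed (controls in roster order,
draws sequential), so a seed fully determines the profile. Controls are
designated by sample label in configuration, never hard-coded.

## Signature refitting

Exposures are estimated by non-negative least squares
(`scipy.optimize.nnls`), the standard refitting engine for fixed
signature matrices. The strict best-subset rule then prunes:

- Fit all K signatures; record reconstruction cosine `c_K`.
- At each step, find the best subset one smaller than the current one —
  exhaustively over all subsets of that size when K ≤ 12, by dropping
  one member of the current subset otherwise — and descend iff its
  cosine is ≥ current cosine − `max_delta`.
- Stop otherwise; final exposures are the NNLS fit on the selected
  subset, zero elsewhere.

`max_delta` (default 0.004) is the tolerated reconstruction-quality loss
per descent: larger values prune harder and yield stricter (sparser)
activity estimates. Selection is monotone in `max_delta` and
scale-equivariant in the input; at `max_delta` = 0 only exactly
redundant signatures are dropped, at 1 a single signature always
remains. Ties between equal-cosine subsets (beyond 1e-12) resolve to the
lexicographically earliest index set, making results deterministic.
Exposures "scaled to one" are exposures divided by their sum; an
all-zero exposure vector is flagged rather than normalized.

**Recovery contract.** On catalogs of 1,000 mutations drawn from a
random pair of the six bundled synthetic signatures, the refit selects
the true pair *and* recovers the mixing fraction within ±0.05 in ≥ 90%
of replicates. The contract is deliberately joint (pair correct and
fraction accurate, per replicate): at n = 1,000 the fraction estimate
carries binomial noise with SD ≈ 0.016 even for orthogonal signature
pairs, so a worst-case bound over 100 replicates would sit at ~3σ and
fail by chance alone for any signature design; the joint per-replicate
rate is the statistically well-posed version of the same property.

**Presence test.** Whether a target signature is active is assessed by a
multinomial likelihood-ratio statistic `2(ℓ₁ − ℓ₀)` between NNLS
reconstructions with and without the target (reconstructions floored at
1e-9 and renormalized to probabilities so zero-reconstruction channels
with observed counts stay finite), with the null distribution obtained
by parametric bootstrap from the without-target reconstruction and
`p = (1 + #{null ≥ obs}) / (reps + 1)`. This is an approximation in the
spirit of signature-activity tests from dedicated packages, not a
reimplementation of any of them; the statistic is non-negative by model
nesting, and type-I behavior is exercised in the tests.

## APOBEC statistics

"APOBEC-related" is operationalized as the eight channels T[C>T]N and
T[C>G]N (C>T and C>G at 5'-TCN), following the kataegis-context
definition; a TCW (W = A/T) restriction is available as configuration
because pentanucleotide analyses suggest W-biased 3' contexts. The
choice is always explicit, never silent.

The two-sided Fisher exact p is computed by enumerating the
hypergeometric support with exact integer binomial coefficients and
summing the probabilities of all tables (at fixed margins) whose
probability does not exceed the observed table's, with the customary
1 + 1e-7 relative tie tolerance. This in-package enumeration is exact to
float rounding and fast enough to sweep every 2×2 table with margins
≤ 30 in seconds; `scipy.stats.fisher_exact` serves as an independent
cross-check in the tests, and `scipy.stats.contingency.odds_ratio`
provides the conditional-MLE odds ratio with its exact 95% CI (the
sample cross-product ratio is also reported; the MLE is primary, as is
conventional for reported odds ratios with exact CIs). Multiple
comparisons against a common reference group use Bonferroni,
`p_adj = min(1, m·p)`. Degenerate margins give p = 1; a zero cell gives
boundary OR estimates (0 or ∞).

Pentanucleotide profiling collects the −2..+2 reference context of every
C>T and C>G mutation (purine-stranded equivalents reverse-complemented),
keeps k-mers matching N-T-C-N-N, and tallies per-position base
frequencies; positions −1 and 0 are all-T and all-C by construction,
which the tests assert as the filter's defining contract.

## Cohort comparison

Samples are binned per gene: "mut" iff at least one variant (SNV or
indel) in the gene has a classification other than "Intron"; a combined
group is "mut" if any of several genes is. Variants with a missing
classification count as non-intronic by default (configurable); samples
with no call for a gene are excluded from that gene's comparison and
tallied. Signature activities are divided by the sample's total mutation
count exactly once before any comparison — this guards against total-
burden confounding between genotype groups.

The Wilcoxon rank-sum test uses midranks for ties; p-values come from
the exact null distribution when min(n, m) ≤ 10 and there are no ties,
and from the normal approximation with tie and continuity corrections
otherwise (delegated to `scipy.stats.mannwhitneyu`; the reported
statistic is the rank-sum W of the first group, W = U + n(n+1)/2). The
exact branch is pinned against a full rank-permutation enumeration in
the tests, and null calibration/power are measured on simulated cohorts.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

- **Reference**: seeded i.i.d. bases at configurable GC (default 0.41,
  the human genome-wide value); default length 100 kb guarantees every
  trinucleotide is represented many times. Tests use 20–40 kb, which
  comfortably hosts the few hundred mutations per sample they place.
- **Signatures**: deterministic shapes — `sbs2-like` (97% of mass on
  T[C>T]N with a T > A > C = G 3' preference), `sbs13-like` (same on
  T[C>G]N), `flat`, and `c-to-a-skewed` (90% on the 16 C>A channels
  with an A/T-flank preference, emulating the concentration of
  oxidative-damage-like backgrounds) — plus seeded Dirichlet-drawn
  `random-<n>` profiles for refit stress tests.
- **Variants**: each counted channel mutation is placed at a reference
  position whose trinucleotide matches on either strand (sampled
  without replacement), so reverse-complement handling is exercised by
  construction. Clonal VAFs are Beta(50, 50) (mean 0.5, SD ≈ 0.05)
  truncated to the passing window; noise enters only through explicit
  knobs — a contamination fraction (VAF placed outside [0.3, 0.7]), a
  non-PASS fraction, and a parental-shared fraction. The truth table
  records which variants should survive filtering, and with all knobs
  at zero the simulate → VCF → filter → catalog loop reproduces the
  simulated catalog exactly.
- **Controls**: multinomial rows at configured totals (default
  800/1000/1200, a triplicate with moderate depth spread).
- **Cohorts**: per-sample target-signature fractions are Beta-
  distributed around the group mean (concentration 20, i.e. SD ≈ 0.08
  at mean 0.15) with a configurable additive effect in the mut group;
  totals are log-normal around 3,000 mutations. Defaults of 100
  samples per group and a +0.10 effect correspond to the power setting
  the comparison tests measure.

What the generator does **not** emulate: read-level errors, mapping
artifacts, subclonal structure, regional mutation-rate covariates
(replication timing, chromatin), strand asymmetries, and inter-signature
correlations of real tumors. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's computations under its own
model assumptions, not robustness of biological conclusions to
real-data confounders.

## Numerical choices

- Catalog counts are floats so the same container carries raw and
  background-corrected (fractional) matrices; raw-catalog row sums equal
  classified-SNV counts exactly.
- Signature columns must sum to 1 within 1e-6; cosine similarity returns
  0 when either vector has zero norm.
- Fisher tie tolerance is the exact integer ratio 10000001/10000000,
  matching the convention of mainstream implementations.
- The presence-test probability floor is 1e-9 per channel before
  renormalization.
- Seeds: every stochastic routine takes an explicit seed and consumes
  randomness in a documented order; the pipeline manifest records the
  seed and SHA-256 checksums of all outputs, and reruns are
  bit-identical.

## Problem sizes in the bundled checks

The test suite and acceptance script run entirely on generated data:
catalogs of 300–2,000 mutations, references of 20–40 kb, 100-replicate
recovery and power sweeps, the full 164,176-table Fisher enumeration at
margins ≤ 30, and 200-replicate null calibrations. These sizes give the
oracle comparisons tight Monte-Carlo error while keeping the whole suite
in the tens of seconds on one CPU.

## Known limitations

- The best-subset search is exhaustive only up to K = 12 signatures;
  beyond that, backward elimination may miss non-nested optima.
- The presence test is an approximation (multinomial LRT with bootstrap
  null), not a validated reimplementation of published activity tests;
  its p-values floor at 1/(reps + 1).
- Genotype binning trusts upstream variant classification labels; the
  coordinate-overlap fallback does not re-annotate consequences.
- The Fisher conditional-MLE CI relies on scipy's test inversion, which
  reports open bounds (0/∞) at zero cells rather than refusing.
- Background subtraction is element-wise and can zero out channels with
  genuinely low signal; it is intended for designs with matched controls
  of comparable depth.
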