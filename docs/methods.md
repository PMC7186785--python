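# Methods

## Model and estimators

`linkdiv` treats the genome as a set of half-open windows [start, end) tiled
per chromosome at several sizes (2.5 kb, 5 kb, 50 kb, 100 kb, 500 kb, 1 Mb by
default). All coordinates are 0-based half-open internally; VCF positions
(1-based) and GFF features (1-based inclusive) are converted on read, BED is
taken as-is. One convention everywhere removes a whole class of off-by-one
errors.

Per window, two estimators of the per-bp population mutation parameter θ are
computed from biallelic segregating SNPs:

- **θ̂π** accumulates the unbiased per-site heterozygosity
  2j(n−j)/(n(n−1)), which equals the mean Hamming distance over all C(n,2)
  chromosome pairs at that site (the test suite verifies this equivalence by
  explicit pair enumeration).
- **θ̂w** accumulates 1/a(n_i) per segregating site, a(n) = Σ_{i=1}^{n−1} 1/i.
  Accumulating per site with that site's genotyped chromosome count n_i —
  rather than dividing the total k by one fixed a(n) — keeps the estimator
  unbiased when genotypes are missing at random; with complete data the two
  forms coincide.

Both divide by `neutral_bp`, the number of window positions that are outside
the merged transcription mask and are not 'N' in the reference. Restricting
to nontranscribed sites focuses the estimators on putatively neutral
variation; dividing by eligible rather than total positions is the
internally consistent companion choice (a `denominator="window"` option
preserves the alternative). Windows whose eligible fraction falls below a
floor (default 10% of window length) are flagged ineligible and excluded
from statistics: gene-dense or N-rich windows otherwise contribute
high-variance estimates. A SNP-only VCF cannot distinguish unsequenced from
invariant positions, so no accessibility correction beyond the N/mask
restriction is possible; this matches the estimators' inputs and is a known
limitation.

Sites enter the analysis when: QUAL ≥ 100 (inclusive; the threshold is
configurable), biallelic SNP, and segregating within the named population
sample (1 ≤ j ≤ n−1 computed over those samples' genotypes only). Indels,
multiallelic records, and monomorphic-in-sample records are excluded with
logged counts. Diploidy is assumed (n = 2 × samples).

## Recombination rates

The recombination rate of a 5-Mb interval is the OLS slope of the Marey map
(genetic position in cM against physical position in Mb) over the markers in
the interval. Intervals with fewer than `min_markers` (default 3 — a slope
plus one residual degree of freedom) or with no spread in marker position
get a missing rate. Negative slopes are kept but logged: genetic maps can
locally invert through genotyping error, and discarding them would bias the
rate distribution.

Windows take the rate of the interval containing their midpoint. Percentile
classes (low/mid/high) cut the genome-wide distribution of per-window rates
at the 5th and 95th empirical percentiles (linear interpolation between
order statistics); a window at or below the low threshold is "low", at or
above the high threshold "high". Hotspots are counted into windows by
hotspot midpoint under the same half-open convention.

## Covariates

- **Transcribed proportion**: overlap length of the merged transcription
  mask with the window, over window length.
- **CpG count**: forward-strand 'C' followed by 'G' (CpG is its own reverse
  complement, so one strand suffices). Soft-masked lowercase counts;
  anything involving 'N' does not. A dinucleotide straddling a window
  boundary is attributed to the window containing the C. CpG enters models
  as the raw per-window count; counts at different window sizes are
  therefore on different scales, which is how the coefficient magnitudes
  should be read.
- **Divergence**: a per-interval track of (aligned_bp, mismatches) is
  aggregated into each window — partially overlapping track tiles contribute
  in proportion to the overlapped fraction — giving the mismatch proportion
  p, corrected for multiple hits with Jukes–Cantor d = −(3/4)ln(1−4p/3).
  p ≥ 0.75 is saturation and yields a missing value, as do windows whose
  aligned bases fall below 10% of window length. The track format keeps the
  package self-contained: producing it from a whole-genome alignment is a
  preprocessing step outside scope. By default divergence uses all aligned
  window positions (not only nontranscribed ones); the mask option exists.

## Statistics

- **Spearman**: midrank ties; ρ is the Pearson correlation of rank vectors.
  Two-sided p from the exact permutation distribution for n ≤ 10 and from
  the t approximation t = ρ√((n−2)/(1−ρ²)) above.
- **Wilcoxon rank-sum**: exact enumeration of rank assignments for
  n₁+n₂ ≤ 12; otherwise normal approximation with tie correction and 0.5
  continuity correction. The percentile contrast is two-sided; the hotspot
  contrast is one-sided with hotspot-containing windows higher under the
  alternative.
- **Linear model**: OLS of θ̂π on rate, divergence, CpG count, transcribed
  proportion and the CpG×transcribed interaction (the interaction is always
  included because CpG density and transcription are positively correlated
  across real genomes), complete cases only, rank-deficient designs refused
  with the collinear terms named. Raw p-values are reported — multiple
  windows sizes and populations are deliberately not corrected, matching
  standard practice for this analysis — with a Bonferroni summary in the
  log.

## Synthetic data: what it emulates and what it does not

The generator inverts the estimators. Per model window (default 1 Mb) the
true per-bp θ is β₀ + β_rate·rate + β_div·d + β_cpg·cpg + β_tx·tx +
β_cpgtx·cpg·tx, clipped below at 10⁻⁵, where the covariates are the window's
*realized* values (scanned CpG count, realized transcribed fraction,
realized divergence draw, true Marey slope). Segregating sites are then
independent: k ~ Poisson(θ·a(n)·neutral_bp) placed uniformly on
nontranscribed positions, derived-allele counts from the neutral spectrum
P(j) ∝ 1/j, carriers uniform. Under this model E[θ̂π] = E[θ̂w] = θ exactly,
so estimator calibration and OLS coefficient recovery are clean tests.

Default planted values: β₀ = 3.2×10⁻³, β_rate = 1.55×10⁻⁴,
β_div = 3.16×10⁻³, β_cpg = −8.53×10⁻⁸ (per CpG at 1 Mb),
β_tx = −6.10×10⁻⁴, β_cpgtx = −2.94×10⁻⁸ — signs and magnitudes of the
wild-mouse setting this package was built around, giving genome mean θ near
2.4×10⁻³/bp. Marey slopes cycle through 0.5/1.0/0.14/1.20/0.3/0.8 cM/Mb per
5-Mb segment (bracketing realistic 5th–95th percentile rates), divergence
mismatch averages 15% (mouse–rat scale), CpG frequency 0.5–2% per window
(CpG-depleted, as in mammals), transcribed fraction 15–55% per window with
~20-kb transcripts, hotspots ~5/Mb of ~1.2 kb. QUAL values are drawn from
bands on both sides of the 100 threshold so the filter path is always
exercised.

Deliberately *not* modelled: linkage disequilibrium within windows (sites
are independent, so sampling variance is smaller than a coalescent with
linkage would give — calibration tolerances would need widening under a real
coalescent), demography, selection, sequencing error beyond the QUAL decoys.
Passing recovery tests therefore establishes correctness of the estimators
and statistics, not robustness to LD or demographic confounding; a
coalescent simulator's VCF can be swapped in wherever a file bundle is
consumed. Sequences are built from two-base tiles that cannot form CpG
across tile joins, so the realized CpG count is binomially controlled at the
configured frequency; base composition is consequently slightly C-poor,
which is irrelevant to every consumer of the sequence (CpG counting, N
masking, REF lookup).

The fast in-memory variant path may occasionally place two mutations at one
base pair (an infinite-sites approximation with replacement); the
file-writing path enforces distinct positions as VCF requires. With
genotype missingness configured, the in-memory table reduces (j, n) by
hypergeometric subsampling; the emitted VCF prefers masking non-carrier
samples, so the two paths can differ slightly for sites where missingness
collides with carriers — missingness defaults to 0.

## Numerical and design choices

- Exact-regime cutoffs (n ≤ 10 Spearman, n₁+n₂ ≤ 12 rank-sum) follow the
  sizes where enumeration is instant; beyond them the approximations are
  standard and are cross-checked against scipy in the test suite.
- OLS is fit via statsmodels; tests verify the estimates and standard errors
  against an explicit normal-equations oracle.
- Percentile definition: numpy's linear-interpolation quantile.
- Degenerate inputs: zero eligible bases → missing estimate (never division
  by zero); all-identical rates → everything "mid" with a warning; zero rank
  variance → correlation flagged undefined.
- Problem sizes in the acceptance checks (500 × 1 Mb calibration windows,
  400–1,000 null replicates of 200 windows, 2,000–2,500-window model fits,
  50–100 directionality seeds) were chosen to make each statistical bound
  comfortably testable on a laptop-class machine; the type-I bound (≤ 6% at
  α = 0.05) and the 2% calibration tolerance come from the binomial/CLT
  margins at those sizes.
- The end-to-end directionality check plants the default β_rate on 5-kb
  windows, where the per-window estimator noise (≈3×10⁻⁴) still leaves the
  planted rank correlation (~0.15) detectable at 1,000 windows with power
  >99%.

## Limitations

- Recombination rates are interval-constant (5-Mb OLS slopes); fine-scale
  rate variation is only represented through hotspot counts.
- The divergence input must be pre-summarized; chain/net alignment parsing
  is out of scope.
- No SFS statistics beyond θ̂π/θ̂w (no Tajima's D), no haplotype or
  LD-based statistics, no multiple-testing correction beyond the logged
  Bonferroni summary.
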