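# Methods

## Model and assumptions

The package implements two-sample Mendelian randomization for summary
statistics.  A genetic variant j is a valid instrument for an exposure
when it is (1) associated with the exposure, (2) independent of
confounders of the exposure–outcome relation, and (3) affects the
outcome only through the exposure.  Under those assumptions, with γⱼ the
SNP–exposure effect and Γⱼ the SNP–outcome effect (log-odds scale for
binary outcomes), each variant's Wald ratio Γⱼ/γⱼ estimates the causal
effect β, and the estimators combine the ratios with inverse-variance
weights wⱼ = 1/se(Γⱼ)²:

- **IVW**: β̂ = Σwⱼγⱼ Γⱼ / Σwⱼγⱼ², the weighted regression of Γ on γ
  through the origin.  The fixed-effect SE is (Σwⱼγⱼ²)^{-1/2}; the
  random-effects model (the primary analysis) multiplies it by
  max(1, √(Q/(J−1))) where Q is Cochran's heterogeneity statistic —
  multiplicative overdispersion floored at 1, so the random-effects SE
  never undercuts the fixed-effect one.  P-values are two-sided normal.
- **MR-Egger**: the same weighted regression with a free intercept after
  orienting all variants so γⱼ ≥ 0.  The slope is consistent for β when
  instrument strength is independent of the direct (pleiotropic) effects
  (InSIDE); the intercept estimates the average directional pleiotropy.
  Inference uses exact weighted-least-squares t statistics with J−2
  degrees of freedom and a freely estimated residual scale.  The scale is
  deliberately *not* floored at 1: flooring makes the intercept test
  reject at well below its nominal level (≈0.016 instead of 0.05 in our
  null calibration), and a calibrated pleiotropy test matters more here
  than symmetry with the IVW convention.
- **Weighted median**: per-variant ratios are ordered, weights
  wⱼ = γⱼ²/se(Γⱼ)² normalized to sum 1, and the estimate interpolates the
  ratios at cumulative midpoint 0.5 (consistent when valid instruments
  carry more than half the weight).  The SE is a parametric bootstrap:
  γⱼ and Γⱼ are resampled from normal distributions with their reported
  SEs, the median recomputed, and the standard deviation taken over
  1000 seeded draws by default.
- **MR-PRESSO**: the observed residual sum of squares
  RSS = Σⱼ wⱼ(Γⱼ − β̂₍₋ⱼ₎γⱼ)² uses leave-one-out IVW fits.  The null
  distribution simulates Γⱼ* ~ N(β̂₍₋ⱼ₎γⱼ, se(Γⱼ)) n_sim = 1000 times and
  recomputes RSS with leave-one-out fits inside each simulated dataset;
  the global p-value is the tail fraction with a +1/(n_sim+1) continuity
  correction.  Per-variant outlier p-values compare each observed
  weighted squared residual with its simulated distribution and are
  Bonferroni-adjusted over J; flagged variants are removed for the
  corrected IVW estimate.  An optional distortion test compares the
  raw-vs-corrected slope change against the change from removing random
  subsets of the same size.

Sensitivity diagnostics: Cochran's Q about the fixed-effect IVW center
(chi-square, J−1 df), the Egger intercept test, and the PRESSO global
test.  A candidate passes the screen when the IVW p-value is below 0.05,
both pleiotropy tests are at or above 0.05, and all four estimators agree
in sign (a zero estimate counts as disagreement).  Heterogeneity is a
reported flag rather than an exclusion by default — the emulated screen
retained a candidate with Q p = 0.041 — and `strict_heterogeneity=True`
restores the literal three-criterion reading.  The Bonferroni tier marks
candidates with IVW p below α/m, m = 486 by default (the number of
metabolites in the emulated screen); the threshold interpretation α/486 ≈
1.03 × 10⁻⁴ is the only reading consistent with exactly the two
candidates at p = 4 × 10⁻⁵ and 2.1 × 10⁻⁶ surviving while p = 0.011 does
not.  Reverse MR swaps the exposure and outcome roles with identical
settings; the reverse test is "null" when the reverse IVW p ≥ 0.05 and
the three complementary methods are concordantly non-significant.

Pathway over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for a pathway of m compounds overlapping k of the n mapped query
compounds in a background of N_bg, with expected overlap n·m/N_bg.  The
pathway-topology "impact" score is an externally supplied number (it
requires KEGG pathway graphs); when present, significance requires
p < 0.05 and impact > 0.1, and when absent, p < 0.05 alone.

## Instrument selection parameters

| parameter | default | meaning |
|---|---|---|
| p_threshold | 1 × 10⁻⁵ | exposure association cutoff (strict `<`) |
| r2_max | 0.01 | clumping LD cutoff (`≥` pruned) within the window |
| window_kb | 500 | clumping distance window |
| f_min | 10 | per-variant F cutoff (F < 10 excluded, F ≥ 10 kept) |

The F filter is applied per variant (K = 1 with that variant's R²),
matching the stated per-IV exclusion rule; for small R² and large N it is
asymptotically (β/se)².  Clumping is greedy on ascending p-value with
ties broken by (chrom, pos); LD is a pluggable pairwise-r² source and a
pair the rule needs but the source lacks is an error, never a silent
zero.  `IndependentLd` asserts r² = 0 everywhere and is only appropriate
for pre-pruned panels or the generator's layout.

Harmonization policy for palindromic (A/T, C/G) variants defaults to
`infer_by_eaf`: drop when either study's allele frequency is within 0.08
of 0.5, otherwise orient so the frequencies fall on the same side of 0.5.
Exposure allele frequency is authoritative for R²/F; the outcome
frequency is used only for palindrome inference.  Instruments missing
from the outcome are dropped and logged (no proxy search).

## The synthetic-data generator

The generator emulates the statistical shape of the emulated study —
continuous exposure GWAS with N = 7,824; binary outcome GWAS with
N = 486,484 and case fraction 11,643/486,484; 7–37 instruments per
exposure — directly on the summary-statistic scale.  Per variant: MAF ~
U(0.05, 0.5); true effect γⱼ ~ N(0, gamma_sd) with gamma_sd = 0.3 by
default, resampled until the expected F-statistic N·R²/(1−R²) (with R² =
2·maf·(1−maf)·γ²) exceeds `f_expected_min` = 30; observed effects add
noise with se(γ) = (2·maf(1−maf)·N_exp)^{-1/2} and se(Γ) =
(2·maf(1−maf)·N_out·cf(1−cf))^{-1/2}, the normal approximation to a
logistic GWAS.  The truncation bound sits at 30 rather than at the
selection cutoff 10 because the emulated screen's weakest retained
instrument had F = 17.41 — real instrument sets live well above the
cutoff — and because a bound at 10 would leave a substantial fraction of
intended instruments below the *observed*-F filter purely through
sampling noise.  The trait-increasing allele is reported as the effect
allele (a labeling convention; it is what makes "directional" pleiotropy
with mean α ≠ 0 a well-defined quantity after Egger's γ ≥ 0
orientation).  Outcome rows are randomly re-oriented (allele swap or
strand complement) so harmonization is always exercised.

Horizontal pleiotropy enters as αⱼ ~ N(pleiotropy_mean, pleiotropy_sd)
added to Γⱼ = β·γⱼ + αⱼ, independent of γⱼ (InSIDE holds); planted
outliers add ±outlier_scale·se(Γⱼ).  Optional LD decoy blocks
(`ld_block_size`, `ld_r2`) exercise clumping, and outcome-specific loci
(`n_outcome_snps`, with `reverse_beta` their effect on the exposure)
make reverse-MR scenarios possible.  All randomness flows from one seed
through `numpy.random.SeedSequence` spawning, so identical configurations
reproduce identical tables byte-for-byte.

What the generator does **not** emulate: winner's curse from discovery
thresholds, sample overlap between the two studies, population
stratification, fine-scale LD structure, or non-normal effect-size
distributions.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
those real-data complications.

## Experiment sizes and numerical choices

Operating-characteristic experiments run 500 replicates: null calibration
(β = 0, J = 20, defaults) checks that IVW, Cochran's Q, the Egger
intercept and the PRESSO global test each reject within the binomial 99%
band around 0.05; parameter recovery (β = 0.3, J = 30) checks mean bias
within 3 Monte-Carlo SEs and 95% CI coverage in [0.92, 0.975].  Recovery
runs use a strong-instrument setting (gamma_sd = 0.8) chosen a priori:
first-order IVW carries a known O(1/F̄) weak-instrument attenuation that
is a property of the estimator, not an implementation defect, and the
bias check is only meaningful where that term sits below Monte-Carlo
resolution.  Null calibration keeps the default gamma_sd = 0.3, since
test size does not depend on instrument strength.  The screening
experiment uses 50 exposures with 3 causal at |β| = 0.5, instrument
counts drawn from 7–37, and the full selection pipeline.

Other numerical choices: p-values are clamped to (0, 1] (the smallest
positive double at the lower end); MR-PRESSO requires J ≥ 4 and leaves
the corrected estimate undefined when all or all-but-one variants are
flagged; the weighted-median bootstrap guards against resampled γ* = 0 by
substituting the smallest positive double; Egger requires spread in γ
(singular designs are an error, not a NaN).  Estimator SE floors,
degrees-of-freedom and tie-break conventions are stated inline in the
module docstrings.

## Known limitations

- The Egger residual-scale choice (unfloored) trades agreement with one
  common convention for a calibrated pleiotropy test; both behaviors are
  standard in the literature.
- Reverse MR inherits the classic bidirectional ambiguity: when a strong
  forward effect pushes instrument p-values past the selection threshold
  in the outcome study, the reverse analysis will "detect" an effect.
  No Steiger filtering is applied (none was used in the emulated design).
- The pathway impact score is consumed, never computed.
- No liftover, multi-allelic decomposition, proxy-SNP lookup, or LD
  computation from genotypes; the LD source is always external.
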