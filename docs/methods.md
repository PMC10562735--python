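# Methods

## The model

Two-sample summary-data MR treats each instrument SNP *j* as a natural
experiment.  With γⱼ the SNP's true effect on the exposure and αⱼ its
direct ("horizontally pleiotropic") effect on the outcome, the observed
summary statistics are

    β̂x,j = γⱼ + εx,j            εx,j ~ N(0, sx,j²)
    β̂y,j = β·γⱼ + αⱼ + εy,j     εy,j ~ N(0, sy,j²)

where β is the causal effect of interest (log-OR per SD of exposure for a
binary outcome).  Valid instruments have αⱼ = 0; the per-SNP Wald ratio
β̂y,j/β̂x,j then estimates β.  The estimators differ in how they pool the
ratios and in how much instrument invalidity they tolerate:

- **IVW**: weighted regression of β̂y on β̂x through the origin with weights
  1/sy²; equivalently the bx²/sy²-weighted mean of Wald ratios.  Efficient
  when all instruments are valid; biased by any directional pleiotropy.
- **MR-Egger**: the same regression with a free intercept.  Under the
  InSIDE assumption (instrument strength independent of direct effects)
  the slope remains consistent for β and the intercept estimates the mean
  direct effect.  Inference uses a t(k−2) reference.
- **Weighted median**: the weighted median of ratios (weights bx²/sy², the
  inverse first-order Wald-ratio variance); consistent while valid
  instruments carry more than half of the total weight.
- **Simple / weighted mode**: the argmax of a normal-kernel density of the
  ratios; consistent while the largest homogeneous cluster of instruments
  is the valid one.

A screen hit must satisfy the conjunction rule: IVW p < 0.05 *and* all
five estimates share one sign.  Multiple testing is controlled per
taxonomic level at 0.05/n, n being the number of taxa screened at that
level (defaults 9/16/20/35/131, the composition of the 211-taxon
microbiota GWAS battery the pipeline emulates; synthetic batteries
substitute their own counts, because the denominator must track the tests
actually run).

## Instrument processing

Selection keeps SNPs with p < 1×10⁻⁵ (strict inequality) and minor-allele
frequency ≥ 0.01.  The relaxed threshold reflects the exposure GWAS being
emulated: taxon abundances at n ≈ 18,000 rarely yield genome-wide
significant loci, so the field's convention is the sub-genome-wide cutoff
with a compensating strength filter.  Clumping is the standard greedy
procedure (retain the best remaining p, discard same-chromosome SNPs
within 10,000 kb at r² > 0.001), with two determinism guarantees: p-value
ties break lexicographically by SNP id, so the result is independent of
input row order; and LD is an explicit input — a labelled signed-correlation
matrix, or a block-diagonal list of them — rather than something estimated
from a reference panel, which keeps the algorithm exercisable and testable
without external genotype data.  Pairs absent from the matrix count as
r² = 0.

Strength is screened per SNP: R² from the summary-statistic identity
(algebraically β²/(β² + N·SE²); the 2·EAF(1−EAF) factor cancels, which the
tests assert) and F = R²(N−2)/(1−R²) with K = 1, filtered at F > 10.  The
joint-K variant (summed R², K = k) is also computed and reported, but the
per-SNP form is the enforced filter: it is the conventional weak-instrument
screen and is the quantity the emulated screen reports as "all F > 10".

Harmonization aligns outcome rows to the exposure's effect allele: exact
match kept, swapped alleles negate the outcome beta (and complement its
EAF), strand-complement matches are reconciled before exclusion (default
on, controllable), anything else is dropped as `allele_mismatch`.
Palindromic SNPs are dropped outright — no allele-frequency rescue — and
every input SNP lands either in the harmonized set or in the exclusion log
with exactly one reason.

## Numerical choices

- **IVW variant**: multiplicative random effects by default — the
  fixed-effect SE is inflated by max(1, √(Q/(k−1))).  The truncation at 1
  means the estimator is deliberately conservative under the
  no-heterogeneity null (empirical size ≈ 0.036 at α = 0.05, k = 30); the
  fixed-effect variant (`mode="fe"`) is exactly calibrated there, and the
  calibration test asserts both facts.  With k = 1 IVW degenerates to the
  single Wald ratio with its fixed-effect SE (no heterogeneity is
  estimable), which keeps the k = 1 → Wald-ratio identity.
- **Egger orientation**: SNPs are recoded so β̂x ≥ 0 before fitting — the
  standard identification convention, making the fit invariant to allele
  recoding.  A consequence worth knowing when planting pleiotropy in
  simulations: a nonzero mean direct effect planted on the raw allele
  scale is sign-flipped for negatively oriented SNPs and cancels; a
  recoverable directional pleiotropy must be planted relative to the
  exposure-increasing allele.  The recovery tests therefore build
  harmonized sets with positively oriented instrument effects directly.
- **Bootstrap SEs**: weighted median and both modes use parametric
  resampling (β̂x* ~ N(β̂x, sx), β̂y* ~ N(β̂y, sy)), n_boot = 1000 by
  default, caller-supplied seed, bit-reproducible.
- **Mode bandwidth**: h = φ·0.9·min(SD, MAD/0.6745)·k^(−1/5) with φ = 1,
  density evaluated on a 512-point grid spanning the ratios ± 3h, first
  grid argmax on ties; identical ratios short-circuit to that ratio.
- **MR-PRESSO**: observed statistic is the weighted leave-one-out residual
  sum of squares; the null is rebuilt by parametric simulation
  (n_sim = 1000 default) with the RSS recomputed identically per
  replicate.  P-values use the (r+1)/(n+1) correction so they are valid
  Monte-Carlo p-values and never 0 (the raw fraction is available via
  `add_one=False`).  The outlier test Bonferroni-adjusts each SNP's
  simulated-residual exceedance probability across the k SNPs.  The
  distortion test is out of scope: the emulated workflow uses only the
  global test plus outlier exclusion.
- **Cochran's Q** is parameterized on the Wald-ratio scale
  (Q = Σ (bx²/sy²)(r − β)²), which is identical to the weighted residual
  form of the through-origin regression; the identity
  Q = (k−1)·(IVW inflation factor)² is asserted in tests.
- **Leave-one-out flag**: "a single SNP drives the result" is
  operationalized as any exclusion flipping the estimate's sign or moving
  the IVW p across 0.05 in either direction — the qualitative criterion
  made explicit.
- **p-value floors**: two-sided normal/t/χ² tails are clipped to
  [1e-300, 1] to keep records valid under extreme signals.

## The synthetic generator

`simulate_two_sample` works entirely at the summary-statistic level — the
pipeline consumes nothing else, so individual-level genotypes would add
cost without coverage.  Per SNP: EAF ~ U(maf_range); the theoretical GWAS
SE 1/√(2·EAF(1−EAF)·N) for each study; γⱼ ~ N(0, gamma_sd²) for the
designated instruments and 0 otherwise; αⱼ ~ N(pleio_mean, pleio_sd²);
observed effects as in the model above, with het_sd² added to the outcome
noise variance (but not to its reported SE — that mismatch is what
Cochran's Q detects).  Exposure sampling noise is equicorrelated within LD
blocks at ld_rho (one-factor construction for ρ ≥ 0, per-block Cholesky
otherwise), and the implied block-diagonal correlation matrix is returned
as the clumping input.  Blocks are laid out 20 Mb apart (twice the default
clumping window) across 22 chromosomes so distinct blocks never clump.
Allele pairs are palindromic (A/T, C/G) with probability palindromic_frac;
`outcome_swap_frac` optionally re-encodes outcome rows onto the other
allele to exercise harmonization.  Everything is a pure function of the
config, including the seed.

Defaults emulate the study conditions: n_exp = 18,340 (the microbiota
GWAS sample), a large binary outcome study (n_out = 100,000, log-odds
scale directly — no liability-scale conversion, matching how outcome betas
are interpreted as log-ORs), gamma_sd = 0.08 so a taxon contributes a
handful of sub-genome-wide instruments, causal_beta = 0 (the global null)
and no pleiotropy or heterogeneity unless planted.
`simulate_battery` derives each taxon's seed deterministically from the
master seed (`numpy` SeedSequence spawn keys) and concatenates the
per-taxon outcome rows into one shared outcome study.

What the generator does *not* emulate — realistic allele-frequency
spectra, imputation quality, sample overlap between studies, liability
scaling, and LD beyond equicorrelated blocks.  Passing tests therefore
demonstrate the pipeline's statistical machinery is correct under its own
model, not that real microbiome-GWAS screens are free of those
complications.

## Scale of the validation runs

Monte-Carlo suites use 500 replicates for bias/recovery checks (k = 30
instruments), 1000 for IVW size, 200 × n_sim = 500 for MR-PRESSO
uniformity, and k ≤ 12 instances for the brute-force clumping oracle —
sizes at which the Monte-Carlo error bands in the assertions are already
much tighter than the effects being ruled out.  The weighted-median
contamination check (40% invalid instruments with directional pleiotropy
0.05 on causal_beta = 0.3) asserts a mean bias below 0.05 *and* strictly
below the IVW bias under the same contamination; the residual
median bias (~0.04) is the expected boundary effect of contaminating
almost half the weight, not an implementation artifact.

## Known limitations

- Reverse-MR instrument selection reuses the forward p < 1×10⁻⁵ threshold
  (the emulated workflow does not state one); with few outcome-associated
  SNPs the reverse screen can legitimately report pairs as unanalyzable.
- In forward-causal synthetic pairs the outcome's instruments coincide
  with the taxon's, so the reverse direction is often also nominally
  detectable — the classic caveat motivating, and illustrated by, the
  bidirectional design.
- Multi-allelic sites and indels are rejected at I/O; records are
  biallelic SNPs by construction, and no genome-build lifting is
  attempted.
- The Egger intercept's finite-sample attenuation under exposure
  measurement error (order sx²) is visible in very tight Monte-Carlo
  bands; recovery checks use strong instruments so the band tests the
  intercept, not attenuation.
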