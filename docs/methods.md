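# Methods

## The model

Two-sample Mendelian randomisation treats genetic variants as instruments
for an exposure. For SNP *i*, let γᵢ be its true effect on the exposure
(here standardised childhood BMI, per allele) and Γᵢ its true effect on the
outcome (MS liability, log odds per allele). Under the instrumental-variable
assumptions Γᵢ = b·γᵢ, where *b* is the causal log odds ratio per SD of
exposure. Each estimator recovers *b* from the observed pairs
(β̂ˣᵢ, σˣᵢ; β̂ʸᵢ, σʸᵢ):

- **Wald ratio** (single SNP): β̂ʸ/β̂ˣ, SE σʸ/|β̂ˣ| (first-order delta
  method).
- **IVW**: weighted regression of β̂ʸ on β̂ˣ through the origin, weights
  1/σʸ². The multiplicative-random-effects (MRE) variant — the primary
  method — multiplies the fixed-effect SE √(1/Σβ̂ˣ²/σʸ²) by
  max(1, √(Q/(n−1))), so over-dispersion (horizontal pleiotropy,
  heterogeneity) widens but never narrows the interval. P-values are
  standard normal.
- **MR-Egger**: the same weighted regression with a free intercept, after
  orienting each SNP to its exposure-increasing allele. The intercept
  estimates directional pleiotropy; the slope is a pleiotropy-robust (but
  low-precision) causal estimate. Both SEs carry a max(1, √(Q/(n−2)))
  inflation and p-values use t(n−2).
- **Weighted median / modes**: computed over per-SNP Wald ratios with
  weights equal to inverse *second-order* delta-method ratio variances
  (σʸ²/β̂ˣ² + β̂ʸ²σˣ²/β̂ˣ⁴). Median: interpolated 0.5-quantile of the
  weight-sorted ratios. Modes: argmax of a Gaussian-kernel density of
  ratios, bandwidth 0.9·min(sd, MAD)·n^(−1/5) scaled by φ (default 1),
  evaluated on a 512-point grid extended three bandwidths beyond the data.
  SEs by parametric bootstrap (resampling β̂ˣ, β̂ʸ from normals; SD for the
  median, normal-scaled MAD for the modes, whose bootstrap distribution is
  heavy-tailed).

Estimates are reported on the log-odds and odds-ratio scales with 95% CIs
fixed at ±1.96·SE; exponentiation reproduces published abstract-style OR
presentations.

## Sensitivity statistics

- **Cochran's Q** about the IVW fit: Σwᵢ(rᵢ − b̂)² with wᵢ = β̂ˣᵢ²/σʸᵢ²;
  chi-square on n−1 df.
- **Instrument strength**: per-SNP F = (β̂ˣ/σˣ)²; a set mean above 10 is
  the conventional weak-instrument bar.
- **Steiger filtering**: variance explained approximated per SNP by
  r² = z²/(z² + N), with N the GWAS sample size on the exposure side and
  the effective size 4/(1/cases + 1/controls) on the case-control side;
  SNPs with r²_out > r²_exp are removed. The z²/(z²+N) form is one of
  several reasonable approximations for a binary outcome; it reproduces the
  null filtering result on the packaged data.
- **Pleiotropy residual test (PRESSO-style)**: observed RSS
  Σᵢ wᵢ(β̂ʸᵢ − b̂₍₋ᵢ₎β̂ˣᵢ)² with b̂₍₋ᵢ₎ the leave-one-out IVW slope,
  compared with RSS from parametric simulations under no pleiotropy
  (β̂ˣ* ~ N(β̂ˣ, σˣ), β̂ʸ* ~ N(b̂₍₋ᵢ₎β̂ˣ, σʸ)); add-one correction so p is
  never 0. Per-SNP outlier p-values compare each observed deviation with
  its own simulated distribution, Bonferroni-multiplied by n; outliers at
  adjusted p < 0.05. The outlier-corrected estimate refits the remaining
  SNPs by weighted through-origin least squares with the classical
  regression SE (residual-dispersion scaled, *no* floor at 1) and a t(n−1)
  p-value — the convention of the original formulation, and the one that
  reproduces the published corrected birth-epoch estimate (−0.06, p 0.69);
  the MRE-with-normal-p convention used everywhere else gives p 0.67 here.
  The distortion test compares the percentage change of the estimate with
  the change from dropping equally many randomly chosen non-outlier SNPs.

## Multivariable MR

The residual method regresses β̂ʸ on the secondary-exposure betas (weights
1/σʸ², no intercept — the summary-data convention; an intercept option
exists because the underlying two-step description is ambiguous at summary
level), then regresses the residuals on β̂ˣ through the origin with MRE
inflation. With all secondary betas zero this reduces to univariable
MRE-IVW at machine precision. The joint method fits both exposures in one
weighted regression without intercept (classical WLS SE, t(n−2)).

Identifiability caveat: when the secondary effects are close to a scalar
multiple of the primary ones (the fully-age-shared case — empirically the
situation for late-childhood vs adult BMI), the direct effect is not
identifiable; the residual estimate then collapses toward zero and a
collinearity warning is attached. Simulations with an independent secondary
trait recover direct effects without this degeneracy.

## Instrument selection and harmonisation

Selection: strict p < 5×10⁻⁸; greedy clumping keeps the smallest-p SNP per
LD region (r² > 0.001 within 10,000 kb; ties broken by smaller SE then
rsID for determinism; SNPs missing from the LD matrix are an error unless
explicitly allowed as unlinked — silent retention would inflate
instruments); MHC chr6:25–35 Mb (hg19, 1-based inclusive) removed; epoch
amalgamation keeps each SNP's smallest-p time point.

Harmonisation flips the outcome beta (and complements its frequency) when
the outcome's effect allele is the exposure's other allele, resolving
strand complements for non-palindromic SNPs and never guessing on
ambiguity. The default palindromic policy is **strict discard**: it
reproduces the published instrument counts (7 of 8 at birth — dropping the
C/G SNP rs7310615 — and 4 of 5 in later childhood, dropping rs545608).
The often-quoted alternative, discarding only when inferred MAF > 0.42, is
available as `maf_threshold` but does *not* reproduce those counts
(rs545608 has exposure MAF 0.234 and would be kept), so it is not the
default. The packaged instrument tables are post-selection (already
clumped and MHC-filtered, no positions printed), so the pipeline skips
those stages for fixture runs and the MHC filter is exercised on synthetic
data.

## Synthetic data

The generator simulates summary statistics directly — no individual-level
genotypes — which is sufficient for every estimator here and fast. True
per-SNP exposure effects are N(0, sd²) (optionally folded positive so that
effect alleles are exposure-increasing, which is what makes *directional*
pleiotropy directional after Egger's orientation); observed betas add
normal noise with the analytic SE 1/√(2·MAF·(1−MAF)·N), using the effective
sample size 4/(1/cases + 1/controls) on the outcome side. Outcome effects
follow Γ = b·γ + m·βsec + α with α balanced, directional, or correlated
with γ (InSIDE violation). The longitudinal variant draws per-SNP effect
vectors across time points from a multivariate normal with a user
correlation matrix (PSD-checked).

Defaults mirror the study conditions: N_exp = 28,681; 14,802 cases /
26,703 controls; MAF 0.2–0.8; effect SD 0.08, which puts typical
instruments at the published loci's strength (F ≈ 30–60).

What the generator does not emulate: LD between instruments (SNPs are
post-clumping by construction), allele-frequency differences between
samples, population stratification, winner's curse from discovery-sample
selection, and sample overlap. Passing simulation tests therefore show
estimator correctness under clean two-sample assumptions, not robustness
to those artefacts.

## Numerical and design choices

- Tie-breaks and orderings are deterministic everywhere (mergesort,
  explicit tie keys); all stochastic components (bootstrap, PRESSO
  simulations, generator) take a seed and are reproducible bit for bit.
- The mode estimators' bandwidth convention is stated above but is the one
  genuinely under-determined convention in the suite; published mode values
  are treated as approximate (agreement within 0.02).
- The weighted median is exactly consistent only when SNPs contributing at
  least half the weight are valid instruments. When *every* SNP carries a
  balanced pleiotropic term of SD comparable to the typical outcome effect,
  it attenuates slightly toward the null (~10% at pleiotropy SD 0.02 in the
  default scenario) — a finite-sample property of the estimator, visible in
  the brute-force oracle as well, and the reason the recovery tests pair
  IVW/Egger with the pleiotropic scenario and the median with the
  all-valid-instrument one.
- Reproduction of the published table from the packaged per-SNP data is
  asserted at 1e-4 absolute: the shipped betas/SEs carry at most six
  significant figures, and propagating that input rounding moves the
  estimates by up to ~5e-5, so tighter agreement is not attainable from the
  printed values.
- Problem sizes in tests (e.g. 10,000 PRESSO simulations for the birth
  epoch, 200-replicate recovery studies, 100-replicate uniformity checks)
  were chosen so the full suite runs in well under a minute while keeping
  Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

- Positions/chromosomes are optional; operations that need them (MHC
  filter, distance windows) fail loudly rather than imputing.
- The PRESSO distortion test has no published value to check against and is
  property-tested only.
- Palindromic-SNP frequency inference (aligning by MAF rather than
  discarding) is deliberately not implemented.
- Conditional F statistics / formal instrument-strength diagnostics for
  multivariable MR are out of scope; collinearity is reported via warning.
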