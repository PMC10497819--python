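# Methods

`mrmediate` implements a two-sample Mendelian randomization (MR) analysis
pipeline with two-step mediation, together with a summary-level GWAS
simulator that provides ground truth for every stage. This note documents
the statistical model, the estimators and their numerical conventions, the
simulator's design and its limits, and the choices made where the design was
genuinely open.

## Model and notation

For each instrument SNP *j* we observe two-sample summary statistics: the
SNP–exposure association γ̂ⱼ with standard error σ_γⱼ, and the SNP–outcome
association Γ̂ⱼ with standard error σ_Γⱼ, both expressed per copy of a shared
effect allele after harmonization. Under the instrumental-variable
assumptions (relevance, independence, exclusion restriction), each SNP's
Wald ratio Γⱼ/γⱼ estimates the causal effect θ of the exposure on the
outcome; the estimators below combine the ratios with different robustness
properties. Continuous traits are analyzed in SD units and binary outcomes
on the log-odds scale, so θ is a log odds ratio per SD of exposure.

For mediation, the two-step decomposition uses three estimates:

* β₀ — total exposure→outcome effect (univariable MR),
* β₁ — exposure→mediator effect (univariable MR),
* β₂ — mediator→outcome effect adjusted for the exposure (multivariable MR).

The mediated (indirect) effect is β₁β₂ and the mediation proportion is
PM = β₁β₂/β₀, with delta-method variance

Var(PM) = (β₂/β₀)² Var(β₁) + (β₁/β₀)² Var(β₂) + (β₁β₂/β₀²)² Var(β₀),

treating the three estimates as independent — they come from separate
regressions on non-overlapping or partly different samples, and no
cross-covariances are estimable from summary data. PM values outside [0, 1]
are reported as computed and flagged, never truncated.

## Estimators

**IVW.** Weighted least squares of Γ̂ⱼ on γ̂ⱼ through the origin with weights
1/σ_Γⱼ², algebraically identical to a fixed-effect meta-analysis of the Wald
ratios with weights (γⱼ/σ_Γⱼ)². Cochran's Q (χ², J−1 df) is always reported.
Random-effects IVW is multiplicative: the fixed-effect SE is scaled by
√φ with φ = max(1, Q/(J−1)), so heterogeneity can inflate but never deflate
the SE. This is the convention of mainstream two-sample MR tooling.

**MR-Egger.** Weighted regression of Γ̂ⱼ on γ̂ⱼ *with* intercept after
flipping each record so γ̂ⱼ ≥ 0 (the estimator is not orientation-invariant).
The intercept estimates average directional pleiotropy; the slope is the
pleiotropy-adjusted causal effect under the InSIDE assumption. Both SEs
carry φ = max(1, Q/(J−2)).

**Weighted median.** Per-SNP ratios are sorted; with cumulative standardized
weights pⱼ = (Sⱼ − wⱼ/2)/S_J (wⱼ = (γⱼ/σ_Γⱼ)²), the estimate interpolates
the ratio at p = 0.5. Consistent when ≥ 50% of the weight comes from valid
instruments. SE by parametric bootstrap: γ and Γ resampled from normals with
their reported SEs, default 1000 replicates, explicit seed.

**Weighted mode.** Argmax on a 512-point grid of a weighted Gaussian kernel
density over the ratios, bandwidth = factor × 0.9·min(SD, MAD/0.6745)·J^(−1/5)
(modified Silverman; default factor 1). If all ratios coincide the common
value is returned. Bootstrap SE as above.

**MR-PRESSO.** Global test: observed residual sum of squares
RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₋ⱼ γ̂ⱼ)² with leave-one-out IVW estimates β̂₋ⱼ; the null
distribution is built by drawing Γ*ⱼ ~ N(β̂₋ⱼ γ̂ⱼ, σ_Γⱼ²) and
γ*ⱼ ~ N(γ̂ⱼ, σ_γⱼ²) (default 1000 simulations, vectorized) and the p-value
is the exceedance fraction. Outlier test: each SNP's observed weighted
squared residual against its own simulated distribution, Bonferroni-corrected
by J, flagged at 0.05. Distortion test: the shift of the outlier-removed IVW
estimate against a null of random removals of the same count. All three use
one explicit seed and are exactly reproducible.

**Multivariable MR.** MV-IVW regresses Γ̂ⱼ on the K columns of exposure
effects with no intercept and weights 1/σ_Γⱼ²; SEs come from the weighted
information matrix with φ = max(1, Q/(J−K)). MVMR-Egger adds an intercept
after orienting every record on a caller-chosen exposure (default the
first), with φ df J−K−1. A rank-deficient design raises an error naming a
collinear pair; an exposure column that is identically zero is excluded from
the fit and reported as NaN, so the remaining coefficients reduce exactly to
the lower-dimensional model. P-values are normal-based everywhere (GWAS
large-sample convention) and all 95% CIs use z = 1.959964.

## Instrument construction

Selection takes genome-wide-significant SNPs (default p < 5×10⁻⁸) and
applies greedy p-ordered LD clumping: candidates sorted by ascending p
(snp_id breaks ties), accepted iff panel r² < 0.001 with every accepted SNP
within 10,000 kb on the same chromosome. Greedy-by-p is the field's
"clumping" semantics and is deterministic; the output is invariant to input
row order. Instruments missing from an outcome dataset are replaced by the
best panel proxy with r² ≥ 0.8 (ties: smaller distance, then lexicographic
id), taking the proxy SNP's own effect sign-aligned by the dosage
correlation.

Harmonization aligns the outcome record to the exposure's effect allele:
matching alleles kept, swapped alleles negated, strand flips resolved by
complementing. Palindromic (A/T, C/G) SNPs carry no strand information in
their alleles, so they are oriented by allele frequency: kept only when both
EAFs exist and fall outside (0.42, 0.58), with the sign set by whether the
frequencies lie on the same side of 0.5. Applying harmonization twice is a
no-op, and flipping both alleles and the beta of an outcome record leaves
the harmonized result bit-identical.

Composite-phenotype instruments (e.g., an insulin-resistance score defined
by higher fasting insulin, higher triglycerides and lower HDL-C) are
weighted by a per-SNP fixed-effect IVW pool of the orientation-aligned
absolute component betas; components that lower the composite enter with
inverted sign, so a sign-corrected component yields the same pooled value.
Instrument strength is summarized as the mean per-SNP F = (γⱼ/σ_γⱼ)², with a
warning below the conventional threshold of 10.

The reverse-causation check runs the full univariable pipeline with the
mediator as exposure. Variants that are genome-wide significant for the
original exposure are excluded from the mediator instrument set first:
such shared instruments act on the exposure through the forward path and
their reverse Wald ratios (≈ 1/β₁, with small SEs) would mimic reverse
causation even when no mediator→exposure path exists. This is an
instrument-disjointness rule, not Steiger filtering (directionality
filtering by explained variance is deliberately not implemented).

A mediation proportion is reported only for pathways passing a four-step
eligibility screen: (1) total effect significant; (2) exposure-adjusted
mediator→outcome effect significant; (3) direct (β₀ − β₁β₂) and indirect
(β₁β₂) effects share a sign; (4) exposure→mediator significant while the
reverse estimate is not. Benjamini–Hochberg q-values are computed within
caller-declared analysis families (statsmodels implementation behind the
module surface).

## The simulator

Summary statistics are simulated directly at the summary level: true
per-SNP effects plus independent normal noise with the standard GWAS error
se = √(1/(2·MAF·(1−MAF)·n)), with MAF ~ Uniform(0.05, 0.5). Binary-outcome
effects are drawn directly on the log-odds scale with n read as an effective
sample size. The three samples use independent noise (no overlap), matching
the two-sample design. Defaults are set at a realistic study scale: a
biobank-size exposure GWAS (n = 450,000), a consortium-size mediator GWAS
(n = 150,000), a case-control outcome with effective n = 200,000, J = 100
exposure instruments and 50 mediator-specific instruments, and a causal
chain θ (total) = 0.2, β₁ = 0.4, β₂ = 0.15, hence a true mediated fraction
of 0.30.

True instrument effects are drawn N(0, h²/J) and floored at |z| = 7.5 so
that ≥ 90% of instruments are recovered at p < 5×10⁻⁸ under their own
sampling noise. The default per-trait h² is 0.25, in line with the SNP
heritability of anthropometric traits; besides realism, a wide
instrument-strength spectrum is what makes MR-Egger identified — with a
much smaller h² the floor dominates, |γ| becomes nearly constant across
SNPs, and the Egger slope is unestimable at any replicate size.

Mediator-specific instruments affect the mediator only and reach the
outcome only through β₂. They are not optional decoration: the mediator
column of the multivariable design would otherwise be β₁γⱼ — exactly
proportional to the exposure column — and β₂ would be unidentified, just as
a real two-step analysis is impossible without the mediator's own GWAS hits.

Pleiotropy modes for the direct SNP→outcome effects αⱼ: `none`; `balanced`
(N(0, sd²)); `directional` — sign(γⱼ)·N(mean, sd²), i.e. a shift *relative
to the exposure-increasing allele*, since an unconditional shift against
symmetrically signed instruments is orthogonal to instrument strength and
biases nothing; and `inside_violating` (αⱼ correlated with γⱼ).
`pleiotropy_frac` confines pleiotropy to a random subset of instruments (the
70%-valid weighted-median scenario); `outlier_frac`/`outlier_multiplier`
inflate a subset's αⱼ for outlier-detection experiments. A configurable
fraction of outcome records is emitted with swapped alleles and negated
betas to exercise harmonization; allele pairs are non-palindromic by
construction.

The LD panel contains each instrument as an independent variant with
dosages Binomial(2, MAF) over 500 samples, instruments spaced > 10 Mb apart
so clumping windows do not interact. `simulate_ld_block` generates
controlled LD via haplotype copy-with-mutation (copy probability √r²),
realizing consecutive-pair r² within about ±0.1 of the target at panel
size ≥ 500.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: realistic genome-wide LD structure (only
single blocks), population stratification, sample overlap, case-control
ascertainment and the binary-trait noncollapsibility of odds ratios, allele
frequency differences between samples, and winner's-curse bias in the
exposure effect estimates. The weak-instrument regression dilution that the
simulator *does* reproduce is visible as a ≈1–5% attenuation of IVW and
MVMR estimates at the default instrument strength.

## Numerical conventions and problem sizes

Seeds are explicit everywhere randomness enters (simulator, bootstraps,
MR-PRESSO, distortion nulls); identical seeds give bit-identical results.
The packaged experiments use 500 replicates for estimator-recovery means and
CI coverage, 100 runs × 1000 simulations for MR-PRESSO calibration and
power, and 1000 triples for delta-method CI coverage — sizes at which the
Monte-Carlo error of each reported mean is well inside the tolerance being
checked, while the whole suite runs in well under a minute. Ratio p-values
use the two-sided normal tail; p-values that would underflow to zero are
reported at the smallest positive double.

Degenerate inputs are handled explicitly: zero γ in a Wald ratio, an
all-zero γ vector in IVW, monomorphic panel variants in r² (an error for
the direct query; treated as independent during clumping, where LD is simply
unassessable), identical ratios in the weighted mode (bandwidth zero →
common value returned), and an empty harmonized set (an error naming the
stage).

## Known limitations

* First-order Wald-ratio SEs ignore σ_γ (a second-order option exists); with
  strong instruments the difference is negligible.
* The delta-method CI for PM is a linearization: with a noisy total effect
  (CV ≳ 0.2) the true sampling distribution of PM is heavy-tailed and the
  moment SD exceeds the delta SE by ~10%, though the central 95% interval
  remains calibrated (coverage 90–97% in the packaged experiments).
* MVMR estimates carry weak-instrument attenuation; conditional F statistics
  are not implemented.
* No Steiger filtering, MHC exclusion, liftover, or remote LD services; the
  LD panel is always local.
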