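# Methods

## Setting

Two-sample Mendelian randomisation treats genetic variants as instruments
for a modifiable exposure. With summary statistics from non-overlapping
samples — per-SNP exposure effects γ̂ⱼ with standard errors, and outcome
effects Γ̂ⱼ on the log-odds scale for a binary outcome — the causal effect β
is identified under three assumptions: the instruments predict the exposure
(relevance), are independent of exposure–outcome confounders, and affect the
outcome only through the exposure (no horizontal pleiotropy). The package
implements the estimators under this model, the summary-data plumbing around
them, and a generator that produces data from the model with every
assumption individually violable.

## Estimators

**Wald ratio.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with the first-order SE se(Γ̂ⱼ)/|γ̂ⱼ|. The
exposure-side uncertainty is ignored at first order (standard no-measurement
-error, "NOME", approximation); this is accurate when instrument F
statistics are large and is the convention the ratio-based diagnostics
(Cochran's Q, funnel precision) follow as well.

**IVW.** Weighted least squares of Γ̂ on γ̂ through the origin with weights
1/se(Γ̂ⱼ)², algebraically identical to the ratio-weight (γ̂ⱼ²/se(Γ̂ⱼ)²)
average of the Wald ratios. The default variance model is multiplicative
random effects: the fixed-effect SE is scaled by the weighted residual
standard deviation *floored at 1*, so over-dispersion (heterogeneity,
pleiotropy) widens the interval while under-dispersion never narrows it
below the fixed-effect SE. A `fixed` model is available by flag. Inference
is normal. A single instrument degrades gracefully to the Wald ratio.

**MR-Egger.** Each SNP is first oriented so γ̂ⱼ ≥ 0 (negating both betas
where needed — the estimator is not invariant to per-SNP reorientation, so a
convention is required and this is the standard one). WLS of Γ̂ on γ̂ with a
free intercept and weights 1/se(Γ̂ⱼ)²: the slope estimates β under InSIDE
(pleiotropic effects uncorrelated with instrument strength), the intercept
estimates mean directional pleiotropy. Inference uses the estimated residual
scale and t(k−2) — *without* flooring the residual scale: flooring makes the
intercept test conservative (empirical size ≈ 2–3% at nominal 5%), whereas
standard WLS t-inference is exact under the no-pleiotropy null with normal
outcome noise. The same choice applies to MVMR-Egger (t with k−m−1 df). The
IVW flooring is retained because for IVW the SE is a robustness device, not
a calibrated test.

**Weighted median.** Ratio estimates are ordered; with normalised ratio
weights wⱼ = γ̂ⱼ²/se(Γ̂ⱼ)², the estimate is the value where the cumulative
weight (evaluated at wⱼ/2 past each point) crosses 0.5, linearly
interpolated. Consistent when valid instruments carry >50% of the weight.

**Mode estimators.** The ratio estimates are smoothed with a normal kernel,
bandwidth φ·0.9·min(SD, MAD/0.6745)·k^(−1/5) (modified Silverman rule;
φ = 1 by default); the estimate is the density argmax on a 512-point grid
spanning the data ±3 bandwidths, unweighted (simple mode) or weighted by
inverse ratio variance (weighted mode). Consistent when the largest group of
instruments sharing a ratio value is the valid group. If all ratios
coincide, that common value is returned directly.

Median and mode SEs come from a seeded parametric bootstrap (default 1,000
draws of γ̂ⱼ and Γ̂ⱼ from normal distributions centred on the observed
values with their reported SEs); whether analytic approximations or
bootstrap should be preferred is unsettled, and bootstrap was chosen for
transparency and reproducibility — the seed is mandatory, never implicit.

**Diagnostics.** Cochran's Q over ratio estimates with ratio weights
(chi-square, k−1 df); the Egger intercept test; the mean per-SNP F statistic
γ̂ⱼ²/se(γ̂ⱼ)² (values below ~10 flag weak-instrument bias); funnel-plot
coordinates (ratio vs precision |γ̂ⱼ|/se(Γ̂ⱼ)) emitted as data, not figures.

## Multivariable MR

With m exposures, WLS of Γ̂ on the k×m matrix of exposure betas (no
intercept; weights 1/se(Γ̂ⱼ)²) gives each exposure's direct effect
conditioning on the others; with an upstream→downstream chain between
exposures this separates direct from mediated effects, which univariable MR
of the upstream exposure conflates. Residual scaling is floored at 1 as in
IVW. Rank-deficient exposure matrices raise a collinearity error naming the
offending exposures. MVMR-Egger adds an intercept after orienting each SNP
to a chosen exposure's positive direction (the first, by default).

**Conditional instrument strength** follows the Sanderson–Windmeijer idea:
regress one exposure's betas on the other exposures' betas (weights
1/se of the target exposure's betas, no intercept), form
Q_x = Σ residⱼ²/se(γ̂ⱼ)², and report F = Q_x/(k−m+1) with a
chi-square(k−m+1) upper-tail p-value for the null of *no conditional
signal* (small p = conditionally relevant instruments). The exact
normalisation is stated here and in the JSON report because several variants
circulate; the statistic equals the marginal mean F when exposures are
orthogonal and falls to 0 when one exposure duplicates another.

## Harmonisation

SNPs are matched by identifier only (the simulation-first design has no
genome-build ambiguity). Outcome records are re-expressed on the exposure's
effect allele: direct matches are kept or sign-flipped; complementary-allele
matches are strand-corrected first; palindromic SNPs (A/T, G/C) cannot be
strand-resolved from alleles and are handled by policy — `drop`, or the
default `infer`, which aligns by allele-frequency agreement and drops SNPs
whose frequency on either side lies within 0.08 of 0.5 (the default
behaviour of widely used harmonisation tooling). Every disposition is
logged per SNP. Harmonisation changes only signs, labels and frequencies —
never magnitudes, SEs or p-values — and all downstream estimators are
invariant to arbitrary per-SNP allele relabelling of the inputs (checked
bit-for-bit in the tests).

## Instrument selection

Significance filtering uses strict `p < threshold` (genome-wide 5e-8;
suggestive 5e-6 corresponds to roughly one false positive per GWAS).
Clumping is greedy: take the smallest-p remaining SNP as index, remove SNPs
on the same chromosome within the window (default 10,000 kb, the cited
clumping tool's default) with r² ≥ the threshold (default 0.001), repeat.
Ties in p break by (chrom, pos, snp_id) for determinism; SNPs absent from
the LD panel are dropped with a warning rather than assumed independent.
Enrichment admits candidate SNPs from a correlated trait when they associate
with the target exposure at 0.05/n_tests, unions them with the base
instruments and re-clumps, so candidates in LD with existing instruments are
admitted and then pruned.

## Meta-analysis

Fixed-effect inverse-variance weighting on effect sizes (β_meta =
Σβᵢ/seᵢ² / Σ1/seᵢ²; se_meta = (Σ1/seᵢ²)^(−1/2)) — the SE-based scheme, not
sample-size z-weighting. Tables are aligned pairwise to the first table's
allele convention; the analysed set defaults to the union of SNPs with a
per-SNP cohort count (intersection by flag), since cohort-specific coverage
is the norm when a small cytokine GWAS meets a larger one.

## Binary-trait scale conversion

Linear (mixed-model) betas on a 0/1 phenotype convert to log odds ratios by
β/(μ(1−μ)), SEs likewise, with μ the case fraction — the first-order
expansion of the logistic link around the population prevalence. It is
exact for z-scores and accurate to within a few percent for |log-OR| ≤ 0.3
and MAF ≥ 0.1 (validated against per-SNP logistic regression on simulated
cohorts); accuracy degrades for large effects, where the expansion is no
longer adequate. This is a log-odds conversion: a genuine liability-scale
(probit-threshold) conversion is a different transformation and is
deliberately not attempted.

## Synthetic data

`simulate_two_sample` draws true SNP-exposure effects γⱼ ~ N(0, γ_sd²); a
second exposure receives θ·γ₁ⱼ plus its own effects (the biomarker chain);
outcome effects are Γⱼ = Σβₘγₘⱼ + αⱼ with pleiotropy αⱼ zero (`none`,
under which InSIDE holds identically), centred normal (`balanced`), or
mean-shifted normal (`directional`) applied to a configurable fraction of
SNPs. Directional pleiotropy is defined on the exposure-increasing allele
orientation — with sign-symmetric γ a fixed-sign α on arbitrary allele
labels would average out and bias nothing, which is not what "directional"
means. Observed betas add independent noise in each sample with the
variance-standardised closed forms se = (2n·maf(1−maf))^(−1/2) for
quantitative traits and se = (2n·maf(1−maf)·μ(1−μ))^(−1/2) on the log-odds
scale for the binary outcome (optionally emitted on the 0/1 scale to
exercise the conversion). LD is injected at the level of true effects —
block members share the index SNP's signal attenuated by √r² and the
realised block-structured r² matrix is returned — giving clumping a
meaningful target without haplotype simulation. All randomness flows from
one integer seed with deterministic sub-streams.

Scenario defaults mirror the motivating study's magnitudes: outcome
n = 153,560 at a 4.37% case fraction (2.26% for the stricter outcome
definition), exposure sample sizes 8,296 and 48,164, causal effects
(0, −0.08) on the log-OR scale with chain θ = 0.5, γ_sd = 0.05 (instrument
F well above 10 at the larger exposure n, near the weak-instrument boundary
at the smaller — as in practice).

`simulate_cohort` generates Hardy-Weinberg genotypes, a liability-threshold
binary phenotype at the configured case fraction, and per-SNP linear
(0/1-outcome) and logistic summary statistics; it is the independent oracle
for the scale conversion and for null p-value calibration, and is capped at
desk scale (n ≤ 100,000).

**What the generator does not emulate:** genome-wide realistic LD,
population stratification, sample overlap between exposure and outcome
GWASs, relatedness, winner's-curse selection of instruments from the same
sample, and case-control ascertainment effects. Passing tests therefore
validate the estimators and plumbing under the stated model, not robustness
to these real-data complications.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 1,000 random instances
for the IVW/ratio algebraic identity (tolerance 1e-10); 1,000 replicates
(500 in the script) at k = 50 instruments for IVW bias and coverage and for
intercept-test size; 500 replicates for the 30%-invalid robustness ordering
and the k = 60 chain/mediation recovery; 200 random instances (k ≤ 12)
against the brute-force clumping oracle; one n = 20,000 cohort for the
scale-conversion oracle. These sizes make Monte-Carlo error small relative
to the tolerances being checked while keeping the default run quick on a
single core.

## Known limitations

* Wald/IVW/median/mode inference ignores exposure-side measurement error
  (first-order only); weak instruments attenuate estimates, as the mean and
  conditional F statistics are there to flag.
* The log-odds conversion is first-order; no liability-scale transform.
* Clumping requires an explicit LD matrix; no reference-panel computation
  or proxy-SNP lookup.
* Multi-allelic variants and indels are rejected; no genome-build liftover.
* MVMR is intended for a handful of exposures, not high-dimensional
  screens; no MVMR-median/lasso, MR-PRESSO, Steiger filtering or radial MR.
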