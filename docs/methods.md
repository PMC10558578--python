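# Methods

`mrmediate` implements a two-sample Mendelian-randomization (MR) mediation
analysis for a single exposure–mediator–outcome triple (in the motivating
application: an adiposity trait, log C-reactive protein, and grip strength
in kg, stratified by sex), together with a parallel observational
two-regression mediation arm and a synthetic-data generator that makes
every stage verifiable by parameter recovery.

## Model and estimands

All estimators work on per-SNP association estimates
(β̂_Xj, β̂_Mj, β̂_Yj with standard errors) for k harmonized, mutually
LD-independent SNPs, estimated in non-overlapping samples so cross-trait
sampling covariance is zero. The structural model is linear and recursive:

- total effect θ_total of X on Y (univariable MR),
- direct effect θ_dir of X on Y conditional on the mediator M
  (multivariable MR),
- indirect effect θ_ind = θ_total − θ_dir (difference method), with
  SE √(se²_total + se²_dir) (propagation of errors, zero covariance
  between the two arms' estimates).

### Univariable estimators

**IVW.** The inverse-variance-weighted mean of per-SNP Wald ratios
r_j = β̂_Yj/β̂_Xj with first-order weights w_j = β̂²_Xj/se²_Yj, under a
multiplicative random-effects model: the fixed-effect SE 1/√Σw_j is
inflated by max(1, √(Q/(k−1))), so under-dispersion never shrinks the SE.
The ratio form and the weighted regression-through-origin form are
algebraically identical with these weights; the second is kept as an
internal cross-check. Heterogeneity is reported as Cochran's Q
(χ²_{k−1} under homogeneity) and I² = max(0, (Q−df)/Q)·100.

**MR-Egger.** Weighted regression of β̂_Yj on β̂_Xj with intercept
(weights 1/se²_Yj), after orienting each SNP to the exposure-increasing
allele (joint sign flips). The slope is the pleiotropy-robust estimate
under the InSIDE assumption; a non-zero intercept indicates directional
horizontal pleiotropy. Random-effects scaling uses df k−2.

**Weighted median.** Ratios are sorted; with standardized cumulative
weights s_j = (Σ_{i≤j}w_i − w_j/2)/Σw the estimate interpolates r at
s = 0.5. It is consistent while SNPs carrying ≥ 50% of weight are valid.
Its SE comes from a parametric bootstrap (β̂s resampled from normals at
their stated SEs; default 2,000 iterations, seed required); the SE is the
bootstrap SD with a normal approximation. The bootstrap count and SE
method are package defaults, flagged in the result metadata.

### Multivariable estimators and diagnostics

**MVMR-IVW.** Weighted regression of β̂_Yj on (β̂_Xj, β̂_Mj) without
intercept, weights 1/se²_Yj, multiplicative random-effects scaling on
df k−2. An identically-zero mediator column is treated as the nested
univariable model (θ_M = 0 with infinite SE) rather than a rank error;
genuine collinearity raises.

**Conditional F.** Instrument strength for one exposure given the other,
in the two-sample Q formulation with zero cross-trait covariance:
F_cond = min_δ Σ_j (β̂_1j − δβ̂_2j)²/(se²_1j + δ²se²_2j) / (k−1).
A numerical caution discovered during development: as |δ| → ∞ this
objective tends to Σ(β̂_2j/se_2j)², so a *global* minimisation runs away
to a spurious asymptote whenever the exposure of interest is the stronger
set. The statistic is therefore computed at the interior minimum near the
weighted regression of β̂_1 on β̂_2 (IRLS fixed point, polished by bounded
Brent search with a grid fallback on the same neighbourhood). The
rule-of-thumb adequacy threshold is F_cond > 10. At the generator's
default study-scale conditions the exposure's conditional F is ≈ 20.

**Q_A.** Generalised Cochran's Q at candidate direct effects (θ_X, θ_M):
each squared residual (β̂_Yj − θ_Xβ̂_Xj − θ_Mβ̂_Mj)² is weighted by
1/(se²_Yj + θ²_X se²_Xj + θ²_M se²_Mj + 2θ_Xθ_M ρ se_Xj se_Mj), where ρ
is the phenotypic correlation between exposure and mediator (zero when
omitted; the cross-term's functional form is stated in result metadata
because published software does not print it). Under correct
specification, the mean of Q_A at the estimate is ≈ k − 2; the field's
rule of thumb compares Q_A to ≈ k, and the exact χ² df is also reported.

**Q-het.** Direct effects estimated by minimising Q_A: a Nelder–Mead
simplex (tolerance 1e-8) started at the MVMR-IVW solution, with an
11×11 coarse-grid multi-start fallback. Confidence intervals are
percentile bootstrap over parametric resamples of all β̂s (default
2,000 replicates; `n_boot=0` returns the point estimate alone);
replicates restart from the point estimate and skip the grid. More than
1% non-convergent replicates is a hard error. Q-het is always computed
alongside MVMR-IVW; the weak-instrument/heterogeneity trigger
(F_cond < 10 or Q_A > k) only decides which is labelled primary in
pipeline reports.

**Weak-instrument behaviour.** With first-order weights, IVW-family
estimators carry a finite-sample attenuation of order 1/F. At the
default study-scale conditions this is ≈ 2% for the univariable total
effect but ≈ 8% for the MVMR-IVW direct effect (conditional F ≈ 20),
which is why Q-het is the direct-effect estimator of record in the
recovery analyses: it removes essentially all of that attenuation
(measured bias within Monte-Carlo error of zero at the same conditions).

### Observational arm

Equation-wise least squares on the recursive system — model i
(M ~ X + C), model ii (Y ~ X + M + C) and a total-effect model
(Y ~ X + C) with identical covariate sets — coincides with the joint-ML
structural-equation estimates for such systems. The indirect effect is
total − direct, which equals the product a₁b₂ exactly (asserted at
1e-10); its SE uses the delta method on the product form,
√(b₂²se²_{a₁} + a₁²se²_{b₂}), since a₁ and b₂ come from separate fits
with zero cross-equation covariance. The MR arm instead uses
zero-covariance propagation of errors exactly as stated above; both
choices are recorded in output metadata. The proportion mediated
(indirect/total) is suppressed when |total| ≤ 2·se_total, where the
ratio is uninterpretable.

Phenotype preparation follows the study conventions: grip strength is the
maximum recorded value (> 0) of either hand with zeros treated as
missing; the exposure is z-scored within stratum; the mediator is
natural-logged (non-positive values dropped with reasons counted).

## Instrument assembly

- **Clumping** is greedy by ascending p-value after the significance
  filter (p < 5×10⁻⁸), ties broken lexicographically by rsid; a candidate
  is accepted iff its r² with every accepted SNP on the same chromosome
  within 250 kb is below 0.001. Output is invariant to input row order.
- **Proxies**: when an index SNP is absent from a trait's summary
  statistics, the donor SNP with the highest r² strictly > 0.8 substitutes
  (ties: smaller p, then rsid); proxy betas are used as-is after allele
  alignment, with no r² attenuation correction.
- **Harmonization** aligns every trait to the reference allele pair,
  flipping betas and complementing allele frequencies for swapped (and
  strand-complemented) pairs. Palindromic (A/T, C/G) SNPs carry no strand
  information; they are resolved by allele-frequency concordance when
  both frequencies lie outside [0.42, 0.58] and dropped otherwise
  (conservative default; flagged in output). Finally all traits are
  oriented so the designated exposure beta is non-negative. The
  accounting identity (final = union − clumped − unavailable −
  harmonization drops) is asserted exactly.
- Coordinates are 1-based; joins are by rsid, never position; genome
  build is not validated.

## Synthetic-data generator

`simulate_cohort` draws genotypes G_j ~ Binomial(2, maf_j) in
Hardy–Weinberg equilibrium and LD-free (LD enters only through
`simulate_ld` block fixtures, because the estimator theory assumes
independent instruments), then builds X, M, Y by the linear recursive
DAG with configurable horizontal pleiotropy (none / balanced /
directional with mean μ_α) and an optional shared confounder loading.
`cohort_to_sumstats` estimates per-SNP regressions in pairwise-disjoint
subsamples (the two-sample design); `simulate_sumstats` is the fast path
that draws observed betas directly around the composed truth.

Default parameters are the study-scale conditions: 76 exposure and
88 mediator SNPs; exposure standardised (variance explained by its SNPs
2%), mediator on the log scale (2%), outcome in kg with residual SD 8;
estimation sample sizes 230k / 200k / 170k; effect triple
θ_total = 0.30, θ_dir = 0.50, θ_ind = −0.20 (θ_XM = 0.4, θ_MY = −0.5).
Effect magnitudes are uniform on [0.5, 1.5]×scale — instruments are
genome-wide-significant hits, bounded away from zero — and exposure SNPs
are coded to the exposure-increasing allele, the same convention
harmonization enforces; without that coding, directional pleiotropy has
no well-defined sign and the Egger intercept has nothing to recover.
The truth identity θ_total = θ_dir + θ_XM·θ_MY is stored and asserted
exactly.

What the generator does **not** emulate: realistic LD structure,
population stratification, genotyping error, non-linearity,
exposure–mediator interaction, or selection into the cohort. Passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to those real-data features.

## Pipeline

`run_full_analysis` is a pure function of (input files, config): per
stratum × exposure it assembles instruments, runs IVW/Egger/WME with
leave-one-out, single-SNP forest/funnel tables, Cook's distances
(threshold 4/k by default) and the Benjamini–Hochberg confounder filter
(FDR 0.05, applied jointly over the pooled SNP×confounder family — the
more conservative reading; configurable), re-runs estimators after each
exclusion set, fits MVMR-IVW/Egger and Q-het, and produces both mediation
decompositions. A master seed fans out to per-stage seeds through a
CRC32-keyed SeedSequence (all below 2³¹), so single stages are
independently reproducible and repeated runs are byte-identical. A hard
error in one stratum is recorded as a structured error and other strata
continue.

## Numerical choices and test design

- Monte-Carlo suite sizes: 5,000 replicates for the Q null calibration,
  300 for pipeline parameter recovery, 200 panels × 500 bootstrap
  replicates for Q-het CI coverage, 300–500 for the remaining recovery
  and calibration checks — chosen to keep Monte-Carlo error well below
  the effects being measured.
- Asymptotic-unbiasedness checks (IVW recovery, Egger intercept
  recovery, MVMR-IVW recovery) run at large discovery-GWAS sample sizes
  where the 1/F attenuation is negligible; the weak-instrument contrast
  (Q-het vs MVMR-IVW bias) runs at a low-heritability configuration
  mimicking the weakest instrument set in the motivating study
  (conditional F ≈ 5).
- The weighted median's quantile-shift bias under one-sided contamination
  is O(per-ratio noise); its consistency test checks that the absolute
  bias is small and halves when the noise halves, while IVW retains a
  noise-independent share of the contamination.

## Known limitations

- First-order Wald-ratio SEs (no second-order term), matching the named
  IVW model; weak-instrument attenuation of IVW-family estimators is
  documented above rather than corrected.
- Exactly two simultaneous exposures (exposure + mediator); no
  covariance estimation for overlapping samples.
- The observational indirect-effect CI uses the delta method with
  cross-equation covariance zero; full SEM covariance-aware intervals
  can be narrower.
- No MR-PRESSO, mode-based or SIMEX-corrected estimators; plot data are
  exported as tables, rendering is left to the caller.
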