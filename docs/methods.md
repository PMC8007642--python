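# Methods

## Model and causal structure

All estimators operate on two-sample GWAS summary statistics: per-variant
effects on an exposure (SD units) from one GWAS and on a binary outcome
(log-odds per allele) from an independent GWAS. The working causal diagram
is

```
exposure ──(θ_direct)────────────────► outcome
exposure ──(κ)──► mediator ──(θ_M)──► outcome
```

so the total exposure effect is θ_total = θ_direct + κ·θ_M and the true
mediated proportion is κ·θ_M/θ_total. Univariable MR estimates θ_total;
multivariable MR on the union of exposure and mediator instruments estimates
θ_direct and θ_M jointly; the mediation module decomposes the two either by
difference (total − direct) or by product (κ̂·θ̂_M, "two-step network").

Standard instrumental-variable assumptions apply: instruments are associated
with the exposure, independent of confounders, and affect the outcome only
through the modelled paths. The sensitivity suite (Egger intercept,
weighted median/mode, MR-Robust, MR-PRESSO, leave-one-out) probes exactly
the third assumption.

## Estimator details and numerical choices

- **IVW / Egger.** Weighted least squares on the beta–beta scatter; with an
  LD correlation matrix the fit is GLS with Σ_jk = σ_Yj·σ_Yk·r_jk (a
  singular Σ raises an error advising pruning). Random-effects SEs are
  multiplicative, max(1, √(Q/df)), df = J−1 (IVW) or J−2 (Egger). Egger rows
  are flipped so exposure betas are non-negative; with LD present the sign
  flips are propagated into Σ. 95% intervals use ±1.959964 throughout.
- **Weighted median.** Linear interpolation of the inverse-variance-weighted
  empirical CDF at cumulative weight 0.5; requires pairwise LD r² ≤ 0.2
  (enforced, with the offending pair named). SE from a parametric bootstrap
  (default 10,000 draws, seedable); CIs are normal-approximation with the
  bootstrap SE for comparability across methods.
- **Mode-based.** Normal-kernel density of the Wald ratios with the modified
  Silverman bandwidth 0.9·min(sd, MAD/Φ⁻¹(0.75))·J^(−1/5) scaled by φ
  (default 1.0); the mode is located on a 512-point grid then polished by
  bounded scalar minimisation. Weighted (default) and simple variants are
  both exposed, since analyses rarely state which was used. Zero bandwidth
  (all ratios identical) returns the common ratio.
- **MR-Robust.** Tukey-bisquare (c = 4.685) M-regression of β_Y/σ_Y on
  β_X/σ_Y through the origin via statsmodels RLM (IRLS, tol 1e-10, max 200
  iterations); converged IRLS weights are exposed for outlier inspection.
- **MR-PRESSO.** Observed statistic: Σ w_j (β_Yj − b̂₍₋ⱼ₎β_Xj)² with leave-
  one-out IVW slopes b̂₍₋ⱼ₎ and w = 1/σ_Y². The null distribution simulates
  β_X, β_Y from their sampling normals under the leave-one-out fits; global
  p is the rank-based exceedance with resolution 1/(n_sim+1) (default
  n_sim = 10,000). Per-variant outlier p-values are Bonferroni-adjusted
  across variants (α = 0.05). The distortion test resamples replacement
  variants from the non-flagged set to build a null for the relative change
  between raw and outlier-corrected estimates.
- **Joint outlier rule.** A variant is removed from the main analysis only
  when MR-PRESSO flags it *and* its leave-one-out influence
  |b̂_full − b̂₍₋ⱼ₎| exceeds one fixed-effects SE of the full fit
  (threshold configurable). The fixed-effects SE is used deliberately: the
  random-effects SE is inflated by the very heterogeneity the outlier
  creates, which would mask it.
- **Multivariable MR.** No-intercept weighted regression on the exposure
  beta matrix over the union of per-exposure instruments, union-pruned at
  LD r² > 0.2 keeping the smaller discovery p. Variants missing from any
  table are dropped, never zero-imputed (zero-imputation biases coefficients
  toward the univariable estimate). A condition number above 1e6 raises an
  error naming the most collinear exposure pair — adiposity instrument sets
  can correlate at r ≈ 0.7–0.8, so collinearity is surfaced loudly. An
  exposure column with no variation is excluded from the fit (estimate
  reported as NaN) so the remaining coefficients reduce to the smaller
  model exactly.
- **Mediation.** Proportions are computed on the log-OR scale only.
  Intervals propagate independent normal draws of the inputs (default
  100,000) and take 2.5/97.5 percentiles, truncated to [0, 100]% by default
  (truncation never moves the point estimate). Independence of total and
  direct estimates is an approximation — they share instruments — so the
  interval is indicative rather than exact. Draws with |total| < 1e-8 are
  discarded and counted.
- **Power.** NCP = N·R²·φ(1−φ)·b², power = 1 − Φ(z_{1−α/2} − √NCP) +
  Φ(−z_{1−α/2} − √NCP), two-sided α = 0.05. The detectable effect at a
  target power is found by bisection to 1e-8. The φ(1−φ) factor is the
  binary-outcome variance approximation; the formula is benchmarked against
  a full rejection-rate simulation in the tests rather than against any
  external table.

## Harmonisation conventions

Alignment targets the first exposure's effect allele. Swapped alleles flip
the outcome beta and replace EAF by 1−EAF; strand flips are resolved by
complementing. Palindromic variants (A/T, C/G) are oriented by frequency
concordance when EAF is informative, dropped as "palindromic-ambiguous" when
EAF lies within 0.08 of 0.5 (window configurable), and are an error when
EAF is missing altogether. Missing p-values are recomputed from β/σ under
normality and flagged `p_derived`; supplied p-values inconsistent with β/σ
beyond a factor of two produce a warning, not a failure. How any given
published analysis harmonised its alleles is rarely stated; this truth table
is the dominant community convention, not a reconstruction.

## The synthetic-data generator

Summary statistics are generated directly at the summary level — true
per-variant effects plus normal estimation noise with the analytic GWAS
standard errors 1/√(2·EAF(1−EAF)·N), with an extra φ(1−φ) factor for the
case–control outcome. This is exact for every estimator here and avoids
simulating individual-level genotypes. Per scenario:

- EAF ~ U(0.05, 0.5); exposure instrument effects are scaled so the
  instrument-level R² matches the requested value exactly.
- The mediator receives κ·γ_j on the exposure's instruments **plus its own
  instrument SNPs** (default BMI-shaped: 68 SNPs, R² = 0.0232, N = 322,154).
  Without mediator-specific instruments the multivariable design matrix has
  proportional true columns and the direct effect is unidentified; real
  multivariable analyses likewise include each trait's own hits.
- Pleiotropy: `balanced` adds zero-mean N(0, σ_α) outcome effects;
  `directional` adds sign(γ_j)·N(μ_α, μ_α/2) — directional *in the
  exposure-increasing orientation*, the frame in which the Egger intercept
  is defined (a fixed-sign α would cancel against signed instrument
  effects); `inside_violating` couples α to instrument strength.
- LD blocks induce correlated estimation noise with block correlation r and
  ship as the LD matrix; an overlap fraction correlates exposure and outcome
  noise to emulate shared GWAS participants; a flip fraction mis-orients
  outcome rows to exercise harmonisation. Allele pairs are drawn
  non-complementary so no variant is lost to palindrome ambiguity unless
  that is the behaviour under test.
- All draws come from one seeded generator: identical seeds give
  bit-identical datasets.

`study_scenario` encodes the three physical-activity study designs
(MVPA: 7 SNPs, R² = 0.0007, N = 385,790, total OR 0.56; AMPA: 5 SNPs,
R² = 0.002, N = 91,105, total OR 0.60, 32% mediated through BMI; sedentary
time: 6 SNPs, R² = 0.001, null effect) with the colorectal-cancer outcome
GWAS of 31,197 cases and 61,770 controls. The exposure→mediator path is
fixed at κ = 0.3 SD/SD — a plausible PA→adiposity effect — and θ_M is
solved from the requested mediated proportion; these are declared study
conditions, chosen once, not fitted quantities.

What the generator does **not** emulate: realistic LD panels or MAF spectra,
winner's-curse in instrument discovery, population stratification, or
non-linear exposure–outcome relationships. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to those real-data complications.

## Problem sizes used in the shipped analyses

The acceptance script runs 120 replicates per simulated scenario, 150
replicates for test calibration (MR-PRESSO with 400 simulations each), and
80 replicates for outlier handling; the test suite uses 500 replicates for
study-scale parameter recovery and 200 for calibration. These sizes give
Monte-Carlo SEs a few percent of the quantities reported and keep a full
run in minutes on one core.

## Known limitations

- **Weak-conditional-instrument attenuation in multivariable MR.** At
  realistic instrument strengths (e.g. a 5-SNP exposure instrument with
  R² = 0.002 in N ≈ 91,000 fitted jointly with a 68-SNP mediator
  instrument), measurement error in the exposure beta column — dominated by
  the mediator SNPs, whose true exposure effects are near zero — attenuates
  the exposure's direct effect toward the null by a factor of roughly
  signal/(signal + noise) ≈ 0.7 in that configuration. The difference-method
  mediated proportion is correspondingly overstated, and the product-method
  proportion is mildly inflated by ratio noise (Jensen's inequality). The
  estimator is consistent: recovery is exact in the strong-instrument limit
  (verified by simulation at large N in the test suite). Interpret
  study-scale direct effects and mediated proportions as lower/upper bounds
  respectively, and check conditional instrument strength before leaning on
  them.
- Bootstrap and Monte-Carlo intervals assume approximate normality of the
  component estimates; with very few instruments (J ≤ 3) they are rough.
- MR-PRESSO's per-variant test loses power when a single variant carries a
  dominant share (≳50%) of the IVW weight, because its own contamination of
  the remaining leave-one-out fits widens the simulated null.
- The LD-aware path covers IVW and Egger (GLS); median- and mode-based
  methods require pruned, near-independent instruments by construction.
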