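# Methods

This note records the statistical model, the conventions the
implementation commits to where more than one is defensible, and what
the synthetic-data experiments do and do not demonstrate.

## Two-sample MR model

The data are per-SNP summary statistics from two non-overlapping GWAS:
exposure effects β̂_Xj ~ N(γ_j, σ²_Xj) and outcome effects
β̂_Yj ~ N(θγ_j + α_j, σ²_Yj), where θ is the causal effect of the
exposure on the outcome (SD per SD), γ_j the true SNP–exposure effect
and α_j a direct (pleiotropic) SNP–outcome effect. The instrument
assumptions are: association with the exposure (checked via
F_j = β̂²_Xj/σ²_Xj with F > 10 acceptable), no direct outcome effect
(α_j = 0), and no confounding of the instrument–outcome relation.
Estimators differ in which violations they tolerate:

- **Wald ratio** θ̂_j = β̂_Yj/β̂_Xj with SE σ_Yj/|β̂_Xj| (first-order
  delta method; the exposure-noise term θ²σ²_Xj/β̂²_Xj is omitted, which
  is the convention that makes IVW algebraically identical to weighted
  least squares of β̂_Y on β̂_X through the origin with weights 1/σ²_Yj;
  for the small θ of interest it is also numerically negligible).
- **IVW**: inverse-variance-weighted mean of the θ̂_j. Fixed-effect
  SE = (Σw_j)^{-1/2}; multiplicative random effects multiply this by
  max(1, √(Q/(J−1))) with Q = Σw_j(θ̂_j − θ̂)². The floor at 1 makes
  fixed and random estimates (point and SE) coincide exactly when there
  is no excess heterogeneity, which is the behaviour one observes on
  low-I² panels. Diagnostics: Q, its χ²(J−1) p-value,
  I² = max(0, (Q−(J−1))/Q).
- **Weighted median**: sorted ratio estimates with normalised weights
  w′_j; each sits at cumulative midpoint rank p_j = S_j − w′_j/2 and the
  estimate interpolates linearly at p = 0.5 (clamped to the extreme
  estimate when 0.5 falls outside [p_1, p_J]). The SE is a parametric
  bootstrap: resample β̂_X, β̂_Y from their normals, recompute weights
  and median, take the SD over n_boot (default 1000) replicates. The
  seed is a mandatory argument, so results are reproducible by
  construction.
- **MR-Egger**: every pair is first oriented so β̂_Xj ≥ 0 (flipping both
  betas), then β̂_Y is regressed on β̂_X with weights 1/σ²_Yj and a free
  intercept. Slope = causal effect under InSIDE; intercept = weighted
  mean directional pleiotropy. SEs use residual dispersion
  max(1, RSS_w/(J−2)) (same multiplicative convention as IVW) and
  inference is on t with J − 2 df; Wald/IVW/median use normal quantiles.
  The NOME diagnostic I²_GX applies the Q formula to |β̂_Xj| with
  weights 1/σ²_Xj; values below 0.90 flag MR-Egger as unreliable.

### MR-PRESSO

The global statistic is RSS = Σ_j w_j(β̂_Yj − θ̂_{−j}β̂_Xj)² with
w_j = 1/σ²_Yj and θ̂_{−j} the leave-one-out IVW slope. Its null
distribution is simulated parametrically (β*_X ~ N(β̂_X, σ_X),
β*_Y ~ N(θ̂_{−j}β̂_X, σ_Y), RSS recomputed identically); empirical
p-values carry the +1 correction, so the smallest attainable p is
1/(n_sim+1). Per-SNP outlier tests compare each SNP's weighted squared
residual with its own simulated distribution, Bonferroni-adjusted over
J, at α = 0.05. The distortion test is defined here (the upstream
procedure's internals are not fully specified) as: bootstrap the
non-outlier SNPs with replacement, recompute the fixed-effect IVW
estimate θ_b, and report the +1-corrected fraction of
|θ_b − θ_raw| ≥ |θ_corrected − θ_raw| as a two-sided empirical p.
Defaults: n_sim = 1000 (exposed; the analyses here use 500 when many
replicates are needed), 1000 distortion bootstraps.

### Selection and harmonization conventions

- Greedy clumping ties (equal p) break by genomic position then rsid, so
  selection is deterministic and input-order-invariant; published
  clumping tools do not document their tie rule, and determinism is the
  requirement here.
- A lead SNP's block interval is the [min, max] position over its block
  members; blocks closer than 250 kb (transitively) share a locus.
- SNP pairs absent from the LD matrix are treated as r² = 0 with a
  warning, mirroring reference-panel sparsity; a SNP wholly absent when
  it must be looked up is an error.
- Outcome records orient to the minor allele (EAF ≤ 0.5); exposure
  records align to the outcome allele by label, complementing for strand
  mismatches, and never by exposure frequency. Palindromic (A/T, C/G)
  pairs cannot be strand-resolved by labels and fall back to frequency
  concordance; they are always flagged, and rejected when either EAF is
  within ±0.08 of 0.5 (configurable) or missing.
- Proxy substitution requires exposure p < 5×10⁻⁶ and r² ≥ 0.6 with the
  lead, maximising r² with ties broken by smaller p then position.
- Instrument sets selected under the lenient-independence preset
  (r² < 0.3) contain correlated SNPs; IVW still treats them as
  independent (no generalised-IVW correlation correction is
  implemented), and the pipeline logs a warning whenever the supplied
  LD shows pairwise r² > 0.05 among instruments.

### Allometric indices

index = Z · Weight^{p_w} · Height^{p_h}, with Z = waist/hip (WHI),
waist (ABSI) or hip (HI). Exponents are calibrated by OLS of log Z on
log weight and log height; the negated coefficients give exact
in-sample orthogonality to both size variables, which is the defining
property of these indices (the published UK Biobank exponent values are
not reproduced here; callers supply or calibrate their own, per stratum
when sex-specific indices are wanted). GWAS-scale traits use the Blom
rank inverse-normal transform Φ⁻¹((r − 3/8)/(n + 1/4)) with average
ranks for ties.

## Synthetic-data generator

Per SNP: MAF ~ U(0.05, 0.5); γ_j = random sign × |N(γ̄, s_γ)| (effects
live on the minor allele, whose direction is arbitrary); standard
errors follow the SD-trait approximation σ = (2n·MAF(1−MAF))^{-1/2};
observed effects are drawn from the model above. The exposure panel is
sex-combined (default n = 25,314, matching the scale of the cortisol
meta-analysis) and outcome panels are sex-specific (defaults 219,872
women / 186,825 men, the body-shape GWAS sizes), so the pipeline's
sex-handling is exercised. Default γ̄ = 0.065, s_γ = 0.015 put the
per-SNP F statistics in the 15–85 range spanned by the published
instruments. Allele labels and strand are randomly re-encoded per
panel; the truth object stores the observed effects on the coded
(minor) allele, making harmonization checkable to machine precision.

Pleiotropy regimes: `none`; `balanced` α ~ N(0, 0.0015); `directional`
α = sign(γ)·N(0.003, 0.0015) — planted on the exposure-increasing
allele, because a mean direct effect is only identifiable relative to
that orientation (MR-Egger's own convention); `inside_violating`
couples α to |γ|. Gross outliers add `outlier_scale` (default 10) times
the outcome SE to α, on a random SNP or on the lowest-weight SNP
(`low_weight`).

Scenario presets and their rationale:

- `null_no_pleiotropy`, `balanced`: calibration and recovery baselines
  at θ = 0 and θ = 0.05.
- `directional_inside_ok` / `inside_violating` use a better-powered
  exposure panel (n = 100,000) and wider γ spread (0.08 ± 0.03) than the
  cortisol-scale default. This is deliberate: with σ_X comparable to
  s_γ, NOME fails (I²_GX ≈ 0.6) and regression dilution biases the
  Egger intercept by more than its Monte-Carlo error, so intercept
  recovery is only a meaningful check in a NOME-valid regime. The
  cortisol-scale setting is exactly the regime in which the NOME flag
  fires — which the diagnostics, not the recovery tests, cover.
- `one_outlier_no_distortion` plants the 10-SE outlier on the
  lowest-weight instrument and widens s_γ to 0.025. A 10-SE outlier
  shifts the pooled IVW estimate by ≈ 10·√(weight share) standard
  errors, so on an equal-weight ten-SNP panel it would always distort
  (~3 SE); only a low-weight outlier reproduces the empirically
  observed joint pattern of a flagged outlier with a quiet distortion
  test.
- `weak_instruments`: γ = |N(0.01, 0.004)| keeps the per-SNP
  noncentrality ≲ 1.1, so F < 10 on >95% of SNPs.

What passing on synthetic data does **not** show: the generator draws
effect estimates independently across SNPs (LD enters only the clumping
structure, not the sampling covariance), assumes no sample overlap, no
stratification, equal allele frequencies in both samples, and normal
estimation error. Real summary statistics violate several of these,
so recovery results transfer only to the extent those assumptions are
tolerable.

## Numerical and replication choices

- Empirical p-values are never zero (+1 correction); normal/t p-values
  are floored at the smallest positive double.
- Egger's normal equations are solved directly (2×2); no iteration, no
  initialisation concerns. Degenerate inputs (β_X = 0 for a Wald ratio,
  all-equal samples for the Blom transform, constant covariates in
  calibration) raise typed errors rather than returning NaN.
- Pipeline seeds: one integer seeds the run; per-outcome,
  per-component child seeds derive via `numpy.random.SeedSequence`, so
  adding an outcome does not shift another outcome's results.
- Replicate sizes in the test-suite experiments: 500 replicates for IVW
  recovery/coverage and for the MR-PRESSO calibration and power runs
  (n_sim = 500 inside each), 2000 for the Egger-intercept mean — the
  intercept is heavy-tailed at J = 10, and 500 replicates leave its
  Monte-Carlo error too large for a stable 3σ check; 1000 panels for
  estimator-oracle equivalence; 1000 re-encoded pairs for
  harmonization; 200 LD panels for the clumping oracle.
- The null-calibration check of the pipeline (published instrument
  table as exposure, outcomes simulated at θ = 0) uses fixed-effect IVW
  p-values: the multiplicative random-effects SE is floored and hence
  conservative by construction, so only the fixed-effect p is exactly
  uniform under the null.

## Known limitations

- No correlated-instrument (generalised) IVW; the r² < 0.3 preset is
  analysed as if independent, with a logged warning.
- No multivariable MR.
- The CADD column is pass-through annotation; no positional gene
  mapping or functional annotation is performed.
- Palindromic-SNP frequency rescue assumes comparable allele
  frequencies between the two samples' populations.
- The distortion test's bootstrap null is this package's own
  operationalisation; other MR-PRESSO implementations may differ in
  detail.
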