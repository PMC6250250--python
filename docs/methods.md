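# Methods

## Model

`mrpipe` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. For SNP *j*, let β̂_Xj (SE σ_Xj) be its association
with a standardized continuous exposure (SD units) and β̂_Yj (SE σ_Yj)
its association with a binary outcome (log odds ratio), estimated in
non-overlapping samples. Under the instrumental-variable assumptions
(relevance, independence from confounders, no direct effect on the
outcome), each SNP identifies the causal effect θ through the Wald ratio

    θ̂_j = β̂_Yj / β̂_Xj .

Delta-method standard errors are available at two orders:
first, σ_Yj/|β̂_Xj|, and second (the default),
sqrt(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴), which also propagates the
exposure-side uncertainty. Per-SNP weights are w_j = se(θ̂_j)⁻².

Instrument strength is summarized per SNP by F = R²(n−2)/(1−R²), with R²
the exposure variance explained (computed as 2p(1−p)β̂_Xj² for a
standardized trait when the effect-allele frequency p is available) and
F ≤ 10 flagged as a weak instrument.

## Estimators

* **Fixed-effect IVW**: θ̂ = Σw_jθ̂_j / Σw_j, SE = (Σw_j)^−1/2, normal
  reference. Consistent when all instruments are valid.
* **MR-Egger**: SNPs are oriented so β̂_Xj > 0, then β̂_Yj is regressed on
  β̂_Xj with a free intercept and weights w_j/β̂_Xj² (equal to 1/σ_Yj²
  for first-order weights, 1/(σ_Yj²+θ̂_j²σ_Xj²) for second-order). The
  slope is the pleiotropy-adjusted causal estimate; the intercept
  estimates average directional pleiotropy and its two-sided test uses a
  t reference with J−2 df. SEs carry a multiplicative overdispersion
  factor max(1, sqrt(Q′/(J−2))). With these weights the intercept-free
  fit reproduces IVW exactly, which makes the Rucker decomposition below
  internally consistent; whether to use t or normal quantiles for the CI
  is not settled in the applied literature, so the reference used is
  recorded in the output metadata.
* **Weighted median**: order statistics θ̂_(1) ≤ … ≤ θ̂_(J) receive
  standardized cumulative weights p_j = (S_j − w_j/2)/S_J; the estimate
  linearly interpolates θ̂ at p = 0.5. Consistent when valid instruments
  carry >50% of total weight. The SE is the standard deviation of the
  estimator across parametric-bootstrap replicates in which each θ̂_j is
  redrawn from N(θ̂_j, se_j).
* **Weighted mode**: argmax over a 512-point grid of the weighted
  normal-kernel density of {θ̂_j}, bandwidth
  h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) (φ = 1 by default). Degenerate
  spread returns the common value. SE by the same bootstrap as the
  weighted median.

Bootstrap SEs default to 1000 replicates and are exactly reproducible
given (seed, n_boot). All pooled estimates are reported on both the
log-OR and OR scales; the OR fields are exact exponentials of the log
fields.

## Pleiotropy diagnostics

* **Cochran's Q / I²_MR** on the ratio estimates at the IVW fit;
  I² = max(0, (Q−df)/Q)·100. The excess-heterogeneity flag requires both
  I²_MR > 25% and Q-test p < 0.05.
* **Rucker model selection**: Q′ is the weighted residual sum of the
  Egger fit (same weights as Q, so Q′ ≤ Q); Q − Q′ is referred to χ²₁ to
  decide whether Egger fits significantly better than IVW.
* **I²_GX** on the oriented exposure effects with weights σ_Xj⁻²
  quantifies NOME violation (regression dilution of the Egger slope);
  I²_GX > 95% is flagged low-risk.
* **MR-PRESSO**: observed statistic RSS = Σ_j w̃_j(β̂_Yj − θ̂_(−j)β̂_Xj)²
  with leave-one-out IVW slopes θ̂_(−j) and beta-space weights w̃_j. Its
  null distribution is simulated (default 1000 draws) by redrawing
  β_Xj* ~ N(β̂_Xj, σ_Xj) and β_Yj* ~ N(θ̂_(−j)β̂_Xj, σ_Yj). Empirical
  p-values use the add-one rule, so the smallest attainable p is
  1/(n_sim+1). Per-SNP outlier p-values are Bonferroni-multiplied by J;
  detected outliers trigger an outlier-corrected IVW estimate and a
  distortion test comparing the observed relative shift of the estimate
  with shifts from removing random subsets of the same size (two-sided
  empirical p). Flagging every SNP violates the method's majority-valid
  assumption and raises an error.
* **Funnel and radial tables** expose (θ̂_j, 1/se_j) and
  (√w_j, θ̂_j√w_j); the radial through-origin slope equals IVW.

## Study orchestration

`run_study` takes one exposure table, any number of outcome tables with a
tier (`primary`/`secondary`), and an optional plain-text rsID exclusion
list (e.g. SNPs with known secondary GWAS associations). Per outcome it
harmonizes alleles, computes F statistics, runs the seven-method battery
(IVW; IVW after exclusions; Egger; PRESSO raw; PRESSO outlier-corrected,
skipped with a recorded reason when no outliers are found; weighted
median; weighted mode) plus all diagnostics, and applies the tier's
significance threshold: 0.025 for primary outcomes (Bonferroni over two
primary hypotheses), 0.05 for secondary and sensitivity analyses, which
are deliberately not further multiplicity-corrected. Dropped SNPs,
flipped alleles, exclusions and seeds are logged to a run manifest and
reports are deterministic given the config.

Harmonization aligns on rsID only: swapped alleles flip the outcome beta
(and complement the frequency), strand-complement pairs are complemented
first, irreconcilable pairs are dropped and counted. Palindromic A/T and
C/G SNPs default to frequency-based orientation with SNPs whose
effect-allele frequency falls in [0.42, 0.58] on either side dropped as
ambiguous; `drop` and `keep` policies are available. Duplicate rsIDs
within a file keep the row with the smallest p-value. Indel alleles are
rejected — the intended instrument panels are SNPs.

## Synthetic data generator

The generator emulates a strong hematological-trait panel studied against
binary cardiovascular outcomes, with defaults: J = 219 candidate SNPs,
exposure GWAS n = 166,066, outcome GWAS 60,341 cases / 454,450 controls,
θ = 0.07 log-OR per SD, MAF ~ U(0.01, 0.5), h² explained by the panel
0.15, genome-wide selection threshold 5×10⁻⁸.

Per SNP: σ_Xj = (2p_j(1−p_j)n_X)^−1/2,
σ_Yj = ((1/n_cases + 1/n_controls)/(2p_j(1−p_j)))^1/2 (the standard
binary-trait approximation). True effects b_j are half-normal (panels are
reported on the exposure-increasing allele, so directional pleiotropy is
directional in ratio space too) and rescaled so Σ2p(1−p)b² = h².
Pleiotropy: with probability π a SNP receives a direct outcome effect
α_j ~ N(μ_α, σ_α); `inside_violation` scales μ with b_j to break InSIDE;
planted outliers add `outlier_offset`×σ_Yj (default 10) and are drawn
from the retained panel. Selection is applied to an *independent*
discovery replicate of β̂_X, so retained SNPs' observed exposure effects
are free of winner's curse — the two-sample setting the pipeline assumes.
Under the defaults ~55–65% of candidates are retained (~130 SNPs) and
realized F statistics lie predominantly in [30, 2000], the order of
magnitude of a strong published panel; h² = 0.15 was chosen to place the
mean F near 150–200 so that this envelope holds at n = 166,066.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent), population stratification or sample overlap, binary-trait
non-collapsibility (outcome effects are generated linearly on the log-OR
scale), allele-frequency differences between studies, and missingness.
Passing tests therefore show correct estimator behaviour under the
idealized two-sample model, not robustness to those data pathologies.

`make_synthetic_study` writes a six-outcome study (two primary, four
secondary outcomes with case/control sizes and generating ORs from the
published cardiovascular consortia: CAD 1.01, ischemic stroke 1.07, MI
1.03, cardioembolic 1.12, large-artery 1.09, small-vessel 1.08 per SD),
sharing one exposure draw across outcomes, plus a 39-SNP exclusion list
sampled from the panel as a stand-in for a pleiotropy-database lookup.

## Simulation scenarios and their sizes

* Clean recovery: 500 default panels; IVW mean bias and 95% CI coverage.
* Null calibration: 500 panels (J = 50, θ = 0.1, no pleiotropy); Egger
  intercept and PRESSO global rejection rates at α = 0.05.
* Directional pleiotropy: π = 0.3, μ_α = 0.03, σ_α = 0.005 log-OR,
  200 panels. μ_α was fixed by a power analysis: the Egger intercept's
  power is *maximized* near μ_α ≈ 0.03 and declines for larger values
  because the invalid/valid mixture contributes residual variance
  ∝ π(1−π)μ_α², inflating the overdispersion-scaled SE; at the chosen
  value intercept power ≈ 0.55 and the weighted median beats IVW in
  essentially every replicate.
* Outlier detection: J = 50, one planted outlier at 10×σ_Y, 200 panels,
  1000 PRESSO simulations each.

These sizes keep each experiment at seconds on one CPU while leaving
binomial Monte-Carlo error well inside the asserted bands.

## Numerical choices and edge cases

Normal 97.5% quantile used exactly (1.959964…), not 1.96. Weighted-median
interpolation clamps at the extreme order statistics. Ties in cumulative
weights are handled by linear interpolation. β̂_X = 0 raises a named
error rather than propagating infinities. Empirical p-values never return
0 (add-one rule). The mode grid spans [min θ̂ − 3h, max θ̂ + 3h].
Egger requires spread in β̂_X (singular design otherwise). All estimators
are invariant to flipping the reported allele of any SNP subset, and
bootstrap/simulation outputs are bit-reproducible given seeds.

## Known limitations

No LD clumping, proxy lookup or liftover; matching is rsID-only.
No multivariable MR (inappropriate for highly overlapping hematological
traits), no random-effects IVW, no SIMEX correction of the Egger slope,
no Steiger filtering. The PRESSO distortion test uses the random-subset
formulation described above, which may differ in detail from other
implementations. The Egger CI's t-reference choice is a convention, not a
derivation; first-order weights are available by flag and recorded in the
output when used.
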