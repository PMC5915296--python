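# Methods

`ivmr` implements two-sample summary-data Mendelian randomization (MR) for a
continuous, log-measured exposure against a binary outcome, in the setting of
a liver-enzyme (GGT) exposure GWAS and a case-control Alzheimer's disease
outcome GWAS. This note records the statistical model, the defaults and why
they were chosen, and what the synthetic benchmark does and does not show.

## Model and estimators

For instrument j, let β_Xj (SE σ_Xj) be the per-allele association with the
exposure in natural-log units, and β_Yj (SE σ_Yj) the per-allele association
with the outcome in log-odds, both aligned to the same effect allele. Under
the instrumental-variable assumptions each instrument identifies the causal
log-odds ratio per log-unit of exposure via the Wald ratio
θ̂_j = β_Yj / β_Xj, with first-order SE σ_Yj / |β_Xj| (the sampling error in
β_Xj is ignored at this order; the I²_GX diagnostic quantifies how much that
costs).

* **IVW** pools the ratios with weights w_j = (β_Xj/σ_Yj)²:
  θ̂ = Σ w_j θ̂_j / Σ w_j, equivalently weighted least squares of β_Yj on β_Xj
  through the origin with weights σ_Yj⁻². The fixed-effect SE is
  (Σ β_Xj² σ_Yj⁻²)^(−1/2). The default report uses **multiplicative
  random effects**: the fixed SE times max(1, √(Q/(L−1))), with Q the Cochran
  heterogeneity statistic of the ratios. This factor never shrinks the CI; it
  widens it exactly when the instruments disagree more than sampling error
  allows, which is the common convention for instrument counts in the tens.
  Both variants are available.
* **MR-Egger** refits the same weighted regression with a free intercept after
  orienting every instrument so β_Xj > 0. The slope is a pleiotropy-adjusted
  causal estimate (valid under InSIDE — direct effects independent of
  instrument strength); the intercept estimates the average direct effect of
  an instrument on the outcome and is the directional-pleiotropy test.
  Inference uses t with L−2 degrees of freedom and the same multiplicative
  overdispersion floor max(1, RSS_w/(L−2)); small-sample t calibration is the
  standard choice for this regression. The intercept is reported per
  instrument on the log-odds scale and is **not** rescaled per SD of exposure
  (it is not an exposure-scale quantity).
* **Weighted median**: ratio estimates are sorted, weights w_j normalized,
  and the estimate is the linear interpolation of θ̂ against the cumulative
  weight midpoint s_j = Σ_{k≤j} w_k − w_j/2 at s = 0.5. It is consistent
  whenever valid instruments carry more than half the weight. The SE is a
  parametric bootstrap (resampling β_Xj, β_Yj from normals at their observed
  values and SEs), default 1000 replicates; a seed is mandatory so no run
  depends on the clock.

All causal estimates are multiplied by `sd_scale`, the exposure SD in log
units, to express effects per SD of exposure; 0.65 log-units is the value for
serum GGT, equivalent to a 92% increase on the raw scale
((e^0.65 − 1) × 100 ≈ 91.6). P-values are never touched by rescaling.

## Harmonization

Instruments are matched by rsid (intersection, exposure order). Outcome
alleles must match or reverse the exposure pair, directly or after strand
complementing; a reversal negates β_Yj. Palindromic pairs (A/T, G/C) are
retained and flagged by default — the emulated instrument list was curated
upstream, so silently dropping them would change L; `drop` and `keep` are
available. Percent-change exposure effects are converted to log units by
β → ln(1 + β/100) with the delta-method SE σ → σ/(100 + β). Odds ratios are
log-transformed at read time, with the reported SE taken as the SE of the
log-OR (the GWAS convention). Duplicate rsids in one table are an error, not
a silent deduplication.

## Diagnostics

Per-instrument strength is F_j = (β_Xj/σ_Xj)²; variance explained uses
2·eaf·(1−eaf)·β_Xj² / var(X) when the effect-allele frequency is known and
the F-based form F/(n−2+F) otherwise (the two agree up to a factor of order
the per-SNP R² itself). I²_GX is an I² over the oriented exposure effects
with weights σ_Xj⁻²: near 1, the NO-Measurement-Error assumption behind
MR-Egger is nearly satisfied and its regression-dilution bias is minimal.
Funnel data pair each θ̂_j with its precision (reciprocal SE; an
instrument-strength y-axis is available, since published funnel plots use
both conventions). The per-SNP outcome screen reports raw and
Bonferroni-adjusted (α/L) significance.

## Power

The binary-outcome power calculation uses the non-centrality approximation:
with case fraction K and true odds ratio OR per SD, the attenuated effect is
b = K(OR/(1 + K(OR−1)) − 1), the variance term v = K(1−K) − b², and
NCP = N·R²·b²/v with N the outcome sample size and R² the exposure variance
explained by the instruments; power = Φ(√NCP − z_{1−α/2}). An optional
`adjust_r2` flag divides the NCP by (1−R²) — a refinement some calculators
apply — and is off by default (immaterial at R² ≈ 0.02). At the benchmark
composition (N = 54,162, K = 0.314, R² = 0.019, OR = 1.20, α = 0.05) the
formula gives 80.3% power, i.e. roughly the 80–82% range quoted for designs
of this shape; small differences between published calculators trace to
exactly such variant choices. The formula's validity requires v > 0; the
minimum-detectable-OR search brackets inside that region and reports
unattainable targets.

## Synthetic benchmark

The generator draws summary statistics directly from their asymptotic
sampling distributions — the objects two-sample MR consumes — rather than
simulating genotypes; every replicate is sub-millisecond, so the Monte-Carlo
tests run thousands of replicates in seconds.

Defaults mirror the benchmark design: L = 26 instruments, exposure GWAS of
n = 61,089, outcome study of 54,162 with case fraction 0.314, total variance
explained R² = 0.019 (the rescaling to the target is exact by construction).
Minor-allele frequencies are uniform on [0.10, 0.45]. Per-variant variance
contributions are lognormal(0, 0.3) with **one dominant locus at 16×** — the
profile of curated liver-enzyme instrument panels, where a single primary
locus dwarfs the rest. Under the benchmark preset this yields mean F ≈ 46
with a long right tail and a median I²_GX of ≈ 0.92, the regime of strong,
well-measured instrument panels. Effects are oriented positive (the effect
allele is the exposure-increasing allele, the reporting convention for
curated lists) with magnitude inverse to allele frequency; the orientation
matters because directional pleiotropy only biases ratio estimates coherently
when instrument orientation is informative.

Pleiotropy: a configurable fraction of instruments receives a direct outcome
effect α_j ~ N(μ_α, τ²), drawn independently of instrument strength (InSIDE
holds by construction). `balanced` forces μ_α = 0; `directional` requires
μ_α ≠ 0. The directional preset used in the robustness tests (μ_α = 0.05 on
30% of instruments) implies an average direct effect — hence an expected
Egger intercept — of 0.015 on the log-odds scale, a realistic magnitude for
a panel whose pleiotropy test sits near the significance boundary.

What the generator does **not** emulate: linkage disequilibrium between
instruments (the emulated panel is independent by construction), winner's
curse in the exposure effect estimates, sample overlap between the two
studies, population stratification, and case-control ascertainment effects
beyond the K(1−K) variance scaling. Passing Monte-Carlo tests therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to those real-data complications.

## Numerical and testing choices

* Monte-Carlo scales: 500 replicates for parameter-recovery checks (null and
  θ = 0.133, the per-log-unit effect whose per-SD version is 0.133 × 0.65 ≈
  0.086), 300 for the pleiotropy-robustness orderings, bootstrap 200 inside
  grids. These sizes put the Monte-Carlo SE of a mean IVW estimate near
  0.003, an order of magnitude below the biases the robustness scenarios
  induce.
* Coverage calibration is asserted on the fixed-effect IVW interval, which is
  the correctly-specified one under a homogeneous generative model; the
  random-effects interval is conservative by construction (its multiplier is
  floored at 1) and is asserted to be never narrower.
* Scenario-grid replicate r of a config with seed s uses seed
  (s·100003 + r) mod 2³¹, making grids reproducible and non-overlapping
  across replicates.
* Weighted-median ties and exact cumulative-weight hits resolve by linear
  interpolation (`numpy.interp`), which clamps at the extreme ratios when
  0.5 falls outside [s_1, s_L].
* Degenerate inputs raise typed errors naming the offending instrument: zero
  exposure effect (undefined ratio), fewer than 3 instruments for Egger or
  the weighted median, identical exposure effects (collinear Egger fit),
  empty harmonized intersection.

## Limitations

The Egger intercept's scale is per instrument per unit weight and is not
comparable across panels with different allele codings. The first-order Wald
SE understates uncertainty when instruments are weak (mean F near 10 or
below); the package reports F and I²_GX so users can judge. No leave-one-out,
outlier-removal, or mode-based estimators are provided, and the headline
analyses of any particular published study are reproducible only with that
study's instrument-level summary statistics.
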