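# ivmr — two-sample summary-data Mendelian randomization

`ivmr` estimates the causal effect of a continuous exposure on a binary
disease outcome from published GWAS summary statistics, using genetic
variants as instrumental variables. It was built for the canonical
liver-enzyme setting — serum gamma-glutamyltransferase (GGT), measured on the
natural-log scale, as the exposure and Alzheimer's disease case-control
status as the outcome — but every component is generic: any pair of
summary-association tables with alleles, effects, and standard errors will
do.

It is aimed at epidemiologists and statistical geneticists who have two
summary tables (one per trait) and want the standard MR workflow without
individual-level data:

* **Harmonization** — match variants across tables, align both effects to one
  effect allele (flipping signs across reversed or strand-complemented
  alleles), and flag or drop palindromic A/T and G/C variants.
* **Unit handling** — percent-change effects to log units
  (β → ln(1 + β/100)), odds ratios to log-odds, and per-log-unit estimates to
  per-SD of exposure (for log-GGT, 1 SD = 0.65 log units ≈ a 92% increase).
* **Estimation** — per-SNP Wald ratios θ̂_j = β_Yj/β_Xj; the inverse-variance
  weighted (IVW) estimate θ̂ = Σ β_Xj β_Yj σ_Yj⁻² / Σ β_Xj² σ_Yj⁻² with
  fixed- or multiplicative random-effects SEs; MR-Egger regression (slope =
  pleiotropy-adjusted effect, intercept = directional-pleiotropy test, t
  inference with L−2 df); and the bootstrap-SE weighted median, consistent
  when valid instruments hold >50% of the weight.
* **Diagnostics** — per-SNP F = (β_Xj/σ_Xj)² and variance explained,
  Cochran's Q, the I²_GX measurement-error statistic for MR-Egger, a
  Bonferroni outcome screen, and funnel/forest plot data exports.
* **Power** — the binary-outcome non-centrality approximation
  (NCP = N·R²·b²/v with b the attenuated effect) and its inverse, the
  minimum detectable OR.
* **Simulation** — a generator of synthetic exposure/outcome summary tables
  with known ground truth (configurable causal effect, pleiotropy mode,
  instrument count and strength profile), plus a scenario grid reporting
  bias, coverage and rejection rates per estimator.

## Worked example

Simulate a 26-instrument benchmark dataset with a true causal effect of
θ = 0.133 log-odds per SD (OR ≈ 1.14), then run the full pipeline:

```sh
ivmr simulate --config scenario.yaml --out-dir data/
ivmr run --exposure data/exposure.tsv --outcome data/outcome.tsv \
    --exposure-scale log-units --outcome-scale log-odds \
    --sd-scale 1.0 --seed 7 --out results/
```

where `scenario.yaml` holds the generative design:

```yaml
l: 26
n_exp: 61089
n_out: 54162
case_fraction: 0.31402
theta: 0.133
pleiotropy_mode: none
seed: 42
```

The run prints (stderr), for one such simulated dataset:

```
ivw-random: OR 1.06 (0.93 to 1.21), p = 0.359
egger: OR 1.15 (0.85 to 1.55), p = 0.363
weighted-median: OR 1.12 (0.93 to 1.35), p = 0.237
report written to results/report.json
```

Each line is an odds ratio per 1 SD of exposure with its 95% CI: all three
estimators bracket the simulated truth (OR 1.14), the Egger CI is widest (it
spends information on the intercept), and none would claim significance at
this sample size — the expected behaviour for a modest effect with 1.9% of
exposure variance explained. `results/` also contains the harmonized
instrument table and funnel/forest data, and `ivmr diagnose` on the
harmonized table prints e.g. `mean F = 45.6, I2_GX = 89.7%` (strong,
well-measured instruments).

The power calculator reproduces design-stage numbers directly:

```sh
$ ivmr power --cases 17008 --controls 37154 --r2 0.019 --odds-ratio 1.20
{ ... "ncp": 7.91, "power": 0.8030 ... }
```

i.e. ~80% power to detect an OR of 1.20 per SD with this outcome study and
instrument panel.

Everything the CLI does is available as a library
(`ivmr.summary_data`, `ivmr.estimators`, `ivmr.diagnostics`, `ivmr.power`,
`ivmr.synthetic`, `ivmr.report`).

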