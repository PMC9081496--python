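# mrmediation

Two-step, two-sample Mendelian randomization (MR) mediation analysis from
GWAS summary statistics.

The package is for epidemiologists and statistical geneticists who want to
ask not only *does an exposure causally affect a disease outcome* but *how
much of that effect runs through specific intermediate risk factors* —
using nothing but published per-SNP association tables (beta, SE, p-value
per variant) from non-overlapping GWAS samples. The motivating use case is
decomposing the protective effect of later age at menarche on myocardial
infarction into contributions mediated by smoking, glycemic traits, blood
pressure and lipids, but every component is trait-agnostic.

## The model

Genetic variants serve as instrumental variables. For SNP *k* let
(X_k, σX_k) be its effect on the exposure and (Y_k, σY_k) its effect on the
outcome (log-odds for a binary outcome). Under the standard IV assumptions
the per-SNP causal (Wald) ratio is Y_k/X_k with first-order delta-method
SE σY_k/|X_k|, and the fixed-effects inverse-variance-weighted (IVW)
estimator pools them:

```
β̂_IVW = Σ_k X_k Y_k σY_k⁻²  /  Σ_k X_k² σY_k⁻²
se(β̂_IVW) = ( Σ_k X_k² σY_k⁻² )^(-1/2)
```

Mediation is decomposed in two steps. Step 1 estimates the
exposure→mediator effect `a_i` by the same IVW formula with mediator
effects Z_k in place of Y_k. Step 2 estimates the mediator→outcome effect
`b_i` adjusted for the exposure by regression-based multivariable MR: a
weighted regression of Y_k on (X_k, Z_k) jointly without intercept. The
indirect effect through mediator *i* is the product a_i·b_i, and its
mediation proportion is `100 · a_i·b_i / β̂_IVW` percent; the combined
proportion is the sum over mediators passing the two p < 0.05 screens.

The sensitivity battery covers MR-Egger (slope + intercept test for
directional pleiotropy, t inference with K−2 df), simple and weighted
median (robust to <50% invalid weight, bootstrap SEs), MR-RAPS (profile
score robust to weak instruments), MR-PRESSO (simulation-based global
heterogeneity test and outlier removal), leave-one-out and single-SNP
analyses.

Because real consortium GWAS inputs are multi-gigabyte downloads, the
package ships a synthetic summary-statistics generator with known causal
structure (true direct effect, mediator paths, optional pleiotropy, LD
blocks, noise scaling with GWAS sample size) so the entire pipeline is
testable at desk scale.

## Worked example

Simulate a benchmark study whose four mediators truly carry 14/12/10/9% of
a −0.1 total effect, then run the full two-step analysis:

```sh
mrmediation simulate --seed 42 --out demo/study --benchmark
mrmediation mr --exposure demo/study/exposure.tsv \
               --outcome demo/study/outcome.tsv \
               --ld demo/study/ld.tsv --seed 42 --out demo/mr_out
```

```
ivw                beta=-0.0914 se=0.0065 OR=0.913 [0.901, 0.924] p=2.32e-45 nSNP=50
egger              beta=-0.0617 se=0.0251 OR=0.940 [0.894, 0.989] p=0.0174 nSNP=50
egger_intercept    beta=-0.0025 se=0.0021 OR=0.997 [0.993, 1.002] p=0.225 nSNP=50
simple_median      beta=-0.0922 se=0.0100 OR=0.912 [0.894, 0.930] p=2.26e-20 nSNP=50
weighted_median    beta=-0.0846 se=0.0096 OR=0.919 [0.902, 0.936] p=8.8e-19 nSNP=50
raps               beta=-0.0914 se=0.0065 OR=0.913 [0.901, 0.924] p=5.37e-45 nSNP=50
```

The IVW row says: one unit more exposure lowers the odds of the outcome by
a factor 0.913 (95% CI 0.901–0.924), estimated from 50 instruments; the
near-zero Egger intercept (p = 0.23) gives no evidence of directional
pleiotropy, and the medians and RAPS agree with the main estimate. Then
the mediation step (config file listing the four mediator tables):

```sh
mrmediation mediate --config demo/mediation.yaml --seed 42
mrmediation report --in demo/med_out/mediation.json
```

```
total effect beta=-0.0914 (OR 0.91)
mediator                indirect   prop %  included
smoking                  -0.0148     16.2  yes
hba1c                    -0.0114     12.5  yes
sbp                      -0.0104     11.4  yes
tg                       -0.0091     10.0  yes
(combined)               -0.0458     50.1
```

Each row is one mediator's product-of-coefficients indirect effect and its
share of the total effect; this replicate recovers the configured truth
(14/12/10/9%, combined 45%) within sampling noise. Mediators failing a
screen would show `no (<reason>)` and be excluded from the combined row.

The same workflow is available as library calls
(`total_effect_analysis`, `two_step_mediation`, `simulate_study`) on
in-memory tables.

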