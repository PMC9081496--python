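# Methods

## Estimand and workflow

The package estimates the causal effect of an exposure on an outcome from
two-sample GWAS summary statistics, and decomposes that effect into
mediator-specific indirect components. The workflow mirrors standard
practice: instruments are SNPs reaching genome-wide significance for the
exposure (p < 5×10⁻⁸, strict inequality), pruned to approximate
independence by greedy LD clumping (keep the smallest-p SNP, discard
everything with r² ≥ 0.001 to a kept SNP; ties broken by variant id so the
result is deterministic). Clumping consumes a precomputed r² table rather
than a genotype reference panel: LD estimation is a separate concern and
keeping it external makes the pipeline download-free.

Validity rests on the usual IV assumptions — instruments associate with
the exposure, are independent of confounders, and affect the outcome only
through the exposure. The sensitivity battery probes the third assumption.

## Harmonization

Effect sizes from different GWAS must refer to the same allele per SNP.
The exposure table is always the allele reference. An outcome/mediator
record with swapped alleles has its beta negated and frequency
complemented; alleles reconcilable only on the complementary strand are
complemented first; anything else is dropped as a mismatch. Palindromic
SNPs (A/T, G/C) carry no strand information in their allele codes, so the
effect allele is matched by frequency: after textual alignment, frequencies
on opposite sides of 0.5 imply a strand flip. The default policy drops a
palindromic SNP when either frequency lies within 0.08 of 0.5
(uninformative zone), the common community convention; a stricter
`drop`-all policy is available. This composition of a textual-swap sign
and a frequency-side sign makes harmonization invariant to arbitrary
re-coding of either table, which the suite checks property-style.

## Estimators

- **IVW (main analysis)**: the fixed-effects closed form above,
  algebraically identical to weighted least squares of Y on X through the
  origin with weights σY⁻². A multiplicative random-effects variant
  (SE inflated by the residual standard error when > 1) exists behind a
  flag but is never the default. Normal-approximation CIs and p-values.
- **MR-Egger**: weighted regression with free intercept after orienting
  all SNPs to non-negative X (Egger is not invariant to allele re-coding
  without this convention; IVW is, and is left untouched). SEs follow the
  multiplicative random-effects convention, scaled by max(1, RSE);
  inference uses t with K−2 df. The intercept estimates average
  directional pleiotropy.
- **Simple/weighted median**: per-SNP Wald ratios ordered ascending;
  estimate interpolates the weighted empirical CDF (midpoint convention)
  at 0.5, with inverse delta-method ratio variances as weights (equal for
  the simple median). SE by parametric bootstrap (default 1000 draws,
  explicit seed required through the pipeline) resampling both bx and by
  from their reported SEs.
- **MR-RAPS**: solves the profile score equation
  Σ (by−β·bx)·bx/(σy²+β²σx²+τ²) = 0 by bracketed Brent root-finding
  around the IVW estimate; τ² is zero by default or a method-of-moments
  overdispersion parameter iterated to convergence. SE from the observed
  information Σ bx²/(σy²+β²σx²+τ²). The Tukey-loss robustification of the
  full proposal is deliberately omitted; the implemented score captures
  the weak-instrument (measurement-error) correction, which is what the
  workflow uses it for.
- **MR-PRESSO**: each SNP's outcome effect is predicted from the IVW fit
  of the remaining SNPs; the observed residual sum of squares is compared
  with its null distribution over n_sim (default 1000) parametric
  simulations drawing bx* ~ N(bx, σx) and by* ~ N(β₋ₖ·bx, σy). The per-SNP
  outlier test compares each observed squared residual with its simulated
  distribution, Bonferroni-corrected across SNPs at α = 0.05; flagged SNPs
  are removed and IVW recomputed. Empirical p-values use the (r+1)/(n+1)
  convention, so n_sim bounds the smallest attainable p — with K SNPs the
  outlier test cannot flag anything unless n_sim ≳ K/α.
- **Leave-one-out / single-SNP**: IVW with each instrument omitted, and
  per-instrument Wald ratios, labeled by variant.

## Mediation decomposition

Step 1 (exposure→mediator) is IVW over the exposure's instruments. Step 2
(mediator→outcome given exposure) is a two-exposure multivariable MR per
mediator — weighted regression of by on (bx, bm) without intercept — which
mirrors reporting one adjusted effect per mediator rather than one joint
all-mediator model (a design choice; the per-mediator form matches how
such decompositions are tabulated). The instrument set for step 2 is the
union of the exposure's and the mediator's genome-wide-significant clumped
instruments, available in all three tables and re-clumped jointly; without
mediator-specific instruments the two design columns are collinear and the
model unidentifiable, so the generator always provides them and the fit
raises a collinearity error (condition number in the message) when a user
supplies a degenerate design.

Indirect effects are products a_i·b_i; proportions are signed percentages
of the total IVW effect and are reported outside [0, 100] with a warning
rather than clamped (inconsistent mediation is information, not an error).
Screening retains a mediator iff step-1 p < 0.05 AND step-2 p < 0.05, plus
an opt-in minimum-|proportion| floor (default 0) for excluding nominally
significant but negligible mediators; every exclusion carries its
triggering rule in the report. The combined proportion is the transparent
sum rule Σ indirect / total × 100. Published decompositions sometimes
print a combined row that is not the sum of its components; this package
always reports the exact sum and leaves any discrepancy visible.

## Synthetic data generator

The generator emulates consortium summary data: per-SNP true effects with
observed betas equal to truth plus Gaussian noise at the
standardized-trait SE, σ = (2·maf·(1−maf)·n)^(−1/2). Binary outcomes use
the same form with the GWAS's total n as an effective sample size — a
documented approximation adequate for noise-scale realism, not a logistic
likelihood. Defaults are the emulated study's scale: exposure n = 182,416,
outcome n = 184,305 (cases + controls), mediators n = 337,000, with 50
candidate exposure instruments and 60 mediator-specific instruments per
mediator; per-allele effect magnitudes are drawn uniformly from
0.04–0.12 trait-SD, the range of top GWAS hits, so candidate instruments
are genuinely genome-wide significant at these sample sizes. The causal
graph is SNP→exposure→mediator→outcome with a direct exposure→outcome
path and optional per-SNP direct (pleiotropic) outcome effects; the true
total effect is d + Σ a_i·b_i by construction. Directional pleiotropy is
planted relative to the exposure-increasing allele, since allele-coding
signs are otherwise arbitrary and a "directional" mean would cancel under
orientation.

Reproducibility: one seed determines everything; structural draws (MAFs,
alleles, true effects) advance block-by-block and each trait's noise uses
its own derived stream, so adding a mediator appends draws without
perturbing existing tables. Each trait's sample is independent
(two-sample regime); sample overlap is not modeled. LD is exchangeable
within blocks and zero across — enough to exercise the clumping contract,
not a model of human LD. Generated p-values are clamped to the smallest
positive double to keep extreme associations valid records.

The benchmark configuration plants four mediators with paths
a = (−0.14, −0.12, −0.10, −0.09), b = 0.1 each and direct effect −0.055,
i.e. true proportions 14/12/10/9% of a −0.1 total (combined 45%).

What passing synthetic tests does *not* show: robustness to real-data
features the generator omits — binary-trait likelihood asymmetry, sample
overlap, population stratification, realistic LD, allele-frequency errors
that defeat palindrome inference, and winner's-curse bias in instrument
selection.

## Numerical and validation choices

Degenerate inputs fail loudly: zero exposure effects (Wald), fewer than
3 (Egger, medians, RAPS, MVMR) or 4 (PRESSO) instruments, non-positive
SEs, collinear MVMR designs, and RAPS bracket failures all raise typed
errors the CLI maps to distinct exit codes (2 config / 3 data /
4 numerical). Egger and MVMR share the unscaled-covariance SE path so
noise-free inputs (zero residuals) are exact rather than NaN.

Validation is dual-route throughout: IVW, Egger and MVMR are checked to
1e-10 against normal-equation oracles written independently of the
implementation path; medians against a brute-force CDF scan; RAPS by
score-at-root and no-measurement-error reduction to IVW; PRESSO by
planted-outlier recovery and null calibration. Simulation sizes in the
suite (200 replicates for bias/coverage/power, 100 for full-pipeline
mediation recovery, 500 for the IVW null) were chosen so Monte-Carlo error
is well inside each asserted tolerance while the whole suite stays
desk-scale.

## Known limitations

Single-nucleotide biallelic variants only (indels rejected at read time);
no Steiger directionality filtering, SIMEX, mode-based or
contamination-mixture estimators; no bootstrap CIs on mediation
proportions; no real-data retrieval — consortium-scale replication
requires the user to supply the published summary tables in the TSV
dialect described in the I/O module.
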