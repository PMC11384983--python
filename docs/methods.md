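# Methods

## Model and assumptions

`mrmediate` performs two-sample summary-data Mendelian randomization.  For
each SNP j the inputs are the estimated per-allele effects on an exposure
(β̂ₓⱼ, seₓⱼ) and on an outcome (β̂ᵧⱼ, seᵧⱼ), taken from *different* GWAS
cohorts.  A SNP is a valid instrument if it (i) is robustly associated with
the exposure, (ii) is independent of exposure–outcome confounders, and
(iii) affects the outcome only through the exposure.  Selection targets (i)
via the p-threshold and F filter; (ii) via the confounder exclusion list;
(iii) is untestable and is probed by the sensitivity suite.

Per-SNP Wald ratios are rⱼ = β̂ᵧⱼ/β̂ₓⱼ with first-order SE seᵧⱼ/|β̂ₓⱼ|
(exposure-side noise is ignored in the ratio SE, the standard first-order
approximation; it is accounted for wherever bootstrap resampling is used).

### Estimators

* **IVW**: weighted regression of β̂ᵧ on β̂ₓ through the origin, weights
  1/seᵧ².  The slope equals the inverse-variance-weighted mean of the Wald
  ratios.  Default variant is *multiplicative random effects*: the fixed
  SE (Σwβ̂ₓ²)^(−1/2) is scaled by max(1, √(Q/(J−1))), so heterogeneity
  widens the interval but can never shrink it.  p from the standard normal.
* **MR-Egger**: the same regression with a free intercept, after orienting
  all exposure effects non-negative.  The intercept estimates average
  directional pleiotropy; slope and intercept SEs are scaled by
  max(1, √(RSS_w/(J−2))) and tested on t with J−2 df.
* **Weighted median**: the inverse-variance-weighted empirical CDF of the
  ordered ratios, pⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw, linearly interpolated to 0.5.
  Consistent when valid instruments carry > 50% of the weight.
* **Simple / weighted mode**: argmax of a normal-kernel density over the
  ratios on a 512-point grid spanning the ratio range padded by three
  bandwidths; bandwidth φ·0.9·min(SD, IQR/1.349)·J^(−1/5) with φ = 1 by
  default.  Consistent when the largest group of ratios is the valid one.
* Median and mode SEs come from a seeded parametric bootstrap (default
  1000 draws) that resamples both β̂ₓⱼ and β̂ᵧⱼ from their sampling normals.

All estimates are also presented as OR = exp(β) with 95% CI
exp(β ± 1.959964·se).

### Sensitivity diagnostics

* **Cochran's Q** = Σwⱼ(β̂ᵧⱼ − β̂·β̂ₓⱼ)² about the fixed-effect IVW slope;
  p from χ²(J−1).  The identity random-SE = fixed-SE·max(1, √(Q/(J−1)))
  ties Q to the random-effects variant and is tested.
* **MR-PRESSO**: for each SNP the residual from the leave-one-out IVW
  prediction is computed; the observed weighted RSS is compared with
  1000 parametric replicates simulated under the no-pleiotropy expectation
  (resampling both axes with observed SEs, leave-one-out slopes recomputed
  per replicate).  Monte-Carlo p-values carry the +1 correction, so
  1/(n_sim+1) is the attainable floor.  Per-SNP outlier tests are
  Bonferroni-corrected by J; the distortion test compares the
  outlier-removal shift against 1000 random same-sized removals; minimum
  J = 4 is enforced.
* **Leave-one-out** refits IVW J times and flags any sign change or
  crossing of nominal significance.
* Plot tables (scatter with per-method fits, funnel with the IVW vertical,
  forest with per-SNP and summary rows) are exported as data, optionally
  rendered to SVG.

### Mediation

The product (two-step) method with the *total* effect in the denominator:

    P(%) = 100 · (β₁·β₂)/β₀,

where β₀ (total X→Y) and β₁ (X→M) use the exposure's instruments and β₂
(M→Y) uses the mediator's own instruments; instrument sets are deliberately
not de-overlapped.  P's sign is preserved; a line whose indirect effect
opposes the total effect is flagged inconsistent rather than clipped.  The
reported SE of the indirect effect is the delta-method form
√(β₁²se₂² + β₂²se₁²) and the CI for P propagates both this and se₀ through
the ratio — extensions beyond the bare proportion, labeled as such, since
no closed-form small-sample distribution for P exists.

Screening gates use nominal α = 0.05 in both the bidirectional screen
(forward p < α and reverse p ≥ α) and the mediator screen (both edge
p-values < α), with no multiplicity correction by default — mirroring
common practice in hypothesis-generating microbiome/metabolome screens;
stricter control can be imposed by the caller on the audit tables, which
record every candidate with its p-values.

## Synthetic study conditions

The generator emits *summary-level* data only: observed effects are drawn
around true values with the analytic single-SNP SE

    se = 1/√(2p(1−p)n),   inflated by 1/√(φ(1−φ)) for a case-control trait,

with MAF p ~ U(0.05, 0.5).  Defaults emulate the cohort scales the pipeline
targets: exposure n = 18,340 (microbiome-GWAS scale), mediator n = 8,299
(metabolite-GWAS scale), outcome n = 4,887 with case fraction φ = 170/4887
(a rare congenital disease).  Three SNP blocks carry the causal structure:

* 30 exposure instruments, γⱼ ~ N(0, 0.1²) — median instrument p ≈ 1e-8 at
  the exposure sample size, i.e. comfortably strong (typical F ≫ 10);
* 30 mediator instruments, δⱼ ~ N(0, 0.15²), with outcome effect θ_mo·δⱼ
  and zero exposure effect.  These are essential: without mediator-specific
  instruments the step-2 ratio on chain SNPs identifies θ_total/θ_em rather
  than θ_mo, and no mediation proportion is recoverable;
* 10 outcome-specific loci, ηⱼ ~ N(0, 1²) on the log-odds scale — the
  disease's own GWAS hits, which are what make the reverse direction of the
  bidirectional screen estimable (large per-allele ORs are realistic for a
  strongly genetic congenital phenotype).

True effects compose linearly: mediator = θ_em·γ, outcome =
(θ_direct + θ_em·θ_mo)·γ + θ_mo·δ + η (+ pleiotropic α where configured).
Default θ_em = 0.4, θ_mo = 0.5, θ_direct = 0.6, so the true mediated share
is 0.2/0.8 = 25%.  Pleiotropy is injected per-instrument
(α ~ N(mean, sd²)); an "outlier" receives a deterministic gross effect
outlier_scale·|θ_total|·γ_sd (scale 10 by default) so "10× the typical
causal signal" does not depend on that SNP's own random γ.  Orientation
corruption (allele swap + β negation + eaf complement) and palindromic
allele pairs are applied on request to exercise harmonization.

What the generator does **not** emulate: linkage disequilibrium beyond a
block-diagonal toy r² model, winner's-curse in instrument discovery,
sample overlap between cohorts, non-collapsibility subtleties of the
log-odds scale for common outcomes, and MAF-dependent effect-size
architecture.  Passing tests therefore demonstrate correctness of the
algorithms and calibration under the stated generative model, not
robustness to every pathology of real consortium data.

## Numerical choices

* Strict inequalities where a rule says "greater/less than": p < threshold,
  F > 10, r² > clump cutoff.
* Clumping ties on p are broken by (chr, pos, snp) lexicographic order, so
  the survivor set is independent of input row order.
* Monte-Carlo p-values use (1 + #{exceedances})/(n + 1); zero is
  unreachable.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the pipeline derives per-stage seeds from one global seed via
  SHA-256 (`derive_seed`), so stages rerun in isolation reproduce the full
  run.
* Identical Wald ratios give bandwidth 0 in the mode estimator; the
  estimate is then the common ratio exactly.
* On-disk floats use `%.10g`, making write→read→write byte-stable and
  read∘write the identity to 10 significant digits.
* Degenerate inputs raise typed errors (zero exposure effect, too few
  instruments per method minimum — 1 for IVW/Wald, 2 for Q and
  leave-one-out, 3 for Egger/median/mode, 4 for MR-PRESSO, all flagged
  outliers).

## Problem sizes used by the test-suite checks

Calibration and recovery properties are checked at sizes chosen to keep the
whole suite in the low minutes on one CPU while leaving Monte-Carlo noise
well below the asserted tolerances: 500 replicates for null calibration
(type-I error band 0.05 ± 0.02; KS uniformity of Q p-values at 0.01), 200
replicates for the 25% mediation-proportion recovery (asserted within 3
Monte-Carlo SEs of the replicate median), 100 replicates each for
MR-PRESSO sensitivity (≥ 95% outlier detection) and specificity (≥ 90%
global p > 0.05), with 1000 RSS simulations per replicate.

## Known limitations

* First-order Wald SEs ignore exposure-side noise; with weak instruments
  (F near 10) IVW is mildly biased toward the null (regression dilution).
* The delta-method CI for P behaves poorly when β₀ is near zero; the
  proportion is reported with its components so users can judge.
* MR-PRESSO's distortion test conditions on the flagged set and inherits
  its Monte-Carlo granularity.
* No multivariable MR: the mediation decomposition assumes no
  exposure–mediator interaction and linear effects throughout.
* LD handling is only as good as the supplied r² provider; no reference
  panel ships with the package.
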