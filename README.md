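# mrmediate

Bidirectional two-step Mendelian randomization (MR) with product-method
mediation, built for GWAS **summary statistics**.

## The problem

Observational associations between the gut microbiome, circulating
metabolites and disease are hopelessly confounded.  Two-sample MR sidesteps
this by using genetic variants as instruments: a SNP that raises the
abundance of a bacterial genus is randomized at conception, so its effect on
disease risk estimates a *causal* effect of the genus — provided the
instrument assumptions hold.  `mrmediate` implements the complete analysis
for the three-node question "does exposure X affect binary outcome Y
*through* mediator M?":

1. **Instrument selection** per exposure: p < 1e-5 (5e-6 for the
   outcome-as-exposure reverse direction), greedy LD clumping (r² > 0.001
   within 10,000 kb), removal of confounder-associated SNPs from a
   user-supplied list, and the weak-instrument filter F = (β/se)² > 10.
2. **Harmonization** of exposure and outcome alleles onto one effect-allele
   orientation, with unconditional removal of palindromic (A/T, C/G) SNPs.
3. **Estimation** by five methods: inverse-variance weighted (IVW, primary),
   MR-Egger, weighted median, simple mode, weighted mode — each reported as
   β, SE, p and OR with 95% CI.
4. **Sensitivity**: Cochran's Q, the MR-Egger intercept test, MR-PRESSO
   (global RSS test, per-SNP outlier flags, distortion test,
   outlier-corrected IVW), leave-one-out, and scatter/funnel/forest exports.
5. **Bidirectional screen**: keep exposures whose forward IVW is significant
   while the reverse direction (outcome's own loci as instruments) is not.
6. **Two-step mediation** by the product of coefficients:

   β₀ = total X→Y effect (X's instruments), β₁ = X→M, β₂ = M→Y (M's own
   instruments), and the mediated share

       P(%) = 100 · (β₁ · β₂) / β₀ .

A summary-level **synthetic GWAS generator** with a known causal chain
(`simulate_chain` / `simulate_scenario`) stands in for consortium downloads,
so every stage is testable offline at desk scale.

## Worked example

Simulate one exposure→mediator→outcome chain (true mediated share 25%) and
run the two-step analysis:

```bash
mrmediate simulate --seed 7 --n-exposures 1 --n-mediators 1 --out sim
mrmediate mediate sim/exposure_00.tsv sim/mediator_00.tsv sim/outcome.tsv --out line.tsv
# P = 34.9% (indirect 0.1966, total 0.5631) -> line.tsv
```

`line.tsv` holds the full line (here: true P = 25%, estimated 34.9% with an
approximate SE of 20.7 percentage points — one replicate of a noisy
case-control outcome):

```
   exposure    mediator outcome   or0   or1   or2  indirect  proportion_pct  proportion_se_pct  consistent
exposure_00 mediator_00 outcome 1.756 1.459 1.684     0.197          34.921             20.701        True
```

The same harmonized data through all five estimators
(`mrmediate select` → `harmonize` → `estimate`, or via the library):

```
      exposure outcome          method  nsnp   beta    se  pval    or  ci_low  ci_high
genus_exposure disease             ivw    16  0.563 0.264 0.033 1.756   1.046    2.948
genus_exposure disease           egger    16 -0.117 0.761 0.880 0.889   0.200    3.953
genus_exposure disease weighted_median    16  0.431 0.354 0.223 1.539   0.769    3.079
genus_exposure disease     simple_mode    16  0.433 0.577 0.453 1.542   0.498    4.775
genus_exposure disease   weighted_mode    16  0.249 0.438 0.570 1.282   0.543    3.025
```

The IVW row is the primary estimate (OR 1.76, 95% CI 1.05–2.95); the other
methods lean on different identifying assumptions and here agree in
direction, which is the robustness argument.  `mrmediate run-all config.yaml`
drives the whole screen over many exposures and mediators from one YAML
config and writes tidy TSV reports plus a manifest (config hash, seed,
version).

As a pure-arithmetic example of the product method: three published IVW odds
ratios for a genus→metabolite→disease line — total effect OR 5.387, step-1
OR 0.803, step-2 OR 0.165 — give

```python
>>> from mrmediate import mediation_proportion
>>> from math import log
>>> round(mediation_proportion(log(5.387), log(0.803), log(0.165)), 1)
23.5
```

i.e. the metabolite carries 23.5% of the genus's total effect on disease
risk (two protective steps multiply into a risk-consistent indirect effect).

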