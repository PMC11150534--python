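# Methods

## The causal model

`mrmediate` implements two-sample Mendelian randomization (MR) with
two-step mediation.  Genetic variants G are used as instruments under the
usual MR assumptions: each instrument is associated with the exposure,
shares no confounder with the outcome, and affects the outcome only
through the exposure.  For mediation, the structural model is

```
X = Σ a_j G_j + e_x                         (exposure)
M = β₁ X + Σ b_j G_j + e_m                  (mediator)
Y = direct·X + β₂ M + Σ q_j G_j + e_y       (outcome)
```

so the total effect of X on Y is β₃ = direct + β₁β₂, the indirect
(mediated) effect is β₁β₂, and the proportion mediated is β₁β₂/β₃.  The
three coefficients are estimated by three separate univariable MR
analyses; β₃ is always re-estimated directly from the exposure→outcome
data rather than reconstructed, so the decomposition
`direct + indirect = β₃` holds identically in every result object.

All effect sizes are kept on the log-odds scale for binary traits and in
SD units for continuous traits; odds ratios appear only in output tables.
Recomputing published mediation proportions from two-decimal odds ratios
on the log scale reproduces them to rounding, which is the scale
convention this package adopts throughout.

## Estimators

Per-instrument Wald ratios are β_out/β_exp with the first-order SE
se_out/|β_exp|.  Ignoring the exposure-side noise in the SE is the common
convention; it makes the IVW-as-weighted-mean and IVW-as-regression views
coincide, and its cost is a mild anti-conservatism that is negligible for
strong instruments (the F ≥ 10 filter bounds it).

* **IVW** — weighted mean of ratios with weights 1/se². The fixed-effect
  SE is (Σw)^(−1/2). The random-effects variant inflates it by
  max(1, √(Q/(J−1))) (multiplicative overdispersion, floored so the random
  SE is never narrower than the fixed SE). In `auto` mode the model
  follows the heterogeneity test: random effects when Cochran's Q has
  p < 0.05, fixed otherwise. A single instrument degenerates to the Wald
  ratio.
* **MR-Egger** — weighted least squares of β_out on β_exp with a free
  intercept, weights 1/se_out², after orienting all instruments so
  β_exp > 0.  The intercept estimates the average directional pleiotropy;
  SEs use the same floored multiplicative overdispersion; p-values use the
  t distribution with J−2 df.
* **Weighted median** — interpolates the weight-cumulative distribution of
  the sorted ratios at probability 0.5 (IVW weights, normalized).
* **Weighted mode** — argmax over a 2048-point grid of the weighted
  Gaussian kernel density of the ratios, with bandwidth
  0.9·min(sd, IQR/1.349)·J^(−1/5) scaled by a user factor (default 1).
  When all ratios coincide the bandwidth is zero and the common ratio is
  returned.

Weighted median and mode SEs come from a seeded parametric bootstrap
(default 1000 replicates): each replicate redraws every instrument's
β_exp and β_out from normal distributions centred on the observed values
with their reported SEs and recomputes the estimator.  Confidence
intervals are normal-theory (±1.96·se) everywhere, matching the symmetric
intervals conventional in this literature.

## Instrument selection

Selection applies four steps in order, logging attrition counts at each:

1. **p-filter** — keep variants with p strictly below the threshold
   (defaults: 5·10⁻⁸; 5·10⁻⁶ for mediator-as-exposure legs, where a strict
   genome-wide cutoff would leave too few instruments).
2. **Clumping** — greedy: repeatedly take the smallest-p remaining variant
   as index and discard same-chromosome variants within 10,000 kb whose
   r² with it is ≥ 0.001.  LD comes from a user-supplied sparse table;
   absent pairs mean r² = 0.  This keeps the package free of genotype
   reference panels; the synthetic module emits a matching table.
3. **Harmonization** — outcome effects are aligned to the exposure's
   effect allele: swapped alleles negate β_out and reflect the frequency;
   strand flips are recognised by complementing.  Palindromic (A/T, C/G)
   variants cannot be resolved by allele labels, so allele frequency
   decides — only when both frequencies lie outside 0.5 ± 0.08; otherwise
   the variant is dropped with reason "ambiguous palindrome".  Guessing is
   never attempted.
4. **F-filter** — instruments with F = (β_exp/se_exp)² < 10 are removed
   (strict inequality).  This single-SNP F is the square of the marginal
   z-score; it needs no R²/N bookkeeping and agrees with the common
   weak-instrument rule of thumb.

Missing instruments in the outcome GWAS are dropped and logged; proxy
lookup is out of scope.

## Sensitivity battery

* **Cochran's Q** around the fixed-effect IVW mean, χ²(J−1) p-value; the
  result records the fixed/random decision it implies.
* **Egger intercept** — reported with SE and p; p < 0.05 is flagged as
  evidence of directional pleiotropy.  The pipeline never silently drops
  flagged SNPs; excluding them is an explicit re-run with an exclusion
  list.
* **Leave-one-out** — J IVW re-fits, each omitting one instrument, all
  using the model flavor selected by the full fit.  The qualitative
  "stability" notion is made precise as CI sign concordance: the result is
  stable iff every leave-one-out interval reaches the same sign conclusion
  (positive / negative / spanning zero) as the full estimate; offending
  variants are named.
* **Steiger directionality** — per-SNP variance explained is recovered
  from the marginal t statistic, r² = t²/(t² + n − 2), summed over
  instruments for each trait; the causal direction is accepted when the
  exposure r² exceeds the outcome r².  The p-value compares the two summed
  r² via Fisher's z transform of r = √r².  Working from t statistics
  rather than allele-frequency variance formulas lets the same code serve
  binary and continuous traits with only β, se and N available.

## Synthetic data generator

The generator exists so that every stage of the pipeline is testable with
known truth.  It simulates *individual-level* data for three
non-overlapping cohorts (honouring the two-sample design) and then runs
per-SNP marginal regressions, which guarantees internally consistent
β/se/p/EAF/N and realistic weak-instrument behaviour:

* Genotypes are binomial(2, MAF) draws; optional LD blocks use a
  haplotype-copy construction (each SNP copies a shared block tag allele
  with probability τ = r²^¼, giving pairwise genotype r² ≈ the configured
  value).  Variants are otherwise placed ≥ 25 Mb apart so clumping leaves
  them untouched.
* The exposure has `n_snp_instrument` true instruments; the mediator has
  its own `n_snp_instrument_mediator` direct instruments (without them the
  mediator→outcome leg would have no selectable variants, since the
  exposure's instruments act on M only through the attenuated β₁ path);
  the remaining variants are null.
* Directional pleiotropy q_j ~ Normal(mean, sd) is applied relative to
  the *exposure-raising* allele orientation — the orientation MR-Egger
  uses — because pleiotropy tied to arbitrary allele coding is not
  directional in any detectable sense.
* Continuous traits are scaled to approximately unit variance and
  analysed by vectorised per-SNP least squares.  A binary outcome adds
  standard-logistic noise to the structural liability and thresholds it at
  the configured prevalence (default 6.3%, a subclinical-hypothyroidism
  scale); per-SNP logistic regressions (vectorised Newton–Raphson) then
  return log odds ratios.  With logistic liability noise the marginal
  log-ORs estimate the structural coefficients up to the usual (here
  negligible) non-collapsibility attenuation.

Default study conditions: 20 exposure instruments, 20 mediator
instruments, 60 null variants, MAF ~ U(0.15, 0.5), per-allele instrument
effects U(0.12, 0.20) (strong enough that genome-wide selection at
n = 20,000 keeps essentially every instrument, avoiding winner's-curse
attenuation in recovery experiments), β₁ = −0.15, β₂ = 0.17,
direct = −0.14 (hence β₃ = −0.1655 and a true proportion mediated of
15.4%), 20,000 individuals per cohort, continuous outcome.  The binary
mode mirrors disease-style analyses and is exercised separately.

A direct-summary mode (`simulate_summary`, `simulate_instruments`) samples
the marginal estimates straight from β̂ ~ Normal(truth, se) with
se = (2f(1−f)n)^(−1/2).  It skips genotype-level realism (no LD, no
binary outcomes, no finite-sample regression artefacts) and exists for
large calibration suites — thousands of replicates in seconds.

What passing tests on these data do *not* show: robustness to sample
overlap, population stratification, assortative mating, real LD
structure, or genetic architectures resembling any particular trait.  The
generator is a correctness instrument, not a portrait of real data.

## Numerical and design choices

* Strict inequalities at both selection thresholds (p < cutoff retained,
  F < 10 removed).
* The fixed/random IVW switch is driven by the Cochran's Q p-value — the
  only p-value that can sensibly drive it.
* The heterogeneity type-I-error calibration uses valid instruments with
  zero causal effect; in that regime the standardized ratio residuals are
  exactly standard normal (the first-order ratio SE conditions on the
  realized exposure estimate), so Q is exactly χ².  With a nonzero causal
  effect the first-order weights ignore the c²·se_exp² term and Q becomes
  mildly anticonservative; with F ≥ 10 instruments the effect is a few
  percent at most.
* Mediation indirect-effect intervals use the first-order delta method;
  Sobel-type or bootstrap intervals are deliberately not implemented (the
  delta interval matches the symmetric intervals printed in this
  literature).  Inconsistent mediation (opposite signs of indirect and
  total effect, or |proportion| > 1) raises a warning and is recorded on
  the result, never hidden.
* Mediator screening admits a mediator when both legs are IVW-significant
  at raw p < 0.05; Bonferroni/FDR adjustment is a config switch, off by
  default, mirroring the screening practice this pipeline reproduces.  A
  mediator identical to the outcome is flagged and skipped.
* Degenerate inputs fail loudly: zero exposure effect (Wald ratio), zero
  exposure spread (Egger), empty instrument intersections, zero total
  effect (proportion mediated) are all explicit errors, and each selection
  step names itself when it exhausts the candidate set.
* Monte-Carlo problem sizes in the test suite (e.g. 100 pipeline
  replicates at n = 20,000; 5000 instrument-level replicates for the Q
  calibration; 200 replicates for coverage and directionality) were chosen
  to give Monte-Carlo standard errors small enough for 3-MCSE assertions
  while keeping the default suite fast on a single CPU.

## Known limitations

* No multivariable MR, MR-PRESSO, CAUSE, or contamination-mixture
  estimators; no proxy-SNP lookup; no VCF/BGEN parsing; no liftover.
* Wald-ratio SEs ignore exposure-side noise (see above); with weak
  instruments (F near 10) intervals can be slightly narrow.
* The Steiger comparison treats summed per-SNP r² as independent, which
  is adequate for clumped (near-independent) instruments only.
* One mediator at a time: network mediation with simultaneous mediators is
  out of scope.
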