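# Methods

This note documents the statistical model behind `vadmr`, the defaults and
their rationale, the synthetic data generator, and known limitations. It
describes what the code does, not empirical claims; all numbers quoted in the
README are produced by the analysis scripts and `scripts/acceptance.py`.

## Study design

The pipeline performs two-sample summary-statistic Mendelian randomization
(MR) with cis genetic instruments for drug targets. For a target gene, a
biomarker GWAS (the drug's pharmacodynamic readout) supplies instrument
effects `bx ± sex`, and an outcome GWAS supplies the same variants' effects
`by ± sey`. Under the instrumental-variable assumptions (relevance, no
confounding of the variant-outcome relation, exclusion restriction), the
causal effect of a unit change in the biomarker via that target is estimated
from the ratio of the two.

Restricting instruments to the cis region (±500 kb around the gene,
`flank_bp=500_000`, inclusive on both bounds) makes the exclusion restriction
more plausible: variants acting through the encoded protein are less likely
to be pleiotropic than trans associations.

## Instrument selection

- Candidate variants: cis window, p < 5×10⁻⁸ (`P_PRIMARY`). If none
  qualifies, the threshold relaxes to 5×10⁻⁵ (`P_FALLBACK`) and the result is
  flagged `fallback_used`; the weaker threshold keeps druggable targets with
  modest regional signal analysable at the cost of weaker instruments.
- Greedy clumping: candidates are ranked by p-value (ties broken by position
  then identifier, so results are row-order invariant); each index variant
  removes candidates with r² ≥ 0.001 (`CLUMP_R2`) within 10 Mb
  (`CLUMP_WINDOW_BP`) of it. The near-independence threshold lets downstream
  IVW treat instruments as uncorrelated.
- Missing LD entries are treated as r² = 1 (`missing_r2=1.0`): a pair whose
  correlation is unknown is assumed dependent. This is conservative; set
  `missing_r2=0.0` to assume independence instead.
- Genome-wide mode applies the same threshold-and-clump per chromosome, for
  biomarker analyses not restricted to one gene.
- Proxy lookup: instruments absent from the outcome GWAS may be replaced by
  the most correlated present variant with r² ≥ 0.8 (ties by higher r², then
  position, then identifier).

## Harmonization

Exposure and outcome rows for the same variant are aligned on effect allele:

- direct match — no change; allele swap — negate `by`, flip `eaf`;
- strand complement (A↔T, C↔G) — matched after complementing, then as above;
- palindromic variants (A/T or C/G) — strand cannot be inferred from alleles,
  so allele frequency is used: if both frequencies fall on the same side of
  0.5 the orientation is kept, opposite sides flips it, and variants with
  either frequency in the ambiguous 0.42–0.58 band are dropped
  (`palindromic-ambiguous`);
- incompatible allele pairs are dropped with a per-variant reason recorded.

## Estimators

Let `bx, sex, by, sey` be harmonized per-variant effects.

- **Wald ratio** (1 instrument): `by/bx`, first-order se `sey/|bx|`, or the
  full delta-method se `sqrt(sey²/bx² + by²·sex²/bx⁴)` (second order).
- **IVW** (≥2): weighted least squares of `by` on `bx` through the origin
  with weights `1/sey²`. Fixed-effect by default; multiplicative random
  effects scales the se by `sqrt(Q/df)`; `random_effects="auto"` (the
  pipeline default) escalates exactly when Q/df > 1, so homogeneous sets keep
  exact fixed-effect inference and heterogeneous sets are widened.
- **Generalized IVW** for correlated instruments: GLS with covariance
  `Ω = D ρ D`, `D = diag(sey)`, `ρ` the LD correlation; an optional ridge
  stabilizes near-singular LD.
- **Cochran's Q** with weights `bx²/sey²` measures ratio heterogeneity.
- **MR-Egger** (≥3): WLS of `by` on `bx` with intercept after orienting all
  `bx ≥ 0`; the intercept tests directional pleiotropy; the residual
  dispersion is floored at 1 (multiplicative random effects).
- **Weighted median** (≥3): median of ratio estimates under IVW weights by
  mid-cumulative-weight interpolation; se by parametric bootstrap (default
  1,000 draws, seeded).
- **Instrument strength**: per-variant F = (bx/sex)²; the summary F is the
  mean; F < 10 flags weak instruments.

The pipeline's estimator-choice rule: 1 instrument → Wald ratio; ≥2 → IVW
(auto); ≥3 adds MR-Egger and weighted median as sensitivity analyses.
Case-control estimates are exponentiated to odds ratios for reporting.

## Drug-action orientation

Each target carries `action_sign ∈ {−1, +1}`: −1 for drugs that inhibit or
lower the protein/biomarker, +1 for agonists. Orientation multiplies the
estimate by the action sign (negation swaps the CI bounds; on the OR scale
this inverts the odds ratio), so a protective drug reads as OR < 1
regardless of which allele raises the protein. The operation is an
involution and p-values are unchanged.

## Outcome meta-analysis

Independent case-control cohorts of the same outcome are combined per
variant by fixed-effect inverse-variance weighting after harmonizing the
second cohort's alleles to the first (METAL's STDERR scheme). Sample sizes,
cases, and controls sum across sources; a two-study I² is reported. The
design's clinical outcome combines cohorts of 3,892/466,606 and
3,116/433,066 cases/controls into 7,008/899,672.

## Positive-control gating

A target's dementia estimates are only interpreted if the same instruments
recover the drug class's established indication: the gate passes iff any
positive control shows the expected drug-action sign with p < 0.1. Failures
are classified `fail-direction` (the most significant control is
wrong-signed) or `fail-precision`; targets without analysable controls are
`no-instruments`. The lenient p < 0.1 reflects that controls validate the
instrument, not the hypothesis; strictness here would discard valid targets
with modest control power.

## Colocalization

For each target-outcome region, per-variant Wakefield log approximate Bayes
factors `0.5·log(1−r) + 0.5·z²·r` with `r = W/(V+W)` (prior effect sd
`sqrt(W)` = 0.15 for quantitative, 0.2 for case-control traits) feed the
standard five-hypothesis enumeration (H0 no association … H4 shared causal
variant), computed in log space with `logsumexp` for stability. Priors
p1 = p2 = 10⁻⁴ (trait-specific causal variant) and p12 = 10⁻⁵ (shared).
PP.H4 > 0.5 is flagged as supporting a shared causal variant; MR estimates
without colocalization support may reflect LD confounding.

## Multiplicity

- **ACAT** combines a target's per-outcome p-values via the Cauchy
  transformation `mean(tan((0.5−p)π))`; valid under arbitrary dependence;
  p-values are clipped to [10⁻¹⁵, 1−10⁻¹⁵].
- **Li–Ji effective number of tests**: from the outcome correlation matrix's
  eigenvalues, `Meff = Σ [I(λ≥1) + (λ−⌊λ⌋)]`; the ACAT p is then
  Šidák-adjusted as `1−(1−p)^Meff`.
- The outcome correlation is estimated from the cross-target z-score matrix
  (pairwise-complete Pearson, repaired to positive semi-definite); with
  fewer than three targets an identity matrix is used.
- **FDR**: Benjamini–Hochberg within drug class, then globally across
  targets (statsmodels `multipletests`).

## Synthetic data generator

Real GWAS summary statistics cannot be redistributed, so `vadmr.synthetic`
simulates them directly on the standardized-genotype scale:

- LD: AR(1) correlation `R[i,j] = decay^|i−j|` (default decay 0.5, 60
  variants spaced 2 kb).
- Exposure: a few causal variants (default 6) with N(0, 0.03²) effects;
  marginal effects are `R @ causal`; sampling noise is drawn
  MVN(0, R/n) via Cholesky, giving the correct correlation between
  neighbouring test statistics.
- Outcome: `by = theta·bx_true + alpha + noise`, with optional directional
  pleiotropy `alpha`; case-control standard errors use
  `1/sqrt(N·φ·(1−φ))` with case fraction φ, quantitative ones `1/sqrt(n)`.
- Effects are converted to the per-allele scale by dividing by
  `sqrt(2·maf·(1−maf))`; minor allele frequencies are uniform on a
  configurable range, and a fraction of variants are emitted as palindromic
  to exercise harmonization.
- `simulate_region_outcomes` draws one exposure region and several outcomes
  sharing its ground truth, which is how the toy study gives each target
  consistent effects on the clinical outcome, the imaging outcome, and its
  positive control.

What the generator does **not** emulate: sample overlap between exposure and
outcome GWAS, population stratification, imputation quality, winner's curse
in instrument selection, or non-AR(1) LD structure.

## Calibration

`vadmr.calibration` runs repeated-region Monte-Carlo studies:

- `parameter_recovery` simulates regions with a known effect and reports the
  IVW mean bias, Monte-Carlo se, 95% CI coverage, and mean F, using the
  pipeline's auto-escalating IVW (the estimator actually used for
  inference).
- `null_calibration` simulates null regions and tests the uniformity of
  fixed-effect IVW p-values, and of ACAT combinations of them, by
  Kolmogorov–Smirnov. The fixed-effect test is used here because uniformity
  is a property of the exact test; the auto-escalation is deliberately
  conservative under the null (it can only widen intervals).

Replicates whose regions yield no instruments are skipped, so reported `n`
can be slightly below the requested replicate count.

## Open design decisions and limitations

- The 0.42–0.58 palindromic ambiguity band, the p < 0.1 gate, the
  `missing_r2=1` conservatism, and the coloc priors are defensible defaults,
  not estimated quantities; all are `PipelineOptions` fields.
- MR-Egger's intercept test has low power with few cis instruments; with the
  toy study's 3–5 instruments it is a qualitative check only.
- The generalized IVW assumes the LD matrix comes from the same population
  as the GWAS; mis-specified LD biases it in either direction.
- Colocalization assumes at most one causal variant per trait per region.
- Estimates are per unit of the biomarker on the standardized scale and are
  not calibrated to any drug dose.
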