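# Methods

This note documents the models, numerical conventions and design choices in
`omicmr`, and what the synthetic-data generator does and does not emulate.

## Instrument selection

Selection runs as a fixed cascade — genome-wide significance, cis window,
MHC exclusion, LD clumping, F-statistic, palindrome handling, confounder
screen, allele harmonization — with these conventions:

- **Strictness.** P < 5×10⁻⁸ and F > 10 are strict inequalities; the cis
  window (TSS ± 1,000,000 bp) and the MHC interval (chr6:26,000,000–
  34,000,000, GRCh37) are closed. The cis anchor is the TSS for both pQTL
  and eQTL instruments — a single consistent anchor; the alternative
  (flanking the coding sequence) differs only at window edges.
- **Clumping** is greedy: candidates are visited in ascending p (ties broken
  by snp_id, so audits are reproducible), each retained index SNP pruning
  all SNPs within 10 Mb (center-to-center) whose r² with it exceeds 0.001.
  LD comes from a supplied panel (signed r, squared internally); SNPs absent
  from the panel are dropped rather than guessed. The result is provably an
  independent set and matches an exhaustive subset oracle on small panels.
- **Palindromes.** A/T and C/G SNPs are strand-ambiguous; they are dropped
  only when MAF ≥ 0.42 (the frequency no longer disambiguates the strand),
  retained and flagged otherwise. An `exclude_all` switch is available.
  Missing exposure EAF is a rejection (the palindrome rule and Steiger R²
  need it); missing outcome EAF is tolerated and flagged.
- **Duplicated rsIDs** keep the record with the smallest p, logged as
  `duplicate_snp`. Multi-allelic sites are not otherwise modeled.
- The order of logically independent stages (e.g. MHC vs palindrome) does
  not change the final set; the fixed order exists for stable audits.

## MR estimation and sensitivity cascade

- **Wald ratio** SE uses the first-order delta method (σ_Y/|β_X|), the
  two-sample convention; the exposure-side uncertainty is ignored at this
  order.
- **IVW** is weighted LS through the origin with weights σ_Y⁻². The
  random-effects variant is multiplicative — SE × √max(1, Q/(k−1)) — not
  additive, matching the fixed/random switch behavior of the standard R
  implementations; `auto` selects random effects when the Q-test p < 0.05.
- **MR-Egger** orients every instrument to β_X ≥ 0 (flipping both betas),
  then fits weighted LS with intercept. Coefficient SEs use the WLS
  covariance with the residual SD floored at 1 (so exact fits keep a finite,
  design-driven SE) and a t reference with k − 2 df. A significant intercept
  (p < 0.05) marks the exposure `excluded_pleiotropy`.
- **MR-PRESSO** computes the observed global RSS with leave-one-out IVW
  estimates and simulates its null by redrawing both betas from their
  sampling distributions (n_sim = 1,000 by default, seed mandatory).
  Per-SNP outlier p-values are acted on — instruments removed — only when
  the global test is itself significant; acting on them unconditionally
  would discard valid instruments in roughly a third of clean k = 8 runs at
  the 0.05 per-SNP level. The distortion test is not implemented.
- **Steiger filtering** compares per-SNP variance explained,
  R²_X = 2f(1−f)β_X² for the standardized quantitative exposure and, for a
  case-control outcome, R²_Y = v(1−v)·2f(1−f)β_Y² — the log-odds slope
  mapped to the observed 0/1 scale through the case-fraction variance
  v(1−v) (a linear-probability approximation of the marginal logistic
  slope). The test is the Fisher-z two-correlation comparison on the two
  independent sample sizes; removal requires both the reversed direction
  and p < 0.05. Instruments without an EAF are exempted, not removed.
- **Cascade order** is Steiger → PRESSO → Q/model choice → IVW (Wald at
  k = 1) → Egger verdict. The order of the two filters is a package
  convention; every removal is counted in the per-exposure report.
- **FDR** is Benjamini–Hochberg within each (omic layer × outcome) family;
  layers are never pooled, so a target significant in two layers is two
  family members, not one.

## Colocalization

Single-causal-variant colocalization from summary statistics. Per SNP and
trait, the Wakefield log approximate Bayes factor is
½(log(1−r) + r·z²), r = w/(w+σ²), using the standard-error-based shrinkage.
The effect-size prior variances are w = 0.2² for quantitative traits and
0.15² (log-odds) for case-control traits — the de-facto defaults for this
framework, config-exposed because no single value is canonical. Hypothesis
sums S0…S4 are accumulated with log-sum-exp; S3 uses
log(ΣB₁·ΣB₂ − ΣB₁B₂) via a guarded log-difference, which is exactly −∞ for
a single-SNP region. Posteriors therefore sum to 1 to better than 10⁻⁹ for
|z| well beyond 50. Priors default to p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵; a warning
fires if p₁₂ exceeds min(p₁, p₂). Analysis is restricted to the SNP
intersection of the two regions; nothing is imputed. PPH4 classification
uses closed thresholds (≥ 0.80 high, ≥ 0.50 medium) everywhere, including
in the evidence score.

## Meta-analysis

"Common effects" is inverse-variance fixed-effect pooling;
"random effects" is DerSimonian–Laird with τ² floored at 0 and weights
1/(σ² + τ²). Model choice follows the Cochran Q test on the pooled sources:
common when p > 0.05, random otherwise — a Q-p of exactly 0.05 goes to
random effects (the strict reading of "p > 0.05 → common"). I² =
max(0, (Q−df)/Q)·100 is reported descriptively alongside either model and
never overrides the Q rule.

## Evidence score

Three independently accruable components per (target, outcome): MR (1 point
at adjusted p < 0.05, 0.5 at < 0.10, best class across layers — summing
across layers would let a dual-layer hit exceed what a single line of
genetic evidence warrants), colocalization (1 at PPH4 ≥ 0.8, 0.5 at ≥ 0.5),
and replication (1 when a pooled estimate exists whose 95% CI excludes
OR = 1 with the discovery direction). Outcomes without a replication cohort
are `not_available`, which scores like `no` but is reported distinctly.
Attainable scores are exactly {0, 0.5, …, 3.0}; scoring is monotone in each
component. Ranking is per outcome by score, then best PPH4 (descending),
then best adjusted p (ascending), then symbol. Downstream context (hubs,
drugs, knockouts) is deliberately outside the score.

## Network hub scoring

MCC(v) sums (|C|−1)! over the maximal cliques (|C| ≥ 2) containing v, with
exact Bron–Kerbosch (pivoting) enumeration; MNC(v) is the largest connected
component of the open neighborhood; Degree is the edge count. MCODE weights
each node by k × density of the highest k-core of its closed neighborhood,
grows modules from the highest-weight seeds over unassigned nodes within
(1 − 0.2) of the seed weight, then applies a haircut implemented as iterated
removal of members with fewer than two within-module neighbors (the
module's 2-core); the fluff stage is off and unimplemented. All tie-breaks
are lexicographic in the node symbol. Edge lists may carry a confidence
column with a 0.4 default cutoff. The EPC hub score is out of scope
(stochastic, and not part of the final hub selection this package models).

## Synthetic-data generator

The generator produces individual-level data and then summarizes it, so
standard errors, EAFs and the case-control scale behave like real summary
statistics rather than being asserted.

- **Genotypes.** One cis region of 200 SNPs at 10 kb spacing. Two haplotypes
  per individual from a Gaussian AR(1) copula (latent correlation
  `ld_rho` = 0.9) thresholded at the MAF quantile; MAF ~ U[0.05, 0.5].
  Thresholding attenuates the realized allele-level correlation to the
  φ (tetrachoric-implied point) coefficient — φ(0.9, MAF 0.3) ≈ 0.70 — so
  `ld_rho` is the latent parameter, not the realized r; the realized decay
  with distance is what matters downstream and is verified against the
  orthant-probability expectation. Calibrating the latent scale upward to
  force realized adjacent r = 0.9 would push distance-28 LD to r ≈ 0.5 and
  destroy the near-independence of the 8 instrument loci, so it is not done.
- **Traits.** Exposure X = Σβ_j G_j + ε with ε scaled so var(X) ≈ 1
  (effects in ~SD units); causal effects are drawn N(0, `qtl_effect_sd`²)
  with `qtl_effect_sd` = 0.15 at 8 loci spread across the region (~28 SNPs
  apart, realized r² ≈ 0.003). The binary outcome is drawn
  from a logistic model with log-odds θ·X plus scenario-specific direct SNP
  effects, centered to a 10% case fraction, in an independent cohort of
  20,000 (exposure cohort 10,000) — the two-sample design holds by
  construction. Marginal statistics are simple linear regression (exposure)
  and the logistic score-test approximation (outcome), which keeps 1,000
  simulated studies affordable on one CPU; p-values are floored at 10⁻³⁰⁰.
- **Scenarios.** `h0`–`h4` mirror the five colocalization configurations
  (`h1` GWAS-only, `h2` QTL-only, `h3` distinct variants 50 SNPs apart,
  `h4` shared); `pleiotropy_directional` adds a direct outcome effect of
  0.05 oriented with each instrument's exposure effect (so it appears as a
  directional Egger intercept after orientation); `outlier` shifts one
  instrument's outcome effect by 10 SEs; `reverse_cause` loads the exposure
  on the outcome's genetic liability (loading 0.1, per-allele log-odds 1.0),
  which makes the reverse loci genome-wide significant for the exposure
  while explaining far more outcome variance — the situation Steiger
  filtering exists to catch. An optional `target_z` rescales causal effects
  to a chosen marginal z, used where a stated condition is an association
  strength rather than an effect size.
- **What is not emulated.** Realistic human LD maps, imputation error,
  sample overlap between cohorts, trans effects, and multi-allelic sites.
  Passing calibration tests on this generator demonstrates the estimators'
  behavior under their own assumptions, not robustness to those
  complications.
- Generated SNPs use non-palindromic allele pairs so that scenario truth
  (e.g. "8 instruments") is not randomly eroded by the palindrome filter;
  palindrome handling is exercised by dedicated constructed fixtures.
- All randomness flows from one seed through named substreams;
  `cohort_seed` redraws the cohorts with the population (MAF, alleles, true
  effects) fixed, which is exactly a replication study.

## Reference problem sizes

The calibration checks run at the generator defaults: estimator recovery
(θ = 0.5) over 200 seeds with 95%-CI coverage required in [0.90, 0.99];
type-I error over 1,000 null (θ = 0, QTL-only) seeds against binomial 99%
bounds around 0.05; colocalization recovery over 100 shared-variant and 100
distinct-variant seeds (target z = 10 at the causal SNP) requiring ≥ 80%
correct resolution; reverse-causation detection over 100 seeds requiring
≥ 90% with at least one Steiger removal. Estimator-calibration runs build
the instrument set at the generator's true causal loci: they test the
estimators, not the selection cascade, which has its own designed fixtures
(with defaults, adjacent causal loci at true r² ≈ 0.003 exceed the 0.001
clump threshold, so full clumping deliberately thins any 8-locus set).

## Known limitations

- IVW on marginal logistic effects inherits the usual non-collapsibility
  attenuation (a few percent at these effect sizes); estimates are of the
  marginal log-odds effect.
- The Steiger binary-outcome R² conversion is an approximation; rank
  ordering (which is all the filter uses) is insensitive to the choice
  among the common variants.
- Single-causal-variant colocalization: regions with allelic heterogeneity
  dilute PPH4 by design.
- MR-PRESSO p-values are empirical (resolution 1/n_sim); the distortion
  test is not provided.
- The pipeline assumes GRCh37 coordinates throughout; no liftover.
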