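# omicmr

Multi-omics Mendelian-randomization (MR) target prioritization on summary
statistics, built around the analysis pattern used to triage drug targets
for glomerulonephritis (GN) and its subtypes (acute, chronic, IgA
nephropathy, membranous nephropathy): plasma-protein (pQTL) and transcript
(eQTL) cis instruments against case-control GWAS outcomes, a full
sensitivity cascade, Bayesian colocalization, discovery/replication
meta-analysis, and a rule-based genetic evidence score, plus hub scoring on
a protein-protein interaction (PPI) network.

It is written for statistical geneticists and methodologists who want the
whole pipeline runnable, testable and auditable on data they control: every
stage accepts plain tab-delimited summary statistics, and a synthetic-data
generator with known ground truth stands in for the consortium datasets the
real analysis would download.

## The statistics

**Instruments.** For each exposure (a protein or transcript), candidate SNPs
pass: P < 5×10⁻⁸ (strict); cis position within 1 Mb of the TSS (closed);
exclusion of the MHC (chr6:26–34 Mb); greedy LD clumping (r² > 0.001 within
10 Mb pruned, best p kept, deterministic ties); instrument strength
F = (β/σ)² > 10; exclusion of strand-ambiguous palindromic SNPs
(A/T, C/G with MAF ≥ 0.42); and a confounder screen (any association at
P < 10⁻⁵ in a user-supplied table). Outcome effects are then allele-
harmonized; every removal is logged with a reason and the stage counts
telescope.

**Estimation.** One instrument: Wald ratio θ = β_Y/β_X with delta-method SE.
k ≥ 2: inverse-variance weighting (IVW), the weighted regression of β_Y on
β_X through the origin with weights σ_Y⁻²; a multiplicative random-effects
SE (inflation by √(Q/(k−1)), floored at 1) replaces the fixed model when
Cochran's Q is significant. exp(θ) is the odds ratio per unit exposure.

**Sensitivity cascade.** Steiger filtering removes instruments explaining
more variance in the outcome than in the exposure (Fisher-z test); MR-PRESSO
detects pleiotropic outliers by comparing the observed weighted residual sum
of squares with a parametric bootstrap; MR-Egger regression (with intercept)
estimates directional pleiotropy — exposures with intercept p < 0.05 are
excluded. FDR control is Benjamini–Hochberg within each omic layer × outcome
family.

**Colocalization.** Wakefield approximate Bayes factors,
log ABF = ½(log(1−r) + r·z²) with r = w/(w+σ²), combined over the five
single-causal-variant hypotheses H0–H4 with priors p₁ = p₂ = 10⁻⁴,
p₁₂ = 10⁻⁵, in log space. PPH4 ≥ 0.80 is "high", ≥ 0.50 "medium".

**Replication & meta-analysis.** Discovery and replication estimates are
pooled by inverse-variance common-effect weighting, or DerSimonian–Laird
random effects when the Q test p ≤ 0.05; I² is reported descriptively.

**Evidence score.** Per (target, outcome): 1 point each for MR at FDR < 0.05
(best class across omic layers), colocalization PPH4 ≥ 0.8, and
direction-consistent replication whose pooled 95% CI excludes OR = 1;
0.5 points for suggestive MR (FDR < 0.10) or moderate colocalization
(0.5 ≤ PPH4 < 0.8). Maximum 3.0.

**Network pharmacology.** Degree, Maximum Neighborhood Component (MNC) and
Maximal Clique Centrality (MCC, exact maximal-clique enumeration) hub
scores, and MCODE dense-module detection, on a user-supplied PPI edge list.

## Worked example

Simulate a study with one strong shared causal variant and run MR on the
true instruments:

```python
from omicmr.simulate import ScenarioConfig, simulate_sumstats, truth_instruments
from omicmr.mr import ivw
from omicmr.coloc import colocalize

cfg = ScenarioConfig(scenario="h4", theta_true=0.5)   # 200 SNPs, 8 instruments
sim = simulate_sumstats(cfg, seed=1)
est = ivw(truth_instruments(sim))
print(f"theta = {est.theta:.3f}  OR = {est.or_:.2f} "
      f"[{est.ci_low:.2f}, {est.ci_high:.2f}]  p = {est.pvalue:.2e}  k = {est.k}")

res = colocalize(sim.qtl, sim.gwas)
print(f"PPH4 = {res.pph4:.3f} ({res.class_})")
```

Output:

```
theta = 0.417  OR = 1.52 [1.33, 1.74]  p = 1.10e-09  k = 8
PPH4 = 0.988 (high)
```

The IVW log-odds estimate recovers the simulated causal effect 0.5 up to
sampling noise and the expected mild attenuation of marginal logistic
effects, the CI on the odds-ratio scale excludes 1, and the QTL and GWAS
signals colocalize (the generator placed the causal variants in both traits
at the same SNPs).

The same analysis is available from the shell:

```sh
omicmr simulate --scenario h4 --seed 1 --out study/
omicmr coloc --trait1 study/qtl.tsv --trait2 study/gwas.tsv
omicmr run-all --config run.yaml      # full multi-stage pipeline
```

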