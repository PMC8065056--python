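# Methods

This note records the statistical model behind each stage, the defaults
and why they hold, the numerical choices, and the known limits — in
particular where conventions in the field are not standardized and this
package had to fix one.

## Data model

Genotypes are carried as probability triples (p₀, p₁, p₂) per sample and
variant, the posterior probabilities of 0/1/2 copies of the effect allele
(GEN "allele B", VCF ALT). Coordinates are 1-based inclusive. Effect
estimates always refer to the effect allele; MAF is reported for the minor
allele, computed from expected dosages. A triple summing below 0.98 is
treated as a missing genotype: imputation engines emit deflated triples
for uncertain calls, and using them as-is biases expected dosages toward
zero. Well-formed triples must sum to 1 ± 10⁻³. "NA" is the missing token
in every text output. Dosage-only input (VCF DS) is expanded to the
minimal-variance triple consistent with the dosage — (1−d, d, 0) for
d ≤ 1, (0, 2−d, d−1) above — which preserves the expected dosage exactly
and adds no spurious certainty about homozygosity.

## Marker QC

Pre-association filters remove variants with missingness ≥ 0.05, exact
Hardy-Weinberg p ≤ 10⁻²⁰ over the whole cohort, or MAF < 0.001; the
combination step additionally requires info ≥ 0.7. The HWE test is the
exact conditional test (sum of probabilities of heterozygote counts no
more probable than the observed one, given the allele counts), computed by
the standard mode-anchored ratio recurrence; genotypes enter as hard calls
at probability ≥ 0.9, and samples without a confident call are left out of
the HWE table — expected dosages would smear the genotype distribution the
test conditions on. Post-association, records with control-HWE p < 10⁻⁶
are dropped for every model, and recessive/genotypic records additionally
require at least three hard-called effect-allele homozygote cases; with
fewer, those models' estimates rest on a handful of possibly mis-imputed
individuals and visibly inflate or deflate the genomic-control lambda.
The homozygote count is an integer criterion, so it is taken on hard
calls, not expected dosages.

The info score is the ratio of observed to expected dosage variance,
`1 − Σ(fᵢ − eᵢ²)/(2Nθ(1−θ))`, 1 exactly when every triple is one-hot and
by convention 1 when θ ∈ {0, 1}. Negative values (triples more dispersed
than a binomial at θ) are reported as-is and fail the 0.7 gate naturally.

## Panel combination

Variants are matched across panels on (chromosome, position, unordered
allele pair); panels are assumed strand-harmonized, which holds when one
cohort is imputed against several panels. Per variant the covering panel
with the highest info score supplies both genotypes and info; ties break
by a configured panel priority so output is deterministic. Genotypes are
never blended across panels. The union semantics mean combination can only
add variants relative to any single panel, and the per-variant info is the
maximum over panels. Imputation quality against held-out truth is the
allelic dosage R² (squared Pearson correlation of expected vs true
dosage), summarized per MAF bin with default edges 0.001, 0.005, 0.01,
0.05, 0.1, 0.2, 0.5 as the percentage of variants with R² ≥ 0.5 and
info ≥ 0.7.

## Association

Genotype uncertainty enters through expected encodings (the deterministic
"expected" method) rather than a full missing-data likelihood; for hard
calls the two coincide, and for imputed data the expected encoding is the
standard, reproducible choice. The IRLS fit uses tolerance 10⁻⁸ on the
coefficient step with at most 25 iterations; covariates are standardized
internally for conditioning (genotype effects are unchanged). Any genotype
|β| > 15 or non-convergence is reported as a failed fit with missing
statistics — a deterministic surrogate for quasi-complete separation —
rather than fabricated estimates; such records are excluded downstream.
The genotypic joint test is a 2-df likelihood-ratio test against the
covariate-only model (per-coefficient heterozygote/homozygote odds ratios
are reported separately); 1-df models use Wald tests, and OR confidence
intervals are exp(β ± 1.96·SE).

Only the non-pseudoautosomal X is analysed (hg19 PAR1 ≤ 2,699,520,
PAR2 ≥ 154,931,044; PAR variants are excluded with a warning). Under full
X inactivation a male's single-allele probability p(B) = p₁+p₂ maps to the
homozygote scale: additive 2·p(B), dominant/recessive p(B), heterodominant
0, genotypic [0, p(B)]. The sex-stratified X fit adds a sex main effect
(sex-specific baselines) with a shared genotype effect, which equals the
pooled fit when the strata are homogeneous and lies between the
sex-specific estimates otherwise; single-sex data fall back to the
unstratified fit with a warning. Control-HWE on X is computed in females
only, and hemizygous male carriers count as effect-allele homozygotes for
the case-count filter.

The dominance-deviation test augments the additive dosage with the
expected heterozygosity p₁ and Wald-tests that coefficient; expected
rather than hard-called heterozygosity keeps the test consistent with the
expected-dosage association machinery. It is undefined without
heterozygote carriers and is not applied to X loci (hemizygous males have
no heterozygote state).

## Loci and classification

Genome-wide significant variants (p < 5×10⁻⁸ under any model) are merged
transitively: a variant within 500 kb of any member joins the locus, so
loci on a chromosome end up pairwise more than 500 kb apart and the result
is independent of input order. The experiment-wide threshold divides the
genome-wide alpha by 2.5 effective tests (2×10⁻⁸ by default) — the five
encodings are strongly correlated, so a full 5-fold Bonferroni would be
badly conservative. Classification combines the significance pattern with
the deviation test at α = 0.05: additive-only significance is "additive";
mixed significance is non-additive only when the deviation test rejects;
non-additive-only significance without deviation support is
"undetermined" (the evidence cannot distinguish a true non-additive effect
from an additive one that only crossed the threshold under a correlated
encoding). The non-additive subtype is the model with the smallest p.

## Credible sets

The region is restricted to variants with LD r² > 0.1 to the lead
(computed from the supplied expected dosages; the lead is always kept),
ABFs are computed with prior variance W = 0.04 (a 95% prior OR range of
roughly 0.68–1.48, the conventional weakly-informative choice for
log-odds effects; exposed as a flag), posteriors are the normalized ABFs,
and the 99% set is the ABF-descending prefix ending at the first variant
whose cumulative posterior exceeds 0.99. ABF ties break by genomic
position. The construction assumes a single causal variant per region.

## Meta-analysis

IVW: weights 1/SE², pooled SE (Σw)^{−1/2}, two-sided Wald p. Sample-size
scheme: zᵢ = Φ⁻¹(1 − pᵢ/2)·signᵢ, weights √nᵢ, pooled
z = Σwz/√(Σw²); p = 0 inputs are rejected (unrepresentable z) with advice
to supply β/SE. Default n is the total study size; the effective size
4/(1/n_cases + 1/n_controls) is available via a flag since conventions
differ between tools. Heterogeneity: Q = Σw(β−β̂)², p from χ²_{k−1},
I² = max(0, (Q−df)/Q)·100. Effect alleles are harmonized before pooling;
swapped alleles flip the sign, incompatible allele pairs are dropped.

## Power and required sample size

"Population sample size" means the total cohort at the study's observed
case fraction φ; power is at two-sided α (default 5×10⁻⁸) and the target
is 80%. Required N is found by bisection and rounded up, so
power(N) ≥ target and power(N−1) < target.

*Recessive / dominant*: the variant is a binary exposure with population
frequency f = q² (recessive) or 1 − (1−q)² (dominant) under HWE. Controls
carry the population frequency (rare-disease approximation), cases the
frequency implied by applying the odds ratio to the exposure odds. Power
is the classical two-proportion normal deviate with unequal allocation:
pooled variance under the null, observed-proportion variance under the
alternative.

*Additive*: the per-allele odds ratio is treated as a multiplicative
genotype relative risk in a population whose disease prevalence equals the
case fraction — the convention of the classic genetic power calculators.
Baseline risk solves K = Σ f_g r_g, case/control allele frequencies follow
by Bayes' rule, and power comes from the 1-df allelic-test noncentrality
on 2N alleles with pooled variance. This model is undefined when the
implied top-genotype risk exceeds 1 (large OR at high case fraction); the
package raises rather than extrapolating.

A Monte-Carlo oracle simulates exposure/genotype counts from exactly these
population models and pushes each replicate through the association
engine's logistic fit. With the score statistic (the contrast the analytic
formulas track) it reproduces the analytic power to within 0.03 wherever
the expected number of exposed controls is a few dozen or more; below
that, discreteness makes the normal approximation conservative — simulated
power can sit up to ~0.1 *above* the analytic value, so analytic required
sample sizes err on the safe side. The engine's Wald test is itself
conservative at such counts and its simulated power falls somewhat below
the score test's.

Two caveats for anyone comparing against published sample-size figures.
First, field calculators (epiR-, GPC/GeneticsDesign-style) embed
non-equivalent conventions — allocation, continuity corrections,
risk-vs-odds scales, prevalence assumptions — that move required N by
tens of percent; figures for rare recessive designs computed elsewhere can
exceed this package's two-proportion values by 30–60%, a spread larger
than any of those documented options explains, so cross-tool agreement
should be checked with the simulation oracle rather than assumed. Second,
the additive risk-scale convention was chosen over an odds-scale logistic
population model because it is what the established calculators implement;
at high case fractions the two diverge substantially (the odds-scale model
would nearly double some additive requirements).

## Synthetic cohorts

The generator draws HWE hard-call genotypes at declared allele frequencies
(X males as 0/1 hemizygotes), then disease status from a population
logistic risk model on each variant's declared encoding, with the
intercept bisected so the expected case fraction hits its target —
population simulation plus risk, not retrospective sampling, so one
mechanism serves association, power and calibration checks. Covariates
default to age ~ U(40, 90), sex ~ Bernoulli(1/2), PCs ~ N(0, 1).
Imputation noise is Dirichlet around the true genotype with concentration
1 + κ on the truth and 0.5 elsewhere: κ = 0 is nearly uninformative,
κ → ∞ (capped at 10⁶) gives hard calls, and panel coverage predicates
(e.g. "no indels") reproduce panel-specific variant sets. Variants are
simulated independently: no LD, no population structure, no genotyping
batch effects. Tests passing on this substrate therefore validate the
statistical machinery — calibration, encodings, filters, combination
logic — not robustness to LD-induced confounding or structure, which real
cohorts must handle upstream (relatedness and PCA outlier removal are out
of scope here).

Default test problem sizes were chosen so the full suite exercises each
claim at meaningful resolution (e.g. 5,000 null variants at n = 2,000 for
type-I calibration; 20 replicates of a 57,000-sample cohort for the
recessive-detection property) while remaining a desk-scale run.

## Numerical notes

Log-likelihoods use the log1p-exp form; the IRLS intercept is warm-started
at the logit of the case fraction. The HWE recurrence anchors at the
approximate mode to avoid overflow. The genomic-inflation factor uses the
exact 1-df χ² median (0.4549364…), not a rounded constant. The λ of a set
of exactly-0.5 p-values is 1 by construction. Bisection caps at N = 10⁹
and reports unreachable targets as errors, as does a power request whose
risk-scale model is infeasible.
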