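# Methods

## The case-parent triad POE likelihood

The unit of analysis is a triad (M, F, C): mother, father and affected child
genotypes at one biallelic SNP, coded 0/1/2 as copies of allele a₂ (the PLINK
A2 column). The model has parameters

| parameter | meaning | default treatment |
|---|---|---|
| q | population frequency of a₂ | estimated (logit scale) |
| RRₘ | relative risk of one maternally transmitted a₂ | estimated (log scale) |
| RR_f | relative risk of one paternally transmitted a₂ | estimated (log scale) |
| RR\* (`rr_dd`) | double-dose deviation for a₂/a₂ children | estimated; `free_rr_dd=False` fixes it at 1 |
| RR⁽ᴹ⁾₁, RR⁽ᴹ⁾₂ (`mat1`, `mat2`) | maternal-genotype (mother's own) effects | off by default (`maternal_effects=True` enables) |

Assumptions: parental genotypes in Hardy–Weinberg proportions at q, random
mating, Mendelian transmission, disease risk multiplicative in the transmitted
alleles, ascertainment purely on the child's affection. Under ascertainment
the probability of observing a trio is its HWE × Mendelian × penetrance weight
divided by the same weight summed over all 15 Mendelian-consistent trio
configurations; the baseline risk B multiplies numerator and denominator alike
and is therefore not a parameter. Maternal-genotype effects are off by
default because joint estimation with the transmission RRs is fragile at the
tens-of-triads scale typical of this design; the capability exists because the
model family includes those terms.

Latent structure is marginalized, not imputed: the all-heterozygous trio
(1,1,1) is the one genuinely ambiguous biallelic configuration (maternal or
paternal origin of the child's a₂, prior weight ¼ each); a trio with exactly
one missing member is summed over the unobserved genotype; trios with two or
more missing members, or Mendelian inconsistency, are excluded from the
likelihood (and `n_triads_used` reports the count retained).

## Estimation and inference

The likelihood depends on the data only through the counts of distinct
observation patterns (at most 15 complete plus missing-member patterns), so
evaluation is O(patterns). The default optimizer is BFGS on the per-triad
mean log-likelihood over (logit q, log RRₘ, log RR_f, log RR\*), from three
starting points (null, maternal-skewed, paternal-skewed) to guard against
local optima; convergence is declared at gradient max-norm 1e-6 (or a
relative log-likelihood change below 1e-8 for EM), capped at 500 iterations.
An EM algorithm over the latent (genotype, transmission) completions is
provided (`method="em"`); its M-step keeps the ascertainment normalizer and is
solved numerically. A test requires both routes to reach the same maximum.

Standard errors come from the observed information (numerically differentiated
Hessian of the marginal likelihood at the MLE). The POE estimate is
RRₘ/RR_f with a 95% Wald interval on the log scale and a two-sided Wald
p-value for log(RRₘ/RR_f)=0; a likelihood-ratio variant (`p_poe_lrt`) refits
under RRₘ=RR_f. A singular information matrix (e.g. a monomorphic SNP) is
flagged and no CI is reported.

The Wald statistic was preferred as the default because the design's natural
report is a ratio with a CI; the LRT is an option, not the default.

## Stratified fits and interaction

Stratification uses the offspring's own covariate level (smoking yes/no,
drinking yes/no, BMI class at the 28 kg/m² obesity cut, or sex for the
sensitivity analysis). Each stratum gets an independent fit; the interaction
test for two strata is the Wald contrast
z = (θ̂_A − θ̂_B)/√(se_A² + se_B²) with θ = log(RRₘ/RR_f); for more than two
strata an inverse-variance-weighted heterogeneity chi-square with (k−1)
degrees of freedom is used. This contrast is the minimal statistic consistent
with reporting per-stratum ratios plus a single interaction p-value. A
full-homogeneity LRT (all parameters common vs stratum-specific,
df = (k−1)·p) is available via `lrt=True`. A stratum below the minimum
informative-triad count is reported unfit and the interaction is not computed.
Interaction p-values across SNPs pass through the same BH adjustment as the
main analysis.

## QC

Defaults: call rate ≥ 95% for samples and SNPs, founder heterozygosity within
3 SD of the founder mean, per-sample Mendelian error rate < 5%, MAF > 1%,
Hardy–Weinberg exact-test P > 1e-6, per-SNP Mendelian error rate < 10%.
Order: sample filters first (removing failing samples and every triad touching
them), then SNP statistics on the survivors. Design choices where standard
practice leaves latitude:

- **HWE on founders only.** Offspring genotypes are correlated with their
  parents', which inflates the test; only parents enter the genotype counts.
- **Mendel-error attribution.** A trio's inconsistency at a SNP is counted
  against the offspring's per-sample rate; parents fail only on their own
  statistics. Any attribution convention is defensible; this one keeps the
  planted-violation bookkeeping deterministic.
- **Post-detection masking.** At surviving SNPs, the genotypes of an
  inconsistent trio are set to missing (all three members), the standard
  practice when single-genotype blame cannot be assigned.

The HWE exact test conditions on the observed allele counts and sums the
probabilities of all same-parity heterozygote counts whose conditional
probability does not exceed the observed one (computed via log-gamma; an
exact rational-arithmetic enumeration oracle verifies it to 1e-12 for all
count triples with total ≤ 50).

## Multiple testing

`bh_adjust` is the Benjamini–Hochberg step-up procedure (backed by
statsmodels), capping adjusted values at 1 — uncapped intermediate values can
exceed 1 at small m and the pre-cap maximum is logged for transparency.
Missing p-values are excluded from the family size and returned missing. By
default adjustment runs over all tested SNPs; any subset can be passed to
adjust within a restricted family.

## Annotation

Gene assignment uses 1-based closed intervals (NCBI convention), zero flank by
default with a configurable pad; a SNP maps to every overlapping region. The
bundled `pip2_genes.tsv` lists the 27 PIP2-hydrolysis-pathway genes (DAG
kinases, DAG lipases, MGLL, IP3 receptors, PKC isoforms, RASGRPs) with
approximate GRCh38 spans for orientation — users should supply an exact
coordinate table for production work. mQTL intersection is exact rsID string
matching, order-preserving, with deduplication. The methylation β-value is
max(M,0)/(max(M,0)+max(U,0)+100), which clamps negative probe intensities and
is bounded in [0,1) because the denominator is at least 100.
`compare_beta_groups` is an exploratory Welch t-test utility, not a
calibrated analysis.

## The synthetic-data generator

`simulate_triads` emulates exactly the statistical structure the estimator
assumes: HWE parents, Mendelian transmission, multiplicative
parent-of-origin penetrance with explicit baseline `baseline_b` (default
0.05, a lifetime-risk scale), and ascertainment by rejection sampling
(retain a trio only if the child is drawn affected; bounded at 10⁷
proposals). Defaults: q = 0.3 (a common-variant frequency), 200 triads,
no corruption. Covariate prevalences are smoking 30%, drinking 30%, and BMI
drawn N(25.5, 3.5²) (≈ 35% obese at the ≥ 28 cut) — plausible for an
ascertained Chinese T2D-family setting; under stratified generation the
stratum variable is set from the stratum label instead (BMI drawn within the
class). With several SNPs, one causal SNP drives ascertainment and the rest
are null — a null SNP's distribution is provably unaffected by conditioning
on affection, so this is exact, and it avoids specifying a joint multi-locus
disease model. Simulated SNPs are unlinked; the generator does not emulate
LD, population stratification, genotyping batch effects, or quantitative
phenotypes — passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to those violations.

Mendelian-error injection flips one member of a chosen trio to a value that
creates a genuine inconsistency; trios where no single flip can do so (e.g.
both parents heterozygous) are skipped and the truth record logs actual
injections. Missingness is element-wise uniform. All randomness flows
through one seeded generator; identical seeds give identical outputs.

Fixtures (`make_fixture`): `clean_null`, `strong_maternal`/`strong_paternal`
(RR ratio 4), `bmi_interaction` (ratio 36 in the ≥28 stratum vs 2 in the <28
stratum, 500 triads per stratum — sized so the interaction contrast has high
power at fixture scale), and `qc_violations` (one planted violation per
filter, with the plant list in the truth record).

## Validation scale and numerical choices

The Monte-Carlo studies run at: oracle equivalence on 200 triads (refining
exhaustive grid search to 1e-3 resolution; enumeration agreement to 1e-10);
normalization over 100 random parameter draws (1e-12); recovery over
ratio ∈ {0.25, 1, 4} × q ∈ {0.1, 0.3} with 2000 triads × 200 replicates
(bias < 0.1 on the log scale, pooled CI coverage 93–97%); type-I error over
1000 replicates at 2000 triads (1000/stratum for the interaction) with
acceptance band 3–7% at α = 5%. These sizes give Monte-Carlo standard errors
well inside the asserted bands while keeping a full run in minutes on one
CPU.

## Known limitations

- Biallelic SNPs only; the k-allele generalization and haplotype-level POE
  are out of scope, as are X-linked models and hybrid designs using parental
  affection status.
- The likelihood assumes HWE and random mating in the parental generation;
  unlike mating-type-stratified log-linear variants it is not robust to HWE
  violations (the QC HWE filter is the guard).
- Wald inference is first-order; at very small triad counts (tens) CIs can be
  optimistic and the ratio estimate noisy — the profile-likelihood CI is not
  implemented.
- Gene coordinates in the bundled table are approximate spans, not exact
  transcript boundaries.
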