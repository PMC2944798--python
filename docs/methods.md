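# Methods

This note records the statistical model behind `hapint`, the estimators and
their numerical details, the simulation designs used for validation, and
the design decisions taken where more than one reasonable choice existed.

## Model and interaction measure

Two biallelic loci G (alleles G1/G2) and H (H1/H2) define four
(pseudo)haplotypes G1H1, G1H2, G2H1, G2H2 with population frequencies
p = (p11, p12, p21, p22). "Pseudohaplotype" covers the unlinked case: the
joint frequency of the alleles residing on the same parental gamete is
defined, and estimable, whether or not the loci are syntenic.

Multiplicative interaction on the odds scale is measured through the
cross-ratio CR(p) = p11·p22/(p12·p21). The interaction measure is

    I_GH = ln CR(p_case) − ln CR(p_control),

zero iff the two cross-ratios coincide. Two structural properties anchor
the tests and are asserted in the suite:

- **Marker property.** If one locus carries no disease association (the
  per-haplotype risk factor depends only on the other locus's allele), the
  case and control cross-ratios both equal the population cross-ratio and
  I_GH = 0, regardless of LD between the loci.
- **Symmetries.** I_GH is invariant under swapping the two loci and changes
  sign (preserving the test statistic) under relabeling the alleles at one
  locus.

## EM estimation of pseudohaplotype frequencies

From unphased dosage data each genotype combination except the double
heterozygote contributes phase-known haplotype counts. A double
heterozygote is cis (G1H1, G2H2) with posterior probability
φ = p11·p22/(p11·p22 + p12·p21), trans otherwise; the EM iteration
alternates this E-step with the haplotype-count M-step.

Numerical choices:

- initialization at linkage equilibrium (product of observed allele
  frequencies), which is deterministic and cannot stall on the
  p11·p22 = p12·p21 = 0 boundary;
- convergence when the largest frequency change drops below 1e-10, cap at
  1,000 iterations (convergence flag reported);
- φ = 0.5 when both phase products vanish (symmetric tie);
- frequencies below 1e-12 are truncated to exact zeros;
- missing genotypes: pairwise complete-case deletion per SNP pair.

The observed-data log-likelihood is non-decreasing across iterations, the
M-step preserves the directly counted allele frequencies exactly, and when
no double heterozygotes are present the estimate equals closed-form
haplotype counting. The estimator is validated against an EM-independent
coarse-to-fine grid search of the likelihood surface (final resolution
5·10⁻⁴, agreement within 2·10⁻³) on random small tables.

## Variance of the measure and the T_IH test

The statistic is T = Î² / Var(Î) referred to χ²(1). Each group's log
cross-ratio variance is obtained by the delta method through the expected
Fisher information of the **observed unphased-genotype likelihood**: with
genotype cell probabilities π_c(θ) quadratic in the haplotype frequencies
(random union of gametes) and θ the three free frequencies,

    J = n · Σ_c (∂π_c/∂θ)(∂π_c/∂θ)ᵀ / π_c,
    Var(ln CR) = gᵀ J⁻¹ g,   g = ∂ ln CR / ∂θ,

evaluated at the EM estimate. This matters: the naive phase-known form
(1/2n)·Σ 1/p̂ — correct when haplotypes are directly observed — understates
the variance of EM estimates because double heterozygotes are uninformative
precisely in the cross-ratio direction. At common allele frequencies the
understatement is about a factor of two; using the phase-known form
inflates type I error from 0.05 to ≈0.16 at n = 1,000 per group. The
phase-known variant is retained as `interaction_variance(...,
phase_known=True)` for phased data and for the exact correspondence with
the Woolf comparator (below). Both forms are validated against Monte-Carlo
variance estimates (within 10%).

**Continuity correction.** If any EM frequency is below 1e-8, 0.5 is added
to each of the four expected haplotype counts of that group and the
frequencies renormalized (Haldane–Anscombe style), flagged in the result.
Without it the 1/p terms diverge.

**Case-only variant.** For unlinked loci in population-level linkage
equilibrium, the control cross-ratio is 1 by assumption and the case term
alone is used. The suite verifies exact calibration at D = 0 and the
algebraic decomposition of the case-control measure.

**p-values** are upper-tail χ²(1), clamped below at the smallest positive
float.

## Comparator tests

- **Allele-based ("fast-epistasis").** Per group, a 2×2 allele-pair table:
  phase-known haplotypes counted directly, each double heterozygote's two
  haplotypes split 0.5/0.5 between the phase resolutions; the statistic
  contrasts the group log odds-ratios with Woolf SEs (Σ 1/cell). Zero
  cells receive the 0.5 table-wide correction. On data with no double
  heterozygotes it coincides exactly with T_IH computed under the
  phase-known variance. Calibration finding: the deterministic phase split
  shrinks both odds-ratios toward 1, so at linkage equilibrium the test is
  markedly conservative (null rate ≈0.007 at nominal 0.05), and under LD
  with marginal effects it is anticonservative — both behaviors are
  documented limitations of this classical construction, not defects of
  the implementation, and are covered by tests.
- **Logistic regression.** logit P(case) = b0 + b1·G + b2·H + b3·G·H on
  genotypes coded recessive (0,0,1), dominant (0,1,1) or additive (0,1,2);
  1-df Wald test for b3 (likelihood-ratio behind a flag). Fit as a
  binomial GLM on the nine genotype patterns, which has the identical
  likelihood to the individual-level fit and is far faster inside
  simulation loops; an independent Newton–Raphson fit verifies coefficients
  and Wald statistics to 1e-6. Separation and rank deficiency yield
  non-evaluable results with reasons.

## Simulation designs

**Populations.** A population is (p_G1, p_H1, D); haplotype frequencies are
(p_G1·p_H1 + D, …) with D validated against the Fréchet bounds, and
individuals are random unions of two independent haplotype draws.

**Null calibration** uses a finite-population design: one general
population of 100,000 individuals is generated, and each of 10,000
replicates samples n "cases" and n "controls" from it without replacement
(implemented exactly as multivariate hypergeometric draws on the 9-cell
genotype table). No phenotype model is involved, so the null holds by
construction. Two default scenarios are exposed (both configurable):
scenario 1 with p_G1 = p_H1 = 0.5, D = 0.1 and scenario 2 with
p_G1 = p_H1 = 0.3, D = 0.05 — common alleles with LD in two frequency
settings. Empirical rejection rates match nominal levels 0.05/0.01/0.001
within 3 Monte-Carlo SEs for n between 300 and 1,000 per group, and the
null statistics pass a Kolmogorov–Smirnov test against χ²(1).

**Disease models.** Penetrance over the 3×3 joint genotypes follows a
multiplicative-odds parameterization

    odds(i, j) = δ · λ1^x(i) · λ2^y(j) · λ3^(x(i)·y(j)),
    f(i, j) = odds/(1 + odds),

with x, y the mode-specific scores (recessive/dominant/additive), λ1, λ2
marginal genotype odds ratios, λ3 the interaction odds ratio, and δ > 0
solved by bisection (tolerance 1e-12) so the population prevalence equals
f0. λ1 = λ2 = λ3 = 1 gives all penetrances equal to f0.

**Ascertainment** draws individuals from the population and assigns case
status with probability f(i, j) until both groups are filled (rejection
sampling; the internal batch path samples the equivalent conditional
multinomials directly). `estimate_power` applies one named test per
replicate; `compare_power` applies several tests to the same replicates so
power differences carry no between-stream noise.

**Power study conditions.** Defaults, chosen once per model family and
frozen (units: allele frequency / odds ratios; f0 = 0.1 throughout):

| family | p_G1 = p_H1 | D | λ1 = λ2 | n per group |
|---|---|---|---|---|
| dominant × dominant | 0.5 | 0.05 | 2 | 1,000 |
| recessive × recessive | 0.6 | 0.1 | 2 | 2,000 |
| additive × additive | 0.5 | 0.05 | 1.5 | 1,000 |

The linked-loci setting is deliberate: with the matched genotype coding the
logistic model is correctly specified under this penetrance family, so the
haplotype statistic's power advantage arises where LD couples the marginal
effects into the haplotype cross-ratio. λ3 grids default to
{1, 1.5, 2, 2.5, 3, 4}; validation suites use {1, 2, 3, 4} at 2,000
replicates per point, which keeps each curve under a minute while leaving
2·MC-SE comparisons meaningful.

## Scan pipeline

- **QC** removes SNPs with missingness > 5%, MAF < 1%, HWE p < 1e-4
  (1-df χ² on all genotyped individuals by default; controls-only and
  exact-test options behind flags) or duplicated ids, logging one reason
  per removal (precedence duplicate > missing > maf > hwe).
- **Canonical pair keys.** SNPs are ordered by (chromosome, position, id);
  each unordered pair is emitted once in that orientation, making scan
  output invariant to input column order and to chunk size.
- **Storage threshold.** Only results with p ≤ `store_threshold` (default
  1e-4) are emitted; the total number of tested pairs is carried in scan
  metadata. Because the stored p-values are the smallest of the family,
  their family-wide BH ranks are unchanged, so `bh_fdr(p, m=total)`
  computes correct q-values over the full family — never use the stored
  count as the BH denominator.
- **Replication.** Two modes: FDR intersection (pairs with q below a cut in
  both datasets) and two-stage Bonferroni (discovery at α/m1 over all
  dataset-1 pairs, confirmation of the selected pairs at α/#selected in
  dataset 2).
- **QQ points** are expected vs observed −log10 p with expected quantiles
  rank/(m+1), optionally truncated at the storage threshold's −log10.

Readers for PLINK text and binary filesets are implemented directly (the
.bed decoder unpacks the two-bit SNP-major codes with numpy); dosages count
copies of allele_1, positions are 1-based, and phenotypes follow the PLINK
2/1/0/−9 convention. For `.ped` input, which carries no allele columns,
allele_1 is the minor allele with a lexicographic tie-break.

## What the synthetic data does and does not show

The generator produces idealized panels: two-locus Hardy–Weinberg
populations with exact haplotype-level sampling, independent null SNPs, no
genotyping error, no population structure or relatedness, and no
genome-like LD beyond the simulated pair. Passing calibration and power
suites therefore demonstrates the statistic's sampling properties under its
own assumptions — not robustness to stratification, differential
missingness, or LD between a tested pair and untyped causal variants. The
planted-interaction scan shows end-to-end recovery in a clean panel, not
performance on real GWAS data.

## Known limitations

- The delta-method variance plugs the EM estimate into the *expected*
  information under HWE; strong HWE violations in cases (expected under
  ascertainment with large effects) are not modeled, though calibration
  held in all simulated settings tested.
- The fast-epistasis comparator's miscalibration (conservative at D = 0,
  anticonservative under LD) makes raw power comparisons against it
  meaningless at points where its null is inflated; comparisons should be
  read jointly with its λ3 = 1 rejection rate.
- Under the additive×additive penetrance family the induced haplotype
  cross-ratio difference is non-monotone in λ3: T_IH power peaks and then
  declines beyond λ3 ≈ 3 in the default conditions. The monotonicity
  property is asserted for the dominant and recessive families and for the
  additive family only up to λ3 = 3.
- The case-only test assumes population-level independence of the loci and
  is anticonservative for linked pairs by design.
- Only biallelic loci, two-locus interactions, and covariate-free models
  are supported.
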