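# Methods

## Genetic model

Two loci on different chromosomes carry `K` causal SNPs each. Locus `i`
drives a latent quantitative intermediate

    Z_i = Σ_{k=1..K} G_ik β_ik,

where `G_ik` is the causal genotype standardized to mean 0 / variance 1
on the analysis cohort, and the effects `β_i` are i.i.d. draws from
either a standard normal or a left-truncated standard normal (truncation
at 0, i.e. half-normal with mean √(2/π) ≈ 0.798). The outcome is

    Y = θ₁Z₁ + θ₂Z₂ + θ₁₂ Z₁Z₂ + ε,   ε ~ N(0, σ²).

Defaults θ₁ = θ₂ = 0, θ₁₂ = 1 give a pure-interaction architecture; the
main effects of the latents do not affect the 1-df interaction test, and
with either latent symmetric about zero `Y` is marginally uncorrelated
with each latent. σ² is solved **per replicate** from the empirical
variance of the product term so the interaction explains exactly the
target fraction `v` of `var(Y)`:

    σ² = θ₁₂² · var(Z₁Z₂) / v − var(genetic part).

Using the empirical product variance (rather than a theoretical formula)
keeps the scaling exact under arbitrary `K`, LD and allele frequencies;
solving per replicate rather than once per scenario makes each
replicate's realized `v` comparable. An optional variant gives every
causal SNP an additional main effect of magnitude θ₁₂ (the scenario used
with the two-step marginal prescreen). The half-normal reading of
"left-truncated normal with mean 0 and variance 1" refers to the
*parent* distribution; this is what makes locus effects directionally
consistent so the ancestry signal does not cancel.

Causal SNPs are selected within an ancestry segment subject to cohort
MAF > 0.10 and |corr(genotype dosage, ancestry dosage)| above a
differentiation threshold (0.1 / 0.2 / 0.5 for low / moderate / high
differentiation). The coded allele is oriented to the allele that is
minor in the designated population (population 2, the majority ancestry,
by default — the reference only says "one of the populations"), so that
half-normal effects act in one direction there.

## Admixture simulation

Founder haplotypes for the two ancestral populations come from a
Balding–Nichols model: each SNP has an ancestral frequency `p` uniform
on (0.1, 0.9) and per-population frequencies drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, so differentiation is a single parameter
`F` (the quantity the interaction power actually depends on). Draws
outside (0.01, 0.99) are resampled to avoid monomorphic sites. Sites are
independent by default; an optional template-mosaic scheme (each
haplotype copies one of `T` per-population templates per block of SNPs)
induces within-block LD so that non-causal tag SNPs exist.

Admixed haplotypes are random walks over the founder panel: crossover
breakpoints are placed with exponential inter-arrival distances at the
per-base-pair recombination probability (10⁻⁸ by default) —
mathematically equivalent to per-base Bernoulli trials at this rate and
vastly faster — and at each crossover a new founder is drawn with
replacement, population 1 with probability 0.2 and population 2 with
probability 0.8 (African-American-like proportions). Re-drawing a
founder of the same population causes no ancestry switch, so only ~32%
of crossovers switch ancestry. Two haplotypes form an unphased
individual; genotype dosage is the haplotype sum.

Local ancestry is summarized over equal-width segments as a 0/1/2 dosage
counting chromosomes whose **majority** ancestry in the segment is the
reference population (ties broken by the ancestry at the segment
midpoint; the summarization rule for sub-segment switches is the
package's choice). The two interacting loci live on two independently
simulated chromosomes: on a single 50-Mb chromosome with ~0.5 crossovers
per haplotype, nearby segments' ancestries would be nearly collinear.

Ancestry-inference error is emulated rather than inferred: each
per-haplotype ancestry indicator is flipped independently with a
misclassification probability calibrated by root search so the expected
squared correlation between true and degraded dosages hits a target r²
(published accuracies: ≥0.99 for African Americans, 0.63–0.81 for
Mexican and Puerto Rican cohorts). The calibration uses the closed-form
attenuation of the empirical label moments; realized r² lands within
±0.01 of the target on matrices of a few 10⁴ entries.

## Interaction tests

All three tests are OLS fits of `y ~ 1 + a + b + a·b` with the Wald
statistic `(β̂/se)²` of the product coefficient referred to χ²(1). The
χ² reference (not t) is used because the power theory is χ²-based and at
study-scale N the difference is negligible. Product terms are formed
from the predictors as supplied — standardized genotypes for SNP tests,
raw 0/1/2 dosages for ancestry tests — without re-centering; the Wald
statistic of the product coefficient is invariant to predictor centering
(a property the test suite checks), so this choice affects only
reported coefficients, not inference. Rank-deficient designs raise an
error naming the collinear column; pair scans record such pairs as
flagged rows instead of aborting.

For multi-causal loci the GWAS test uses the **best combined tag**: the
candidate SNP maximizing |Σ_k β_ik ρ_jk| over the K causal variants,
with correlations computed on standardized genotypes and causals in
their coded orientation. The absolute value is taken because a tag's own
allele coding is arbitrary (flipping the tag flips the score's sign and
leaves the Wald statistic unchanged); signed summation across causals is
retained, so opposing effects can cancel — the same mechanism that
nulls ρ_ZL under symmetric effect distributions. Ties break to the
lowest SNP index.

The tagging correlations ρ_GC = ρ(G₁G₂, G₁*G₂*) and
ρ_LC = ρ(G₁G₂, L₁L₂) attenuate the interaction NCP. One subtlety: the
raw Pearson correlation of uncentered ancestry products understates what
the regression (which adjusts both main effects) achieves, because
ancestry dosages have mean ≈ 1.6; diagnostics of effective tagging
should center the dosages first, or use the mean Wald statistic
directly.

The two-step prescreen fits the marginal model `y ~ 1 + x` per
predictor (t-test p-values), keeps predictors with p below a threshold
`t` (0.01 by default), and budgets step-2 multiplicity with the
approximation C(n·t, 2) valid when almost all predictors are null.

## Power machinery

Under the alternative the Wald statistic is non-central χ²(1) with
NCP = N·v·ρ²_tag (v = ρ²(Y, G₁×G₂); ρ²_tag = 1 for sequence data). Power
at corrected level α is the upper-tail non-central mass beyond the
central 1−α quantile, computed with scipy's `ncx2`; the required NCP is
obtained by bracketed Brent inversion to relative tolerance 10⁻⁸ (the
tolerance is the package's choice), cross-checked in the test suite
against a 10⁷-draw Monte-Carlo simulation of (Z+√λ)². Bonferroni
corrections use exact pair counts C(m, 2); presets cover 2×10⁷ sequence
variants, 10⁶ genotyped / 10⁷ imputed SNPs, and 10³ ancestry segments.
The break-even tagging correlation between designs a and b is
√(λ_a/λ_b) of their required NCPs — the point where design a's smaller
correction exactly offsets its imperfect tagging. Cost-adjusted designs
multiply N by a fold factor (6–10× for AIM genotyping vs a GWAS array).
The finite-sample Wald statistic exceeds N·v by a factor ≈ 1/(1−v·ρ²),
negligible at v = 1% but visible in high-v diagnostics.

The smallest detectable `v` at a given N is exposed as a computation
(`detectable_variance`); published claims of that form depend on
unstated tagging assumptions and are not asserted anywhere.

## Replicate study design

The empirical study fixes the genetic and ancestry data and redraws
causal sets, effects and outcomes across replicates. Desk-scale defaults
(all configurable): two 50-Mb locus chromosomes with 1,000 SNPs over 4
segments each; founder panels with F = 0.25, 100 haplotypes per
population, 4 LD templates per population in blocks of 25 SNPs; N = 2,000
base individuals (12,000 simulated to serve the 6-fold arm); v = 0.10;
K ∈ {1, 5}; thresholds {0.1, 0.5}; 500 replicates; S_G judged at
0.05/C(10⁷,2) ≈ 10⁻¹⁵ and S_L at 0.05/C(10³,2) ≈ 10⁻⁷. The elevated v
and reduced panel compensate for the desk-scale N so both tests' powers
are measurable at genome-wide thresholds; these are the package's own
scaled-down study conditions, chosen from the NCP calculus before any
empirical tuning. Causal sets default to a contiguous run of eligible
SNPs ("adjacent" layout), reflecting co-localized regulatory variants;
a "random" layout is available. Within-locus LD matters here: without
any LD the best tag of a multi-SNP latent is essentially its strongest
causal, which understates the tagging achievable with a dense panel and
flips the S_G/S_L ordering at high differentiation.

All randomness flows from one master seed through named substreams
(stage × locus × replicate), so stages re-run independently and results
are bit-reproducible; identical configs produce byte-identical TSVs.

## What the synthetic data does and does not emulate

The generator reproduces the features the method's power actually
depends on: causal-SNP differentiation, admixture-LD between genotype
and segment ancestry, within-locus tag LD (coarsely, via block mosaics),
the latent interaction architecture, and ancestry-inference error at a
chosen accuracy. It does not emulate realistic human LD maps or
recombination hotspots, allele-frequency spectra, three-way admixture,
phasing or imputation error, or real ancestry-inference software, and
segment boundaries are equal-width rather than inferred. Passing tests
therefore validate the statistical machinery and the direction and
rough magnitude of the design trade-offs, not quantitative power
predictions for any specific real cohort.

## Numerical choices and degenerate inputs

Beta draws outside (0.01, 0.99) are resampled; monomorphic causals,
constant predictors, zero-variance products and constant ancestry raise
errors naming the offending input; infeasible scenario cells (too few
eligible causals) are reported as flagged rows. Exponential crossover
distances are rounded up to integer base pairs; zero-length intervals
cannot arise, and adjacent same-ancestry intervals are merged so tracks
are canonical. The degradation search brackets the flip probability in
(0, 0.5). p-values below the floating-point underflow of the χ² tail
report as 0, which only strengthens significance calls.

## Known limitations

Equal-width segments stand in for recombination-defined ancestry blocks;
the founder model has no demographic depth (no drift since admixture, no
population growth); template-mosaic LD has a block structure rather than
a decaying correlation profile; only quantitative traits and two-way
admixture are supported; and the best-tag search is restricted to the
causal segment rather than genome-wide.
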