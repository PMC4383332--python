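# Methods

`wildqtl` implements a complete analysis of the genetic architecture of
gene expression for small RNA-seq cohorts in which individuals may be
related — the situation of wild study populations genotyped directly from
RNA-seq reads.  This note documents the models, the synthetic-data
generator that stands in for real cohorts, the numerical choices, and the
known limitations.

## Expression preprocessing

Gene-level read counts are filtered to genes with non-zero counts in
strictly more than 10% of individuals and mean count ≥ 10 (an exclusion
list handles single dominating transcripts such as hemoglobin genes in
blood).  Normalization is a double quantile normalization: (1) each
sample's log counts are mapped onto the mean empirical distribution across
samples; (2) each gene is mapped onto standard-normal quantiles by the
rank-inverse-normal transform with the Blom offset, (rank − 3/8)/(n + 1/4).
Ties receive average ranks; because step 1 reuses reference values, exact
ties do occur and the per-gene output is standard normal only up to a
~10⁻²-scale perturbation.  The per-gene step removes *any* gene-level
distortion shared across samples — library depth, gene length, and GC
amplification bias — which is why the GC-bias diagnostic (correlation of
gene GC content with expression level) collapses after normalization.
Hidden structure (batches, environment, ancestry-driven trans effects) is
removed by regressing each gene on the top k = 10 expression principal
components.  On small synthetic panels (hundreds of genes rather than the
~10⁴ of a real dataset) the estimated PCs absorb an appreciable share of
true cis signal; this is a small-panel estimation artifact users of
synthetic fixtures should expect, not a property of the method at scale.

## Variant filtering and genotype handling

Six per-site filters, each evaluated on the raw matrix so their order is
irrelevant: monomorphic sites; missingness in strictly more than 12/63 ≈
19% of individuals (stored as the fraction so it generalizes across n);
Hardy–Weinberg violation; quality score below 100; distance greater than
200 kb from every gene (inclusive boundary at exactly 200,000 bp); and mean
depth below 5×.  The HWE test is the exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed, given
allele counts), two-sided by default with p < 0.05 removal — a deliberate
choice where the underlying procedure is conventionally left unstated; the
main purpose is removing ASE-induced heterozygote deficits, and a one-sided
variant is a one-line change.  Remaining missing genotypes (a small
fraction, by design ~1%) are imputed by sampling from Hardy–Weinberg
genotype probabilities at the observed allele frequency — a deliberately
naive, seeded imputer standing where a phasing-based imputer would be used
on real data.

LD is summarized by frequency-matched r² curves: SNP pairs within 100 kb
whose MAFs fall in the same decile band ((10–20], (20–30], (30–40],
(40–50]%), r² being the squared Pearson correlation of dosages.  A
coverage-by-genotype-class diagnostic reports per-site mean depth for
hom-ref/het/hom-alt and a two-sample KS test of the two homozygote depth
distributions, the signature of reference-mapping bias.

## eQTL mapping

Per (gene, SNP) the linear mixed model

    y = μ + xβ + u + ε,  u ~ MVN(0, σ²ᵤK),  ε ~ MVN(0, σ²ₑI),

with K = XXᵀ/p computed from the column-centered genome-wide dosage matrix
(centering is required for K to measure relatedness; a variance-standardized
variant is available and is the version whose off-diagonal estimates twice
the kinship coefficient).  K is eigendecomposed once per dataset; in the
rotated basis the covariance is diagonal and the likelihood profiles to a
1-D problem in λ = σ²ᵤ/σ²ₑ.  λ is maximized per (gene, SNP) over
log₁₀ λ ∈ [−5, 5] — on a 40-point grid in the vectorized scan used for
mapping, by bounded Brent search in the scalar interface.  The Wald
statistic β̂/se(β̂) is referred to t(n−2); the se uses the df-corrected
residual variance RSS/(n−2) so the K = I path coincides exactly with the
OLS t-test and null p-values are calibrated.  Per gene the lowest-p SNP is
retained (ties broken by distance to the gene, then index).

Significance is an empirical FDR: expression labels are permuted (10 full
permutations by default — permutation destroys both signal and the
genotype–kinship pairing), per-gene minimum p-values recomputed, and for
each threshold t, FDR(t) = (mean permuted count ≤ t)/(observed count ≤ t);
q-values are the running minimum over larger thresholds, capped at 1.
An optional local-structure control residualizes each gene on the top two
genotype PCs of its own chromosome before mapping, the standard check that
cis-linked ancestry structure, not proximal regulatory variation, drives
detections.

## Allele-specific expression

At exonic SNPs passing quality > 10, more than five reads in more than two
heterozygotes, and more than 300 reads total across heterozygotes (a
configuration flag switches the last rule to ≥ 300, both readings of the
conventional phrasing), alternate-haplotype read counts are modeled as
beta-binomial: x⁺|y ~ Binomial(y, θ), θ ~ Beta(α, β).  The LRT compares
the balanced null α = β (1-D maximization in log α over [−6, 14]) against
free (α, β) (L-BFGS-B with analytic digamma gradients in log parameters,
method-of-moments start, null-point fallback so the LRT is never negative).
The nominal p uses χ²(1); it is anti-conservative under overdispersion, so
gene-level decisions use an empirical null built by replacing each
heterozygote's x⁺ with a draw from a different site with the identical
total read count (falling back to ±5% depth tolerance with fraction
rescaling when no exact donor exists), re-fitting everything, and applying
the same empirical-FDR machinery to per-gene minimum p-values (20 null
replicates by default).

Two reporting conventions are definitional choices: the ASE effect is
logit(α̂/(α̂+β̂)) with the + haplotype carrying the site's alternate allele
(sign-comparable with eQTL β), and z = sign(mean fraction − 0.5)·√LRT.
One boundary property is worth knowing: for all-or-nothing data (every
read from one haplotype) the *exact* ML null collapses to the α → 0
bimodal solution, capping the LRT at 2n·log 2; consistent but partial
imbalance (e.g. 75/25 in every individual) is far more significant than
total silencing at the same depth.

## Power simulations

Following the canonical design: 10% of genes receive one causal cis-SNP
drawn uniformly from their tested window; expression is the causal effect
plus standard-normal residuals (no count layer, no polygenic term); the
full mapping + empirical-FDR pipeline runs; power is the fraction of
planted genes recovered at 10% FDR.  Effects are parameterized either as a
constant β ∈ {0.25, …, 2.5} or as PVE ∈ {5%, …, 50%} with
|β| = √(PVE/((1−PVE)·var x)), sign random.  Scenario switches: masking the
causal SNP (detection must go through LD proxies), and thinning per-gene
SNP counts to a target distribution by quantile matching (rank-preserving;
thinning a ~45 SNPs/gene panel to a ~20 SNPs/gene target reproduces the
density contrast between a baboon-like and a human-like panel, and
"thin to own distribution" is an exact identity).  The winner's-curse
analysis fixes |β| = 0.75 with masked causals and correlates estimated
|β̂| with MAF among detections only: at n = 63 the selection threshold
bites hardest at low MAF, producing r strongly negative although the truth
is constant; at thousands of individuals power saturates and r ≈ 0.

## Cis/trans variance partitioning

Per gene, the sparse Bayesian linear mixed model

    y = μ + X_cis β_cis + u + ε,
    β_cis,j ~ π N(0, σ²ₐ) + (1−π) δ₀,  u ~ MVN(0, σ²_b K),

where the polygenic term represents the ~p genome-wide trans effects
through their kernel K (with a switch to build K from other-chromosome
SNPs only).  Sampling is Metropolis-within-Gibbs in the eigenbasis of K,
where the marginal covariance of u + ε is diagonal: conjugate updates for
the intercept, spike-slab indicators and effects (per-coordinate Gibbs with
residual updating), σ²ₐ (inverse-gamma, prior IG(2, 0.25)), σ²ₑ (Jeffreys),
and π (Beta posterior under a log-uniform-motivated 1/π prior, truncated to
[1/p, 1]); a random-walk Metropolis step on log λ (λ = σ²_b/σ²ₑ, step 0.7,
uniform prior on log₁₀ λ ∈ [−5, 5]); and an exact conditional draw of u
for the variance bookkeeping.  Defaults are 1000 burn-in and 10,000
sampling steps with thinning 10; per recorded draw, pve_cis =
var(X_cis β)/var(y), pve_trans = var(u)/var(y), pve_total uses their sum.
Posterior medians and 95% intervals are reported, with the λ-acceptance
rate as a convergence heuristic.  The conjugate special case (π ≈ 1, one
SNP, no trans term, fixed variances) is checked against the closed-form
Bayesian regression posterior.

Covariate PVE uses the single-covariate LMM: pve = var(x·β̂)/var(y), with
β̂ the ML estimate under the kinship random effect; cohort-level
significance compares the distribution of per-gene PVEs against a
permuted-covariate reference (labels of the covariate permuted, one
permutation per gene by default) with a two-sample KS test on PVEs binned
at width 0.01.

## Reporting

Cross-method agreement: hypergeometric upper-tail p for the overlap of
eQTL- and ASE-significant gene sets; Pearson correlation of effect sizes on
jointly tested genes.  Positional enrichment maps every SNP to a
strand-polarized relative coordinate — signed flank distance outside the
gene, or one of 20 equal half-open bins across [TSS, TES) inside it (the
TSS falls in bin 1) — and compares eQTL SNPs against the tested background
by per-bin enrichment ratios and a two-sample KS test.  The ASE distance
profile bins within-gene site pairs by distance (default bin maxima 10²,
10³, 10⁴, 10⁵, 10⁶ bp, each bin reaching from the previous maximum) and
reports the mean |Δ|z||.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
all draws derive from one integer seed through a spawning seed sequence,
so identical configurations are bit-for-bit reproducible.

**Genotypes.**  Each chromosome carries a pool of founder haplotypes
(default 66) whose alleles come from a latent Gaussian AR(1) thresholded at
the allele frequency, with inter-site correlation exp(−d/L); L defaults to
20 kb for the baboon-like preset and 5 kb for the YRI-like preset.  Every
sampled haplotype is a founder mosaic (segments ~500 kb), which yields
(i) LD decaying smoothly in distance and (ii) background relatedness of
order 1/pool size — the design median pairwise kinship is 1/66 ≈ 0.015.
Sibling pairs (default 10% of individuals in the baboon preset, none in
the YRI preset) are drawn as two meioses from shared simulated parents.
Note the centered genomic relationship matrix estimates kinship *relative
to the sample mean*, so the realized GRM median is ≈ 0 while sibling
entries stand out at ≈ 2×0.25; the 0.015 background lives in the design
(pedigree-style) kinship.  MAF spectra: the intermediate-rich preset draws
Beta(0.8, 0.8) truncated to [0.02, 0.5]; the rare-rich preset draws from a
1/x-weighted grid on [0.02, 0.5].  Per-gene SNP counts are gamma-Poisson
with means 45.4 (shape 0.65) and 20.3 (shape 1.0) for the two presets,
matching the heavy-tailed counts such pipelines produce.  Site quality
scores, per-class read depths (with a heterozygote depth boost and an
optional reference-bias deficit for alternate homozygotes) and ~1%
missingness give the variant filters real work.

**Expression.**  The latent trait is z = xβ + u + hidden factors +
covariates + ε.  Non-cis components are variance *shares of a unit total*:
a per-gene trans share (Beta-distributed, mean 0.25) realized through
u ~ MVN(0, σ²ᵤK) with K the realized standardized GRM; a shared
hidden-factor share (default 0.20 across 3 factors) — the batch/
environment structure that makes expression-PC correction useful rather
than merely destructive; covariate shares at the scale such cohorts report
(age 1.89%, maternal social connectedness 1.9%, sex 0.82% of variance);
and the residual takes the remainder.  Because the non-cis variance is ~1,
planted β values are on the same scale as the power-simulation convention.
Planted effects: 10% of genes, |β| ~ N(0.96, 0.3²) for the baboon preset
(N(0.80, 0.3²) for YRI), sign random.  Counts are negative binomial
(dispersion 0.2) with log-mean = gene baseline (log-normal around 60) +
1.0·z + GC distortion + library offset.  GC bias is a gene-level
multiplicative distortion exp(slope·(1+jitterₛ)·(gc−mean gc)) shared across
samples up to per-sample jitter (sd 0.3) — the component double quantile
normalization genuinely removes; a distortion *independent* across samples
would survive any per-gene rank transform.

**Allelic counts.**  At exonic SNPs (~30% of a gene's SNPs are placed in
exons), heterozygous individuals receive total reads y ~ Poisson around a
site depth (default mean 30), and alternate-haplotype reads
x⁺ ~ Binomial(y, θ) with θ ~ Beta of mean θ₀ and intra-class correlation ρ
(default 0.02; ρ = 0 is exactly binomial).  In the default phased mode
θ₀ = 0.5 + δ·a/2 where a = tanh(β/2) is the gene's allelic imbalance and
δ ∈ {−1, 0, +1} encodes, through the simulated haplotypes, whether the
exonic alternate allele rides the causal alternate haplotype — so only
causal heterozygotes show imbalance and the sign agrees with the eQTL
effect through LD, exactly the coupling the concordance analyses measure.
A "direct" mode applies E[x⁺/y] = 0.5 + a/2 to every heterozygote for
calibration tests.  An optional reference-mapping-bias term shifts θ₀ down.

**What the generator does not emulate:** read-level artifacts (mapping,
duplicates, junction recovery), admixture tracts and long-range admixture
LD, recombination-distance phase decay between exonic and regulatory
variants beyond the copier's LD, X-linked dosage, and any real covariate
structure.  Passing tests therefore demonstrate the *statistical machinery*
— calibration, recovery, ordering properties — under the assumed
generative structure, not robustness to every artifact of real RNA-seq.

## Problem sizes

Desk-scale runs use 63 individuals and 200 genes (the study shape at a
reduced gene count).  Null-calibration checks draw fresh expression per
replicate and test one SNP per gene, because a KS uniformity test on all
cis SNPs of a single draw inherits LD and shared-trait dependence and
rejects spuriously.  Runs use 10 expression-label permutations for the
eQTL FDR,
8–20 ASE null replicates, 3–12 power-simulation replicates on reduced
grids (3 effect sizes, 3 PVE values), a 2000–5000-individual panel for the
large-n winner's-curse limit, and 200 burn-in / 2000 sampling MCMC steps
for variance-partition recovery checks.  The power analysis stratifying by
causal-MAF quartile plants effects in 40% of genes purely to give each
quartile enough planted genes for a stable power estimate; per-gene power
is unaffected by the planted fraction.

## Known limitations

* The empirical-FDR estimator is grainy at small discovery counts; with a
  handful of significant genes the realized false proportion is effectively
  {0, 1/k, …}, so calibration statements need pooled runs.
* Exact ML for the beta-binomial admits the bimodal α → 0 null at
  all-or-nothing sites (LRT cap 2n log 2); rely on the empirical null, not
  the nominal χ² p, for significance.
* The BSLMM trans component is identified through the spectrum of K; at
  n ≪ p with weak structure the posterior for pve_trans is broad, and the
  reported intervals say so.
* Expression-PC correction on panels of only a few hundred genes removes
  real cis signal along with structure (see above).
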