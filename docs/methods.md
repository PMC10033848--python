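# Methods

`polyarch` implements a quantitative-genetics workflow for a conifer breeding
study with two population types: a polycross training population (maternal
half-sib families over several test sites) and inbred selfing lines advanced
by repeated self-fertilisation with or without selection on seedling height.
Every statistical stage is exercised on synthetic data with recorded truth;
this note describes the models, the defaults and why they were chosen, and
what the synthetic data do and do not emulate.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the test suite.

**Founders.** Unrelated individuals under Hardy-Weinberg equilibrium:
dosage ~ Binomial(2, p) per locus, with minor-allele frequencies drawn
uniform on [0.01, 0.5] by default. The MAF spectrum and linkage of the real
panel are not published, so loci are unlinked; this keeps every Mendelian
oracle exact (per-locus transmission probabilities are known in closed
form). Consequence: tests of LD pruning use planted duplicated columns
rather than realistic decay, and nothing here validates behaviour under
strong LD.

**Polycross progeny.** One dam per family; the sire is redrawn per offspring
from the pollen pool excluding the dam, which makes families maternal
half-sib in expectation (mean additive relationship 0.25), matching how a
polycross is treated analytically. Site assignment is balanced per family.

**SNP effects.** Per-SNP mixture class ~ Multinomial(pi) and effect
beta_j | class k ~ N(0, gamma_k * sigma_g2) with
gamma = (0, 1e-4, 1e-3, 1e-2) — the same four-class prior the Bayesian model
assumes. Default pi = (0.94, 0.04, 0.015, 0.005), chosen so that a
2000-SNP panel carries a handful of large-effect loci, a few dozen small
ones, and a polygenic background, the architecture regime the mixture model
is designed to resolve. The mixture scale sigma_g2 defaults to 8.0: the
realized additive variance of the default panel is roughly
m * E[2pq] * sum(pi_k gamma_k) * sigma_g2 ~ 0.04 * sigma_g2, so this puts
the default trait near h2 = 0.25 against unit-scale site residuals — the
moderate-heritability regime of conifer growth and chemistry traits.

**Phenotypes.** y = site mean + sum_j d_ij beta_j + e, with site-specific
residual variances (default 3 sites, unequal variances) and the true
breeding value stored per individual. Missing dosages are mean-imputed
before computing genetic values and flagged.

**Selfing program.** 15 unrelated founder pairs -> 15 full-sib families
(pedigree F = 0 by construction); from each family's FS cohort,
two "select" lines (tallest seedling by phenotype, standard-normal scale)
and two "random" lines are founded, then advanced one tree per generation by
selfing, choosing among a cohort of 2 x replicates (default 6) selfed
offspring per line per generation. Selection acts on phenotype, not true
breeding value; heights have h2 = 0.5 on a unit-variance scale by default.
The generator reproduces the two classical recursions the analyses rely on:
pedigree F_t = 1 - (1/2)^t and per-generation halving of heterozygosity.
It does not model line extinction, mutation, or selfing avoidance.

**Genotype errors and ring cores.** Error injection flips homozygous calls
to heterozygous (optionally to the opposite homozygote) at a stated rate and
logs every flip as truth. Ring cores generate constant or lognormal ring
widths; a missed pith is encoded by a circular arc whose chord and sagitta
come from a known radius, so the downstream correction can be checked by
round trip.

## Variant QC

Site filters mirror a vcftools/vcflib pass and are applied in a fixed order
(call rate >= 0.95, quality >= 30, mean depth in [15, 60] over called
samples, MAF >= 0.01, heterozygote allele balance, heterozygote-excess exact
test at p >= 0.001), each removed record attributed to its first failing
criterion so counts are reproducible. Sample removal (missingness strictly
greater than 40%) runs after site filters, without a second site pass;
whether MAF should be recomputed after sample removal is unknowable from the
source description, so the single-pass order is the documented choice.
The heterozygote-excess test is exact: conditional on allele counts the
heterozygote count follows the Levene-Haldane distribution, and the
one-sided p sums the upper tail. Allele balance is the mean reference-read
fraction over heterozygous calls (AD-derived); sites without AD skip the
criterion with a warning.

**Selfing-line correction.** Under faithful selfing, homozygosity is
absorbing, so a heterozygous call — or the opposite homozygote — following
an established homozygous state is a likely genotyping error.
"Consecutive homozygous calls" is read as at least two prior generations
(missing generations are transparent); a single aberrant call whose
successor returns to the established state is corrected to that homozygote,
and anything else (two or more conflicting calls, conflicts after a single
homozygous call) flags the line x SNP series for removal rather than risk
overcorrection. Imputation of a single missing generation fills only
logically forced genotypes: the intersection of possibilities from the
previous call ({g} if homozygous g, anything if heterozygous) and the next
call ({het} if heterozygous, {g, het} if homozygous g), left missing unless
that intersection is a single genotype.

## Relationship matrices and inbreeding

The genomic relationship matrix is VanRaden method 1
(G = WW'/(2 sum p(1-p)), dosages centred by 2p-hat from the analyzed
sample, per-locus mean imputation of missing calls), matching the rrBLUP
`A.mat` convention. The pedigree A-matrix uses the tabular method with
selfing supported (sire = dam), giving diagonal 1 + F.

Genomic inbreeding is the correlation between uniting gametes
(PLINK `--ibc` Fhat3): per SNP, [x^2 - (1+2p)x + 2p^2] / (2p(1-p)),
averaged per individual over usable loci (mean of per-SNP ratios, the
estimator-III aggregation; the ratio-of-sums alternative is not used). The
numerator is evaluated as x(x-1) - 2p(x-p), algebraically identical but
arranged so the heterozygous case cancels to exactly -1 in floating point.
Allele frequencies come from the analyzed cohort (or an explicit base
population when supplied — the selfing analyses pass founder frequencies,
since the inbreeding reference population is the outbred base).

LD pruning is greedy left-to-right within scaffold
(window 2168 kb, step 1, r^2 > 0.1 removes the later SNP), per scaffold
because positions are only comparable within scaffolds.

## REML mixed models

All variance-component models are linear covariance structures
V(theta) = sum_k theta_k V_k fitted by average-information REML with
step-halving on the restricted log-likelihood, non-negativity projection for
variances (zero boundary allowed), and convergence at |delta logL| < 1e-9
(200 iterations maximum, flagged if not converged). Two computational paths
share the update algebra: when each observation maps to a distinct entry of
a single relationship matrix and residuals are homogeneous, the model is
rotated by the eigenvectors of ZKZ' so every structure matrix is diagonal
and iterations cost O(n p^2); heterogeneous by-site residuals and bivariate
models use the dense path.

Heritability is h2 = s2_g / (s2_g + mean of per-site residual variances)
(arithmetic mean across sites; an n-weighted mean would be equally
defensible but the plain mean is the documented choice), with a first-order
delta-method SE from the inverse average-information matrix. Bivariate
models carry an unstructured 2x2 genetic and residual covariance; after each
update the 2x2 blocks are clamped to near-PSD (|cov| <= 0.999 sqrt(v1 v2)).
r_g is undefined (NaN, flagged) when either genetic variance sits at the
zero boundary; reported correlations are clamped to [-1, 1].

Adjusted phenotypes are residuals of the fixed-effects-only model (the
additive random term removed), the response used by the Bayesian model.
Wald F-tests use the full coefficient block of a term with denominator
degrees of freedom n - rank(X); the reference software's denominator-df
rule is unknowable, and residual df is the conservative conventional
choice. Fixed-effect defaults: site (and replicate-within-site where
present) for all traits; pith age and sapwood:heartwood ratio are available
as covariates for wood traits. Exact per-trait model tables from the source
study are not published, so terms are configurable per ModelSpec.

The inbreeding-depression report regresses a trait on the genomic
inbreeding coefficient as a fixed covariate inside the mixed model and
reports coefficient, SE, Wald F and p. The selfing-line analyses use OLS:
bv ~ F (slope = inbreeding depression per unit F) and
bv ~ F + line_type + F:line_type + family, where the interaction measures
how selection changes the depression slope.

## Mixture-model SNP effects (Gibbs sampler)

The sampler fits y = mu + D beta + e with beta_j from the four-class
normal mixture above, pi ~ Dirichlet(1,1,1,1), and scaled inverse chi-square
updates for sigma_e2 and sigma_g2. Per sweep each SNP's component indicator
is drawn from its conditional categorical with the effect integrated out
analytically, then the effect from its conditional normal, with a running
residual; mu, pi, sigma_e2, sigma_g2 follow. Hyperpriors default to df 4
with scale half the phenotypic variance for both variances (the reference
implementation's constants are not recoverable; both are configurable, and
sigma_g2 sampling can be disabled). SNP visit order is permuted per
iteration by default; an explicit scan order is supported, which makes
per-SNP outputs exactly equivariant under matched column permutations (up
to float accumulation order). The running residual is re-derived from
scratch every 1000 iterations and the maximum drift reported (observed
~1e-14).

Per-draw heritability is Var(D beta) / (Var(D beta) + sigma_e2) with the
genetic values read off the maintained residual. Effect size is
ES = 2 beta^2 f (1-f) per SNP (f = minor-allele frequency), computed per
chain from that chain's posterior-mean effect and then averaged across
chains, as are the mixture summaries; averaging precedes class assignment.
Assignment takes the rounded (half-up) posterior-mean SNP count per nonzero
class and fills classes by descending ES (large, then small, then
polygenic; ties by map order). Per-class variance shares are normalized ES
sums over associated SNPs.

Convergence uses the Gelman-Rubin potential scale reduction factor on h2
and the three class-variance shares, pass threshold 1.1. The across-chain
(non-split) statistic is the default, clamped at 1.0 from below so that
identical chains report exactly 1; a split-chain variant is available by
flag. Run profiles: the full profile (300k iterations, 100k burn-in,
thin 10, 5 chains) and a desk profile (20k/5k/10, 2 chains) for panels of a
few hundred SNPs.

**Known limitation — class identifiability at small scale.** The zero and
polygenic classes are statistically distinguishable only through
lambda = gamma_1 sigma_g2 x'x / sigma_e2. At desk scale
(n of a few hundred) lambda is of order 1e-2, per-SNP Bayes factors are
1 + O(lambda), and on signal-free data the mixture proportions over the
indistinguishable classes behave as a near-neutral urn: the posterior mean
of pi_0 settles near 1/3 rather than near 1. This is a property of the
model at that problem size, not of the sampler — the conjugate closed form,
the ridge-regression reduction, and planted-architecture recovery all
verify the sampler itself. At real-data scale (n in the thousands) lambda
is of order 0.1-1 and the zero class dominates null SNPs. Tests of null
behaviour therefore assert what is attainable at desk scale (small
posterior h2, zero class modal).

## Set analysis and enrichment

Exclusive intersections (the bars of an UpSet plot) count SNPs belonging to
exactly each subset of traits and partition the union. Linkage-group
enrichment is a one-sided Fisher exact test (upper hypergeometric tail) of
focal SNPs on a linkage group against the full panel — one-sided because
the question is over-representation; a two-sided variant is not provided.
No multiple-testing correction is applied across linkage groups. Gene
context is 1-based inclusive interval membership (BED input converted by
start+1), first gene by start position on ties.

## Ring corrections

For cores missing the pith, the missed radius is the chord-sagitta circle
radius L^2/(8h) + h/2 of the arcing innermost ring — the unique circle
geometry consistent with a chord of length L and arc height h, validated by
the semicircle identity missed_radius(2r, r) = r. Missed ring count is the
missed radius over the mean of the three innermost measured ring widths,
rounded half away from zero (the rounding rule is a documented choice).
Totals compose as measured + missed; heartwood = total - sapwood; cores
missing bark get no correction and are flagged as minimum estimates.

## Problem sizes and numerical choices

Default test and acceptance sizes: 2000 founders x 500 SNPs for
Hardy-Weinberg checks; 200 selfing lines x 2000 SNPs for the inbreeding
recursion; 50 replicates of n=500, m=2000 for GBLUP heritability recovery;
20 replicates of n=400, m=500, 20k iterations x 2 chains for the planted
five-large-SNP recovery; 50k gene drops for the pedigree oracle. These are
the package's standard verification sizes; larger runs only sharpen the
Monte-Carlo error bars. Ridges of 1e-6 stabilise Cholesky factors of
near-singular relationship matrices; variance floors are 1e-8 x Var(y)
(reported as 0 at the boundary); the AI matrix is regularised by a
relative 1e-8 diagonal before solving.
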