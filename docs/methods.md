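# Methods

## Scope and model

`mtgs` analyses multi-environment wheat trials for genomic selection. The
chain of computation is:

1. plot-level phenotypes from augmented designs → adjusted genotype means
   (BLUEs), per environment and combined;
2. SNP codes (−1/0/+1 for minor-homozygous / heterozygous / major-homozygous)
   → additive genomic relationship matrix **K**;
3. BLUEs + **K** → single-trait (ST) and multi-trait (MT) Bayesian genomic
   prediction via Gibbs sampling;
4. Monte-Carlo cross-validation comparing ST-CV1, MT-CV1 and MT-CV2.

### Phenotype adjustment

Per environment the model is

    y = μ + genotype + β·(days to anthesis) + block + ε

with genotype (test entries and checks as levels of one factor), and the
anthesis covariate fixed; blocks random. The published form of this model
writes separate "Gen", "Check" and "IDCheck" fixed terms; these jointly
partition the levels of a single genotype factor and are rank-deficient as
written, so we fit the equivalent full-rank cell-means parametrization. The
combined model adds fixed environment effects and random genotype×environment
and block-within-environment terms; the returned adjusted mean is the
genotype coefficient plus the average fitted environment effect. BLUEs are
invariant to block relabelling and to adding a constant to the covariate
(the covariate is centred).

Variance components are estimated by EM-REML in the V-matrix form
(gradient-EM updates; convergence when the restricted log-likelihood moves
by < 1e−6, max 500 iterations; estimates floored at ~0 during iteration and
truncated to 0 on exit). EM is slow but monotone and derivative-free; at the
problem sizes here (hundreds of plots) each fit takes seconds to a couple of
minutes. Broad-sense heritability is

    H² = σ²G / (σ²G + σ²GxE/n + σ²e/(n·r)),

`n` environments, `r` replicates per environment (1 in an augmented design).

A structural caveat for augmented designs: with unreplicated entries, the
anthesis-covariate slope is identified only by the replicated checks (and,
in the combined model, by within-genotype variation across environments).
With few check plots the slope estimate is noisy and leaks correlated noise
into all BLUEs. Realistic block sizes (~20 entries + 3 checks, i.e. 12
blocks per environment for 236 entries — the generator default) give enough
check replication for a usable slope.

### Kinship

VanRaden: `K = WW'/c` with `W` the column-centred codes and
`c = Σⱼ 2fⱼ(1−fⱼ)`. No MAF filter or shrinkage by default (a `min_maf` flag
exists, off by default). Missing codes are imputed first: per-marker mean
(default; fractional dosages are fine downstream) or k-nearest lines by mean
absolute code distance over shared markers, rounded back to a valid code.
If K's smallest eigenvalue is below −1e−8 it is stabilized by adding
(|λmin| + 1e−6)·I, and the event is logged. Checks are excluded from K for
genomic selection by default (they are spatial controls), with a flag to
include them.

### Gibbs samplers

ST model: `y = μ + Zα + ε`, `α ~ N(0, K σ²g)`, `ε ~ N(0, I σ²e)`. MT model:
`α ~ MVN(0, Σ⊗K)`, `ε ~ MVN(0, R⊗I)` with unstructured Σ and diagonal R.
Both samplers rotate into the eigenbasis `K = U D U'`: the genetic-value
full conditional then factors into independent scalar (ST) or t×t (MT)
Gaussian updates per eigen-coordinate, batched with dense linear algebra.
Eigenvalues ≤ 1e−8 are treated as null directions (genetic value pinned at
0). Missing phenotype cells are drawn from their conditional normals each
iteration (data augmentation), which is also how test-set predictions arise
in cross-validation; the reported prediction for a missing cell is the
posterior mean of μ + g, not the noisy augmented draw.

Priors (all exposed in `GibbsConfig`): scaled-inverse-χ² with 5 df for σ²g,
σ²e and R's diagonal, scale set so the prior mode is half the observed
sample variance; inverse-Wishart with t+3 df for Σ, scale set so the prior
*mean* is half the sample variance per trait. The mean convention for Σ is
deliberate: because R is diagonal, all cross-trait covariance must flow
through Σ, and a strongly diagonal or near-zero-mode scale either shrinks
genetic correlations toward zero (inflating variances to compensate) or
pulls genetic variances down; the half-variance-mean scale is the
multivariate analogue of the scalar priors and gives approximately unbiased
recovery of heritabilities and genetic correlations at n ≈ 236 (checked in
the acceptance tests). Non-positive-definite inverse-Wishart draws (a purely
numerical event) are retried with a logged diagonal jitter.

Defaults are 2000 burn-in / 12,000 iterations, no thinning. Chains are
reproducible bit-for-bit under a fixed seed. Effective sample size,
Monte-Carlo standard errors (batch means for the genetic-value vectors) and
Geweke z-scores are available in `mtgs.diagnostics`. Identity-kinship
panels leave σ²g and σ²e jointly unidentified (only their sum enters the
likelihood); identification comes from the spread of K's eigenvalues, so
variance estimates on small panels remain prior-influenced.

### Cross-validation

`make_splits` draws independent uniform 70/30 partitions (train size
floor(0.7·n) — 165/71 on 236 lines). The same splits are shared by all
schemes for a paired comparison; each replicate's sampler seed derives
deterministically from (global seed, replicate index). ST-CV1 masks the
primary trait of test lines in a single-trait fit; MT-CV1 masks *all*
traits of test lines; MT-CV2 masks only the primary trait. Predictive
ability is the mean Pearson r between held-out observed BLUEs and
predictions over replicates; replicates with degenerate (constant) observed
or predicted vectors are excluded and counted. The percent increase from
ST-CV1 to MT-CV2 is `100·(mt−st)/st`, undefined (missing, with a warning)
when the ST mean is ≤ 0. Masking is structural — held-out primary values
are removed from the data the sampler sees — and an audit test corrupts
them and verifies bit-identical predictions.

## Synthetic data

The generator emulates the study conditions: 236 test entries plus 3
repeated checks, three environments, augmented blocks of ~20 entries with
every check in every block (12 blocks/environment), and seven traits
(HI, GY, GN, SPI, FE primary; NDVI, CT secondary) with heritabilities
0.25–0.64, means/SDs on the published scales, and genetic correlations of
both signs (yield-component traits positive; canopy temperature negative
with everything). Defaults live in `SimParams`; marker panels are drawn
under Hardy–Weinberg with uniform MAF in [0.05, 0.5] and optional missing
calls.

The data-generating model is additive-infinitesimal: breeding values are
MVN(0, Σ⊗K) on the realized K of the simulated markers — deliberately
matching the GS models' own assumptions so parameter recovery is a fair
test. G×E is an independent normal draw per (line, environment, trait),
with σ²GxE/σ²e = 1 for primary traits and 0.2 for the physiological traits
(whose G×E the study found non-significant). Block effects are N(0,
(0.3·SD)²), environment main effects N(0, SD²). Days to anthesis is a
genotype-level value (SD 5 d) plus plot noise (SD 2 d) with an additive
effect on every trait (slope 0.3·SD per anthesis SD). Requested
heritabilities are hit exactly in expectation by solving the H² formula for
the variance split; `SimTruth` stores every component so realized values
can be recomputed. `simulate_blues` generates genotype-mean data directly
at the GEBV-model level (y = μ + g + e) for studies where plot-level
structure is not under test.

What the generator does *not* emulate: population structure and families
(lines are exchangeable draws, so prediction accuracy comes only from the
n/p ratio, not kinship structure — accuracies land in the 0.05–0.4 range
typical of unstructured panels), linkage disequilibrium between markers,
spatial field trends beyond blocks, and non-Gaussian trait distributions.
Passing tests therefore validate the estimators under their own
assumptions; they do not certify performance on structured breeding
populations.

## Problem sizes and profiles

The `demo` profile (default) uses 2000 markers, 500/3000 Gibbs iterations
and 20 CV replicates; `study-scale` uses 27,466 markers, 2000/12,000
iterations and 100 replicates. All demo outputs are labelled with their
profile. The acceptance script runs at the study's 236-line panel size with
demo-length chains; tests use 40–236-line panels chosen per property.

## Known limitations

- EM-REML convergence is first-order; near-boundary variance components can
  hit the 500-iteration cap with the log-likelihood still creeping (a
  warning is logged; estimates are then slightly conservative).
- Genotype-order exchangeability of the samplers holds to Monte-Carlo
  tolerance, not bit-for-bit, because the eigendecomposition of a permuted
  K is not exactly the permuted eigensystem in floating point.
- The combined BLUE model drops the check-identifier×environment term as
  aliased with genotype×environment under the cell-means parametrization.
- Percent increase is unstable when the ST-CV1 baseline is near zero; the
  per-scheme means and standard errors are the robust summary.
- Under the default trait architecture the genetic correlations between the
  primary traits and the physiological secondaries are modest (|r| 0.1–0.4)
  and attenuate further at the BLUE level, so MT-CV2's advantage over ST-CV1
  on the synthetic panel is small and can vanish within Monte-Carlo noise at
  demo replicate counts. The directional acceptance checks therefore use a
  clearly informative secondary (genetic correlation 0.6, heritability 0.6
  against a 0.3-heritability primary), where the MT-CV2 gain is large and
  reproducible. Large observed gains on real panels likely also reflect
  population structure, which the exchangeable synthetic lines do not carry.
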