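# Methods

This note documents the statistical models, numerical choices and known
limitations of `saltgp`. It is written for users who want to know what
the package computes and why, in the package's own terms.

## Marker quality control

Dosages are counts of one allele (0/1/2) per biallelic SNP, `NaN` for
missing. Filtering discards markers with call rate < 0.75,
heterozygosity > 0.10 or minor allele frequency < 0.05 (all strict
inequalities; the defaults match standard GBS pipelines for inbred rice,
where residual heterozygous calls are mostly genotyping error).
Surviving heterozygotes are set to missing, and the missing fraction
recorded at that point (`pre_imputation_missing_rate`) is what the
imputer fills and what LD pruning uses to rank cluster members. A marker
failing several criteria is attributed to the first failing one in the
fixed order call rate → heterozygosity → MAF, purely for reproducible
reporting. Filtering is idempotent except in the corner case where the
het-to-missing conversion pushes a marker's call rate below the
threshold; the property tests use data away from that boundary.

Imputation is deliberately naive (per-marker mode, or rounded mean):
it is plumbing for kernels, not a genotype-phasing method. Complete-LD
pruning clusters columns whose dosage vectors are perfectly linearly
related (identical, allele-flipped, or any |r| = 1 within 1e−12,
detected by grouping canonical standardized column signatures rounded at
1e−9). One representative per cluster is kept: lowest
pre-imputation missing rate, then highest MAF, then map order.
Monomorphic columns have undefined correlation and are left as
singletons (the MAF filter removes them in practice).

## Phenotype models

The screen is a split plot: three replicates staggered in time, each
with six control and six salt tanks. Per trait, adjusted genotype means
come from the fixed-effects part of

    value ~ condition + genotype + condition:genotype  (sum-to-zero)
            + replicate (random) + tank-within-replicate (random)

fitted by REML (statsmodels `MixedLM`). The interaction is included even
though interest centres on main effects, because per-condition genotype
means are otherwise not estimable. For small designs a combined
replicate/tank random term is available. When REML does not converge the
model falls back to ordinary least squares, and as a last resort to raw
cell means; the path taken is recorded on the fit object. On balanced
complete data the adjusted means equal raw cell means exactly, which is
the main oracle used in testing. A caveat: the absolute level of
adjusted means is only identified up to the replicate structure (a
uniform shift in one replicate moves all cell means equally), so only
genotype contrasts are meaningful across designs.

Stress response indices are percent changes,
`iTRAIT = (salt − control) × 100 / control`, undefined when the control
mean is zero. Genotype-by-condition interaction strength is the rank
correlation (Spearman by default, Kendall optional) of per-genotype
adjusted means across conditions. Repeatability within a condition is
`H² = σ²_g / (σ²_g + σ²_ε / r̄)` from a random-genotype REML fit, with
`r̄` the harmonic-mean replicate count — the genotype-mean-basis formula
standard in plant breeding.

## Kernels and bandwidth

GBLUP uses `K = X X′ / p` on centered dosages without MAF
standardization, so simulated genetic covariance equals `σ²_u K`
exactly. RKHS uses `K = exp(−h d²)` on squared Euclidean distances
between dosage vectors.

At genomic marker densities raw `d²` is of order 10³–10⁴, while the
Gamma(shape 3.0, scale 1.5) prior used for the bandwidth concentrates on
h ∈ [0.3, 10]. On the raw scale that combination drives `K` to the
identity and strips RKHS of all predictive information. The pipeline
(`build_kernel`) therefore normalizes squared distances to mean 1 before
estimating `h` and building the kernel; on that scale the prior is
informative and RKHS behaves comparably to GBLUP, which is the empirical
regime reported for kernel methods in diversity panels. The low-level
`gaussian_kernel` still accepts raw distances for users who manage their
own scaling.

Bandwidth estimation maximizes, over a 2-D grid,

    log p(y | h, φ) + log Gamma(h; 3.0, 1.5)

where `p(y | h, φ)` is the marginal density of `y` under
`y = 1μ + u + ε`, `u ~ N(0, σ² K_h)`, `ε ~ N(0, φ σ² I)`, after
integrating `μ` (flat; implemented by a Helmert rotation onto the
orthogonal complement of 1) and the common scale `σ²` (Jeffreys),
leaving a multivariate-t-type criterion evaluated from one
eigendecomposition of the projected kernel per grid point. The h grid is
50 log-spaced points spanning both the data scale
`[10⁻⁴, 10²] / median(d²)` and the prior's 0.1–99.9% support; φ is
profiled over 25 log-spaced points in [10⁻³, 10³] (flat on log φ —
weakly informative and scale-free, since only h carries a stated prior).
A bounded 1-D refinement around the grid argmax is on by default. With
no genetic signal the likelihood is flat in h and the estimate falls at
the prior mode (shape−1)·scale = 3.0, a property used as a test oracle.

## Gibbs samplers

Both prediction models run on one sampler core; the single-environment
model is literally the one-environment special case, so the two agree
draw-for-draw under a shared seed. Genetic effects are updated in the
eigenbasis of their kernel (eigenvalues below 1e−10 dropped), where the
full conditionals factor into independent normals — one vectorized draw
per block per sweep, no per-coordinate loops. Intercepts have flat
priors; variance components have scaled-inverse-χ² priors with df₀ = 5
and scale set so the prior mode allocates R² = 0.5 of the observed
phenotypic variance to the genetic components (divided equally among
them when environment-specific effects are on) and the remainder to the
residual — mirroring common Bayesian GBLUP defaults. Residual variances
are per-environment by default (a pooled option exists).

Unphenotyped lines (`NaN` in `y`) are handled by data augmentation:
their records are drawn from the current predictive distribution each
sweep. This keeps the eigenbasis updates exact under any missingness
pattern and is precisely the masking needed for CV1 and for predicting
a breeding population from a kernel built on the union of panels.
Defaults are 35,000 iterations, 5,000 burn-in, thinning 10 (3,000
retained draws); reduced settings are used in tests and cross-validation
where only posterior means of linear functionals are needed, and the
oracle tests bound the resulting Monte-Carlo error explicitly.
Convergence is monitored by the split-chain Gelman–Rubin PSRF (each
chain halved, between/within variance ratio); parameters with zero
within-chain variance are flagged as undefined. Chains and CV partitions
draw their seeds from independent `SeedSequence` substreams of a master
seed.

For oracle testing the sampler can pin variance components and the
intercept, in which case its posterior mean provably solves the
mixed-model (ridge) equations `K (K + λI)⁻¹ (y − ȳ)`; with a flat prior
on μ and a kernel carrying a strong constant component (Gaussian kernels
especially) the *unpinned* posterior splits the level between μ and u
differently from that closed form, which is expected behaviour, not
error.

## Cross-validation and inference on predictive ability

CV1 draws `floor(0.8 n)` training lines uniformly at random, 100
repetitions by default; the identical partitions are reused across every
trait × method × model combination so that comparisons are paired. The
kernel is built once per trait/method on all samples; per repetition the
validation lines' phenotypes are masked (in all environments for the
multi-environment model), the model refitted, and PA computed per
condition. Repetitions with zero-variance predictions or observations
yield undefined PA and are excluded from cell means with their count
reported, rather than imputed. ANOVA on Fisher-Z-transformed PA uses
type-II sums of squares on the main factor effects, with partition id as
a blocking factor (the pairing makes it informative); factors with fewer
than two levels are dropped with a warning, and identical Z everywhere
short-circuits to zero F statistics.

## Validation-subset selection

Predicted performances for the selected traits and both methods are
converted to percentile ranks (midrank convention); a line's consensus
score is its mean percentile. Strata are deciles of the consensus
*ranking*: the lowest 10% of lines form the bottom stratum, the highest
10% the top. Quotas follow the 20% / 20% / 60% composition
(floors for the tails, remainder to the middle: 8/8/25 at n = 41);
within each stratum, lines sit at evenly spaced quantiles of the
consensus score (maximum spread, deterministic tie-breaks), with a
seeded random alternative. Ranking the consensus rather than
thresholding its value matters: a mean of many percentile ranks
concentrates near 0.5, and absolute thresholds would leave the tail
strata empty. The whole construction is invariant to monotone
transformations of each trait's predictions.

## Population structure

Simple-matching dissimilarity counts the fraction of markers with
unequal calls (a heterozygote mismatches both homozygotes). The
neighbor-joining tree (Saitou–Nei, via scikit-bio) clamps the occasional
negative branch length to zero and recovers additive distances exactly,
which the tests verify on small fixtures. Group assignment is PCA
(fewest components reaching 90% variance) followed by k-means with
seeded restarts — the clustering step of DAPC without the discriminant
projection, which downstream use (subgroup labels) does not need.
Cluster recovery depends on marker density: with a few hundred markers
the admixture continuum can bridge subpopulation clusters, while at
≳2,000 markers pure subgroups co-cluster essentially perfectly.

## Synthetic data

The generator emulates the structure of a japonica rice salinity screen:
Balding–Nichols allele frequencies (ancestral frequencies uniform on
[0.1, 0.9], subpopulation frequencies Beta-distributed at differentiation
F, default 0.1), two subpopulations plus a configurable admixed fraction
(default 0.37) whose alleles are drawn from either subpopulation by an
individual admixture coefficient uniform on (0, 1). Individuals are
inbred by default (the two allele draws are identical by descent),
matching selfing rice accessions — without this, Hardy–Weinberg
heterozygosity would trip the het filter on nearly every marker.
Heterozygote and missing-call injection are available for exercising QC.
Defaults are study scale: 600 individuals, 17,000 markers on 12
chromosomes of 25 Mb.

Phenotypes follow the fitted model's decomposition: shared causal
effects `β₀` and condition-specific effects `β_j` with variance shares
set by the target genetic correlation ρ_G, genetic values rescaled to
hit per-condition heritabilities, plus replicate, tank and residual
noise on the split-plot layout (variance fractions 0.05/0.05 by
default). The default trait panel spans ρ_G ≈ 0.30–1.0 and h² ≈
0.45–0.8, covering the weak-to-strong interaction range seen in
two-condition screens, with ion-like traits (Na, K) generated under salt
only. Ground truth (effects, genetic values, realized h² and ρ_G,
subpopulation labels) is returned for recovery tests.

Limitations of the generator: markers are independent within
chromosomes (no linkage disequilibrium decay), effects are purely
additive, and admixture is a one-generation allele-mixing model. Tests
passing on this data therefore demonstrate the correctness of the
machinery — kernels, samplers, CV, selection — not robustness to LD
structure, dominance/epistasis, or assay artefacts in real data.

## Problem sizes and numerical settings

The test suite and the acceptance script run at reduced scale chosen to
keep each property sharp: oracle checks at n = 50, variance recovery at
n = 300 with 8,000 iterations over 20 replicates, cross-validation at
n = 150–240 with 15–30 partitions and 1,500-iteration chains, QC and
pruning at a few hundred to two thousand markers. These sizes are where
the respective statistical signals are already decisive; the library
itself has no scale assumptions beyond dense linear algebra (an
eigendecomposition per kernel, O(n²) per Gibbs sweep).
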