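# Methods

## The demographic model

The generator targets a wild-plant-like study system: 50 demes in two
genetic clusters.  The "old" cluster holds 25 demes of mean diploid
effective size Ne = 5,000; the "young" cluster holds 25 demes smaller
by a factor 1.5.  Backwards in time, all young demes fuse into the
first old deme `t_split = 20,000` generations ago (the clusters'
divergence time), and all old demes fuse into a single ancestral deme
of size Ne[0] `t_ancestral = 140,000` generations ago.  Migration is
specified as a per-ordered-pair backward probability of a lineage
moving between demes per generation: `m_within = 0.001` inside a
cluster and either `m_between = 0.0001` (high gene-flow regime) or 0
(low gene-flow regime) across clusters.  Times are in generations and
sizes are diploid.

To make populations heterogeneous, each deme draws its Ne and
migration rates from a truncated normal with coefficient of variation
`jitter_cv = 0.10` around the regime mean (redrawn while non-positive);
the two split times are drawn once per model the same way.  The spread
is a modelling choice — it matches the order of the between-population
dispersion expected in real systems without destabilising the model.
Per-deme inbreeding is `F ~ max(N(0, 0.05), 0)`, giving E[F] ≈ 0.02;
inbreeding is applied at genotype construction as
per-(individual, locus) identity-by-descent copying with probability F,
the correct per-locus manifestation of an individual-level inbreeding
coefficient for unlinked loci.

### The panmictic-limit collapse

At the default rates the within-cluster migration is enormous in
population-genetic terms: per-pair Nm ≈ 10, i.e. ≈ 240 immigrants per
deme per generation.  Demes are then deep inside the island-model
panmictic limit — the probability that two lineages sampled in the
same deme coalesce there before either emigrates is
`(1/2Ne) / (1/2Ne + 2·m_total)` ≈ 0.002, the expected within-cluster
F_ST.  The generator exploits this: whenever the scaled total
within-cluster emigration `2·Ne·m_within·(d−1)` is at least 50 for
every deme (and no explicit migration matrix is set), each cluster is
simulated as a single panmictic pool of the summed deme sizes, with
deme labels indexing blocks of samples.  This is orders of magnitude
faster than tracking 50 demes and differs from the finite-migration
model by less than the Monte-Carlo noise of any statistic computed
here; a regression test compares the two paths at matched parameters.
Models with weak migration, and the isolation-by-distance /
central-abundance landscape modes (which need real deme structure),
always take the exact structured-coalescent path.  Genealogies come
from msprime; everything downstream of the trees (ascertainment,
mutation placement, pairing, inbreeding, estimators) is implemented in
this package.

### SNP ascertainment

Each locus is one independent genealogy carrying exactly one mutation.
Because a segregating site falls on a genealogy with probability
proportional to that genealogy's branch length, genealogies are
length-weighted: a tree is accepted with probability `L_qual / C`,
where `L_qual` is its total branch length over *qualifying* branches
and the cap `C` is set from a seeded 64-tree pilot batch as
`max(mean·(1+8·cv), 1.5·max)` (cap exceedance has probability below
~10⁻³ by the exponential tail of tree lengths, a bias far below
Monte-Carlo noise).  The mutation is then placed length-uniformly on
the qualifying set.  A branch qualifies when the derived-allele
frequency it would produce in the pooled total sample lies in the
ascertainment band `[maf, 1−maf]` with `maf = 0.05` by default — the
standard minimum-frequency convention of SNP-simulation marker types
and genotyping arrays.  With `maf = 0` every polymorphic site
qualifies; in a sample of four haplotypes the band is inactive and the
ascertained site-frequency spectrum is the classical `P(i) ∝ 1/i`,
which the test suite checks against the closed form
`E[1 − Σp̂²] = 4.5/11`.

The band matters quantitatively: without it, ascertained mean Hs is
bounded by ≈ `1/H_{n−1}` ≈ 0.13 for 1,500 haplotypes and comes out
near 0.05 under this model; with the 5% band the models yield mean
Hs ≈ 0.24 (high flow) and ≈ 0.23 (low flow), mean F_IS ≈ 0.02, and
overall F_ST ≈ 0.000 (high; individual runs slightly negative through
the sample-size corrections, reported unclamped) versus ≈ 0.05 (low).

### Microsatellites and pooling

Microsatellite loci reuse the same genealogies with Poisson mutations
on branches under a symmetric stepwise model (±1 repeat, root repeat
20, floor at 1 repeat).  The default rate 5·10⁻⁴ per generation is in
the range measured for real microsatellites; with the default
metapopulation size it puts heterozygosity near the stepwise-mutation
equilibrium `1 − 1/√(1+8Neμ)`, which a test verifies on a single pool.
`pool_frequencies` discards individual identity (half-missing
genotypes are excluded from the pool so allele frequencies are
unchanged by pooling); downstream, Ho and F_IS are marked unavailable
for pooled data rather than reported as zero.

## Estimators

Per (locus, population): `Ho` is the heterozygote proportion among
typed individuals (an individual is typed only if both calls are
present); `Hs = ñ/(ñ−1)·(1 − Σₐpₐ² − Ho/2ñ)` with ñ the typed count;
`F_IS = 1 − Ho/Hs`, undefined where `Hs = 0`.  Undefined cells are
counted per population, never dropped silently: the NaN counts are an
object of study (they drive the F_IS bias under individual
subsampling, and the package exposes the Pearson correlation between
replicate mean F_IS and mean NaN count).  Per locus, with s the
populations carrying data and ñₕ their harmonic-mean sample size
(recomputed per locus so missingness propagates exactly):
`Ht = 1 − Σₐp̄ₐ² + H̄s/(ñₕ·s) − H̄o/(2ñₕ·s)` (Ho term omitted for pooled
data) and `F_ST = (Ht − H̄s)/Ht`.  The overall F_ST is the ratio of
per-locus sums (mean-of-ratios also reported).  Loci monomorphic
within a subsample stay in the Hs/Ht denominators, contributing zero
— this retention is exactly the mechanism by which sparse individual
sampling biases F_IS.  Grand means weight populations equally.

Pairwise differentiation uses Weir & Cockerham (1984) θ with the full
per-allele a/b/c variance components for genotype data (multilocus
ratio of sums, vectorised over all pairs), and the analogous haploid
ANOVA on allele counts for pooled data.  θ of a population against a
copy of itself is not exactly zero: the 1984 algebra leaves the
finite-sample term ≈ −1/(2(n−1)), which vanishes with sample size; the
tests assert that behaviour rather than an idealised zero.

## Subsampling designs

A design is an axis (loci, individuals per population, populations, or
the joint individuals×populations trade-off) and a level.  Subsamples
are uniform without replacement within a replicate and independent
across replicates; replicate i's RNG seed derives deterministically
from the design seed, so any replicate is reproducible alone.
Accuracy is summarised by the relative error `(X_est − X_sim)/X_est`
(undefined for a zero reference; overestimates negative), reported
both as the error of the replicate mean and the mean of per-replicate
errors (they coincide when no replicate is undefined), plus the
sign-flip proportion for association statistics.  Per-replicate
failures (e.g. F_ST undefined in a degenerate draw) are recorded as
undefined cells and counted, never aborting a run.

## Landscape statistics

Environmental covariates are summarised by PC1 of the
correlation-matrix PCA (bioclim-style variables have heterogeneous
units), sign-fixed so the largest-magnitude loading is positive.
Geographic distance is haversine (km, R = 6,371 km) for lon/lat data
and Euclidean for planar synthetic coordinates; environmental distance
is |ΔPC1|.  MRM regresses the unfolded lower triangle (diagonal
excluded) of the pairwise-F_ST matrix on both predictor triangles
jointly; significance permutes rows and columns of the response matrix
together, predictors fixed, two-sided on |β| with the observed
configuration counted (so p ≥ 1/n_perm); a single-predictor call
reduces exactly to simple OLS.  Centroid distances are Euclidean to
the coordinate-wise mean (geographic) and to the mean in the space of
the first two environmental PCs (niche; dimensionality configurable).
CAH is the simple linear regression of per-population mean Hs on
centroid distance.

The synthetic landscape scatters demes around two cluster centres and
builds environments as linear spatial gradients plus noise.  Mode
`ibd` replaces migration with `m_ij = m_within_i·exp(−d_ij/σ)` (true
isolation by distance; σ→∞ recovers uniform rates); mode `cah`
rescales deme sizes as `Ne_ref/(1 + d_i/σ)` so size decreases strictly
with distance from the range centre (Spearman −1 by construction).

## Outlier scan

Stage one draws, for each locus, null population allele frequencies
from the Balding–Nichols beta distribution at the locus's pooled
frequency and the genome-wide θ̂, then binomial counts at the observed
per-population haploid sizes, and recomputes the count-based locus θ;
the same count-based estimator scores the observed locus, keeping the
null and the statistic commensurable.  p is the upper-tail proportion
(observed counted); loci monomorphic in the current population subset
are untestable and excluded.  Stage two scores each locus by |Pearson
r| between population frequencies and the environmental PC1, with a
null from permutations of the environment vector shared across loci.
Both p-value sets get Benjamini–Hochberg q-values; an outlier needs
q < 0.05 in *both* stages.  Note the BH floor: with n_null null draws
the smallest attainable p is 1/(n_null+1), so detecting k planted loci
among L requires roughly `n_null ≳ L/(0.05·k)`; the experiment
defaults are sized accordingly.  The population-count experiment draws
its locus subsample once (shared across levels and replicates — the
natural reading of a fixed SNP panel), then scans subsets of 5, 10,
20, 30, … populations with 10 replicates each, recording max locus
F_ST, outlier counts, ids, and cross-replicate intersections.

Ground truth for power checks comes from `plant_env_clines`, which
replaces the last k loci with binomial genotypes around a logistic
cline `1/(1+e^{−s·z})` in the standardised environment (documented,
seeded, so true and false positives are countable).

## Problem sizes used in the checks

Per-locus draws are i.i.d., so means are pinned by modest locus
counts.  The calibration checks simulate both 50-deme models with
3,000 ascertained loci (Monte-Carlo SE of mean Hs ≈ 0.004, far inside
the ±0.05 calibration band); the directional and variance properties
run on a seeded 16-deme dataset (12 diploids × 300 loci) with 200
replicates per design; the trade-off comparison uses a 16-deme
isolation-by-distance dataset with 150 replicates; MRM null
calibration uses 500 datasets × 200 permutations; the ascertainment
limit check uses 10⁵ single-deme loci; the outlier experiment runs 5
seeded datasets × 3 levels × 10 replicates with 400 loci (20 planted),
1,500 differentiation nulls and 800 environment permutations.
`scripts/acceptance.py` re-simulates both models at 3,000 loci
(`--n-loci` raises this).

## What the synthetic data does and does not capture

The generator reproduces hierarchical structure, deme heterogeneity,
inbreeding, SNP-array-like ascertainment, pooled data, and planted
IBD/CAH/selection signals with known truth — the features the
subsampling conclusions depend on.  It does not model linkage
(loci are exchangeable and unlinked), sequencing error or missing
data in the simulated output (missingness enters only through
user-supplied data), chip-specific ascertainment beyond a frequency
band, selection during the simulation itself (planted clines are
post-hoc deformations), or recombination.  Conclusions about axes
whose real-data behaviour is driven by those features — e.g.
missingness-induced F_IS artefacts in empirical genotyping — are
supported only insofar as the fixation mechanism captured here is the
dominant one.

## Known limitations

The low-gene-flow model's mean Hs sits ≈ 0.23, below the ≈ 0.32 a
comparable published simulation reports, and the two regimes differ
little in Hs (their F_ST difference is the robust signal); the
discrepancy is insensitive to every defensible reading of the model
description we tested and is documented where the calibration check
runs.  The beta-binomial differentiation null ignores hierarchical
structure (it is exchangeable across populations), so under strong
two-cluster structure its tail is conservative for within-cluster
outliers and anticonservative for cluster-aligned clines; the joint
q-value rule with the environmental test is what keeps the scan's
false-positive count near zero in the null calibration.
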