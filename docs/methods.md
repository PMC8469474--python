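# Methods

This note documents the models, numerical choices and known limitations of
`asmb`. It is written for users deciding whether the package's inferences
apply to their data, and for maintainers wondering why something is the way
it is.

## β-diversity

Bray–Curtis dissimilarity is computed on counts, BC = Σ|x−y| / Σ(x+y),
which requires the table to be rarefied to a common depth first (rarefaction
uses exact multivariate-hypergeometric sampling without replacement, seeded).
Weighted UniFrac weights every branch by the absolute difference in the
relative abundance of its descendant tips; the **normalized** variant
(default) divides by the branch-length-weighted total abundance so values
fall in [0, 1] and sit on the same scale as Bray–Curtis similarities. Both
metrics are validated against naive per-element / per-branch reference
implementations to 1e−10.

Abundant and rare OTUs are defined by relative-abundance thresholds
(abundant ≥ 0.1%, rare ≤ 0.01%). The default `pooled` mode applies the
thresholds to an OTU's share of the pooled reads; `every_sample` mode
requires the condition in each individual sample. The pooled reading is the
default because the per-sample reading makes the abundant set collapse to
cosmopolitan dominants only; both are exposed because the field uses both.

## Null models and process classification

**βMNTD** between samples A and B is the abundance-weighted mean patristic
distance from each taxon to its nearest taxon in the other sample,
symmetrized: ½[Σ_{i∈A} f_iA·min_{j∈B} d(i,j) + Σ_{j∈B} f_jB·min_{i∈A} d(j,i)].
An `exclude_conspecifics` flag removes the zero-distance self-match of taxa
present in both communities; without it, βMNTD between communities sharing
their dominant taxa is pinned near zero and the selection signal of
cosmopolitan (abundant) subsets cannot be resolved. A one-taxon sample whose
only taxon is its own nearest neighbour falls back to the self-match rather
than returning an undefined value.

**βNTI** standardizes observed βMNTD against a null built by shuffling tip
labels across the whole supplied tree — equivalently, permuting the rows
and columns of the patristic matrix — holding every sample's abundances and
occupancies fixed. The tree passed in defines the regional pool. Pairs whose
null standard deviation is zero (possible on trees with few distinct
distances, e.g. a two-tip cherry where every shuffle is an automorphism)
are flagged `degenerate`, get a NaN score, and are excluded from process
fractions rather than propagating NaN.

**RC_Bray** builds, per sample pair, null communities that preserve each
sample's observed richness and read total: taxa are drawn from the regional
pool without replacement with probability proportional to occupancy
frequency (via exponential sort keys), and reads are then allocated
multinomially with probability proportional to regional relative abundance.
RC = 2·[(#null BC < obs) + ½·(#null BC = obs)]/n_rand − 1 ∈ [−1, 1]; ties
are detected at 1e−12.

Each pair is classified: βNTI > 2 variable selection, βNTI < −2 homogeneous
selection; otherwise RC < −0.95 homogenizing dispersal, RC > 0.95 dispersal
limitation, else undominated. Scores **exactly at** a cutoff fall to the
stochastic/undominated side (strict inequalities for the extreme classes).
999 randomizations is the conventional default; the validation suite uses
199 to keep runtimes low, which widens the score granularity but not its
calibration.

**Calibration caveat.** On neutral well-mixed communities (no selection,
unlimited dispersal) βNTI behaves like a z-score: |βNTI| > 2 fires at ≈ 5%
of pairs. RC_Bray does not: samples drawn multinomially from one common
pool are systematically *more* similar than the richness-constrained null,
whose random exclusion of moderately abundant taxa inflates null
dissimilarity, so nearly all pairs return RC ≈ −1. In the Stegen-style
framework this is precisely the homogenizing-dispersal signature of a
well-mixed metacommunity; users should read RC as a comparison against the
stochastic-assembly null, not as a calibrated test whose null is "my data
are neutral multinomial draws". The acceptance suite documents both
behaviours with measured rates.

## Distances and distance decay

Spatial distances are haversine great circles on a sphere of radius
6371.0088 km; at transect scale the error versus ellipsoidal geodesics is
below 0.5%, and the values are standardized before regression anyway.
Environmental distance z-scores every variable across samples (sample sd,
ddof = 1), averages the z-scores within each of the six environment groups
into one composite per group (a transparent, testable choice for the
"normalized combination"; a PCA composite was considered and rejected as
harder to validate), and takes the Euclidean distance over the composite
vector. Constant variables are dropped with a warning.

Distance-decay fits regress the vectorized upper triangle of a similarity
matrix on the standardized (zero-mean, unit-sd over pairs) distance
triangle by OLS; the slope is the turnover rate per standardized-distance
unit, comparable between spatial and environmental axes. Because pairs
sharing a sample are not independent, significance comes from the Mantel
test (Pearson r, simultaneous row/column permutation, two-sided
p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm)), not from the OLS t-statistic.

Slope comparisons between two sample groups pool the within-group pairs
into similarity ~ distance × group and test the interaction coefficient by
permuting group labels **at the level of whole samples**, recomputing the
within-group pair sets each time. Pair-level permutation would be
anticonservative for the same non-independence reason. The classical OLS
Wald p is also reported for reference. Empirical type-I error of all
permutation tests in the package is verified at 0.05 ± 0.03 over 500
exchangeable-null replicates.

## Variation partitioning and driver importance

Variation partitioning uses multiple regression on distance matrices over
vectorized triangles: r²_full = R²(β ~ env + spa), a = r²_full − R²(β ~ spa),
c = r²_full − R²(β ~ env), b = r²_full − a − c, d = 1 − r²_full. This
reproduces the four-fraction structure of partial redundancy analysis while
staying exactly testable (a + b + c + d = 1 is an algebraic identity,
asserted to 1e−9); a db-RDA variant on PCoA axes is deliberately out of
scope. The stored fractions are the raw decomposition — the shared fraction
b may legitimately be negative — and only the deterministic/stochastic
percentages floor the unique fractions at zero:
deterministic% = 100·a/(a+c), stochastic% = 100·c/(a+c). The shared
fraction is excluded from the percentages because it cannot be attributed;
it is reported so users can recompute alternatives. Both raw and
Ezekiel-adjusted R² are emitted since conventions differ. Exactly collinear
predictors are flagged (`collinear=True`) instead of erroring.

Random-forest importance fits a regression forest (default 500 trees,
mtry = p/3, min leaf 5 — the R `randomForest` conventions) to the
vectorized β-diversity with one column per predictor distance matrix, and
scores each predictor by the mean percentage increase in out-of-bag MSE
when its column is permuted (%IncMSE), computed per tree from the
bootstrap complements. scikit-learn does not expose OOB permutation
importance, so it is computed here directly from
`estimators_samples_`; results are deterministic given the seed.

## Group tests and niche breadth

PERMANOVA, ANOSIM and PERMDISP are scikit-bio's implementations operating
directly on the dissimilarity matrix; PERMDISP defaults to distance to the
group **centroid** (the simpler contract; spatial median behind a flag).
MRPP is implemented here: δ = Σ (n_g/N)·mean within-group dissimilarity,
A = 1 − δ/E[δ_perm], left-tail permutation p. The per-taxon-group layer
contrast uses a paired sign-flip permutation of per-site relative-abundance
differences (topsoil − subsoil) — distribution-free, exact under the
paired-null, two-sided.

Levins' niche breadth B_i = 1/Σ_j p_ij², with p_ij the share of OTU i's
reads found in sample j, ranges from 1 (single sample) to the number of
samples (uniform occupancy) and is invariant to scaling an OTU's counts.
Community breadth is the **unweighted mean** of B over the subset's OTUs
(matching the per-species output of the classical niche-width utilities
averaged to community level); an abundance-weighted mean is available
behind a flag because the aggregation is not standardized in the field.
Layer contrasts use paired t-tests over OTUs present in both layers; class
contrasts use one-way ANOVA plus Tukey HSD with a compact letter display
(insert-absorb algorithm) at α = 0.05.

## Synthetic transect generator

The generator emulates the post-processing output of a two-depth grassland
transect survey: `n_sites` (default 32) sites on a jittered 1500-km line,
two records per site (topsoil/subsoil), 17 environmental variables in six
groups, a pure-birth phylogeny with exponential branch lengths, a lognormal
regional abundance distribution (meanlog 0, sdlog 2 — the top decile of
OTUs carries well over half the reads, as in real rank-abundance curves),
and fixed-depth multinomial sampling (default 5000 reads), which matches
rarefied tables exactly (every row sum equals the depth).

Mechanism: each OTU's niche optimum evolves by Brownian motion on the tree
(rate 1 by default, giving the phylogenetic signal βNTI needs) and is
min-max rescaled to [0, 1]; expected abundance at a sample with
environmental position e is λ_i · exp(−w(e − opt_i)²/(2σ²)) ·
exp(−d_km/dispersal_range). Defaults w = 6, σ = 0.25, dispersal 600 km give
a mixed regime in which both selection and dispersal limitation are
detectable. `with_regime()` exposes the canonical validation regimes:
`neutral` (w = 0, d = ∞), `selection` (w = 12, d = ∞), `dispersal_limited`
(w = 0, d = 100 km).

Environmental variables are linear in the latent gradient plus two noise
components: a **group-coherent site anomaly** (sd = 3 per-variable noise
units) shared by all variables of a group, and independent per-variable
noise. The coherent component reflects how local topography or parent
material shifts a site's whole climate or mineral profile together; without
it every group composite is an affine function of transect position and
"which environmental group drives the community" is unidentifiable against
spatial distance. The per-layer driver is **exactly** the group composite
the environmental-distance module computes — contemporary climate for
topsoil, soil pH for subsoil, mixed by `layer_effect` — built from the
realized (noise-inclusive) values, so the group distance matrices are exact
proxies of the true driver and driver-recovery is a well-posed test.

What the generator does **not** emulate: depth-specific taxon filtering
beyond the driver switch (so between-layer PERMANOVA on the default
transect is weak), sequencing error and chimeras, overdispersion beyond
multinomial sampling, temporal dynamics, and any taxonomy. Passing the
recovery tests therefore shows the inference machinery is correct under a
known mechanism, not that real soil data satisfy that mechanism.

## Problem sizes used in validation

Oracle equivalence runs 50 fixtures of ≤ 10 tips × ≤ 6 samples. Null-model
calibration uses 10 transects of 20 samples × 200 OTUs at 199
randomizations; process recovery 16 samples × 150 OTUs; statistical
calibration 500 replicates per test at 199 permutations; driver recovery 10
seeds of 32 samples × 150 OTUs with 250 trees. These sizes were chosen so
the whole suite completes in a few minutes on one CPU while keeping Monte
Carlo error well inside the asserted bands; the acceptance script uses the
full default transect (64 samples × 500 OTUs, 999 randomizations) for its
end-to-end quantities.
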