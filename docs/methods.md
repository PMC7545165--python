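# Methods

This note records the models, defaults and numerical choices behind
`ecorare`, and what the synthetic-data suite does and does not
demonstrate about real data.

## Rarity indices and classification

Functional distinctiveness is the mean Gower distance of a species to
every other member of the pool, D_i = Σ_{j≠i} d_ij / (N − 1);
geographical restrictedness is R_i = 1 − K_i / K_tot on a binary
cell × species matrix. Both live in [0, 1] (R_i is at most
1 − 1/K_tot, since a species must occupy at least one cell).

Classification uses joint pool quantiles, by default the 25th/75th
percentiles with linear interpolation between order statistics.
The rare and common conditions are **strict** inequalities, so a
species lying exactly on a quantile is neither; the "average" class
(D below the upper and R above the lower quantile) leaves residual
corners of the bivariate plane — high-D/low-R and low-D/high-R species —
which are labelled "other". The four classes partition the pool.
Quantiles are computed on the analysed pool (species that survived
trait/tree/occurrence alignment), not on any larger candidate list.
Threshold sensitivity re-classifies at (0.30, 0.70) and (0.20, 0.80);
rare sets are nested across these by construction, and per-cell rare
richness is correlated across thresholds when an occurrence matrix is
supplied. The alternative lower thresholds mirror the upper ones
symmetrically; only the upper threshold is conventionally quoted
(D70R70, D80R80).

## Gower distances over mixed trait kinds

Per-trait dissimilarities: range-normalised absolute difference
(continuous), 0/1 mismatch (categorical), and half the Manhattan
distance between composition vectors (fuzzy super-traits such as diet
fractions — one trait, many columns). Traits combine as a weighted
mean, so rescaling all weights together changes nothing. A trait
missing for either member of a pair is skipped for that pair (its
weight leaves the denominator); a pair sharing no observed trait is an
error rather than a silent zero. A continuous trait that is constant
across the pool contributes dissimilarity 0 — the range normalisation
would otherwise divide by zero. This is a plain Gower contract; mixed-
variable frameworks with other per-kind scalings (e.g. ordinal ranks,
Chi-square for fuzzy blocks) would shift distances slightly but keep
the same [0, 1] semantics.

## Ordination

PCoA eigen-decomposes the double-centred squared-distance matrix
(delegated to scikit-bio, `method="eigh"`). Gower matrices need not be
Euclidean; negative eigenvalues are dropped — no Cailliez or Lingoes
correction — and variance proportions are computed over the positive
eigenvalues only. Axis retention uses the broken-stick rule: keep the
leading run of axes whose relative eigenvalue is at least
(1/p) Σ_{i=k..p} 1/i. The comparison is `>=` (within 1e-12): with a
single positive eigenvalue the broken-stick share equals 1 exactly and
the axis must still be retained, while perfectly equal eigenvalues
still retain nothing. Which axes to *plot* is treated as reporting;
`axis_distinctiveness_correlation` ranks axes by their correlation with
D_i but no inference hangs on it.

## Curveball null model and SES

Each elementary step picks two grid cells uniformly at random, collects
the species present in exactly one of the two, and re-deals those
presences uniformly between the cells, preserving both cells' richness
and every species' occupancy exactly. The default chain length is
5 × the number of cells (trade attempts), following published mixing
guidance for the algorithm; on the enumerated state spaces of small
matrices the chain's long-run visit frequencies are statistically
uniform (tested at α = 0.01 with 50,000 thinned samples). Each null
matrix is an independent chain restarted from the observed matrix, not
a thinned single chain. Rarity class labels are frozen during
randomization. SES uses the sample standard deviation (ddof = 1) of the
null counts; cells with null sd = 0 get NaN and are excluded from
summaries. Because the null conserves total rare presences, per-cell
SES values are weakly negatively correlated; the self-consistency check
(a null draw scored against the null) therefore uses the a-priori band
|mean| < 0.2, sd ∈ [0.8, 1.2] rather than exact 0/1.

## Fritz–Purvis D

d_obs sums |nodal difference| over all edges, with internal node values
estimated tips-to-root as the mean of direct children. Two null
ensembles of equal size calibrate the scale: tip-label permutations at
fixed prevalence (d_R) and Brownian traits (σ² = 1, variance
proportional to branch length) thresholded so that exactly the observed
number of tips is labelled 1 (d_B). Then
D = (d_obs − mean d_B) / (mean d_R − mean d_B); a vanishing denominator
(degenerate tree or prevalence) is an error, as is a monomorphic trait.
On a 64-tip pure-birth tree, 200 replicate traits give mean D within
±0.02 of 1 (random) and 0 (Brownian-threshold) at 1000 null draws each;
traits confined to one clade score well below 0. Over a tree ensemble,
each tree's RNG stream derives from the master seed and the tree index,
so a single tree's value can be reproduced in isolation (which also
means a tree duplicated at two positions is scored with two independent
streams).

## Evolutionary distinctiveness

Fair proportion divides each edge length by its number of descendant
tips and sums along the root-to-tip path; tip values sum exactly to the
total branch length. Equal splits instead divides each edge by the
product of split sizes between it and the tip. Fair proportion is the
default; both variants match R `picante::evol.distinct` to 1e-6 on a
fixture tree (frozen in the test suite). Class comparisons of ED use
the same rank machinery as the conservation module; classes with fewer
than two members are summarised but excluded from testing.

## Gap analysis and group comparisons

Targets are affine in log range size — t = 1 + (0.1 − 1)·(log A −
log A_min)/(log A_max − log A_min) — pinned at 100% for the
smallest-ranged species and 10% for the largest; the natural log is
used but the mapping is base-invariant. Achievement is protected
fraction divided by target, **capped at 1** (standard in the
gap-analysis lineage; an uncapped ratio would let over-protected
widespread species dominate class means). Targets are meant to be
computed per taxon pool, since pools differ in range-size distributions.
Status regrouping is the exact three-way map CR/EN/VU → TH, LC/NT → LC,
DD/NE → NE, total on that vocabulary and failing loudly otherwise.
Group comparisons use tie-corrected Kruskal–Wallis plus pairwise
two-sided Mann–Whitney tests with Bonferroni adjustment (deliberately
conservative), summarised as compact letters via insert–absorb. A
one-way ANOVA with Tukey HSD is a near-equivalent parametric
alternative for approximately normal indices; the rank version is kept
because achievement and covariate means are bounded and skewed.

## Synthetic pools: what they emulate, and what they do not

Defaults: 200 species on a 20 × 20 grid (the real analyses run at
~6 × 10⁴ cells; 400 keeps the suite fast while preserving the regime
where most R_i are near 1); occupied-cell counts log-normal with
log-mean log 8 and log-sd 1.2 (median range 2% of cells, strongly
right-skewed); ranges grown as contiguous patches by breadth-first
accretion from a seed cell, preserving the spatial coherence the SES
analysis implicitly assumes; four Eltonian-style traits (10-component
Dirichlet(0.3) diet, standard-normal log body mass, 3-level activity,
5-level foraging height); cell area fixed at 50 × 50 km = 2500 km² to
convert occupancy to range size; a contiguous block of 15% of cells
flagged insular; pure-birth trees with tip edges extended by the
waiting time to the next birth event so branch lengths stay positive
and ultrametric; covariate grids as Gaussian-smoothed noise (σ = 2
cells), giving positive lag-1 spatial autocorrelation; threat
probability increasing in restrictedness rank (0.05 + 0.55·rank³), so
rare species are enriched for TH status as in real assessments.

Deliberately absent: real coastlines and water-cell filters, GIS
projections and polygon ranges, trait–phylogeny covariance (traits are
drawn independently of the tree, so the rare class on synthetic pools
is genuinely phylogenetically random), trait–range covariance, and any
climate or land-use dynamics. Passing tests on these pools shows the
*operations* are correct and internally consistent — marginals
preserved, indices at their limiting values, planted effects recovered
— not that any particular empirical pattern (hotspot locations, threat
percentages) would replicate on licensed global datasets.

## Determinism and problem sizes

All randomness flows through `numpy.random.Generator` seeded from
explicit integers (generators use fixed substream tags under the pool
seed; the pipeline derives per-stage streams from the master seed, and
tree generation uses Python's `random.Random` inside dendropy).
Fixed seeds give bit-identical tables. The test suite and acceptance
script use the protocol sizes stated above (200-replicate D
calibration with 1000-draw nulls, 500 SES randomizations, 50,000
curveball samples) and complete in well under a minute each on one CPU.
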