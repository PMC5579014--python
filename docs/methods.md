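# Methods

`seapan` implements the inference chain used in seascape genetics to test
whether oceanographic dispersal barriers leave a genetic signature, or
whether a species is effectively panmictic across them.  The chain has an
oceanographic arm and a genetic arm that meet in a model comparison:

1. passive particles ("larvae") are advected through daily velocity
   fields and their beaching events define an asymmetric connectivity
   matrix of mean transport times between coastal cells;
2. shortest multi-leg paths over that matrix give a stepping-stone
   connectivity matrix; percolation plus leading-eigenvector community
   detection partitions the coast into oceanographic regions, and barrier
   strength quantifies the % reduction in connectivity between regions;
3. mitochondrial sequences and microsatellite genotypes are summarised
   with standard population-genetic statistics (diversities, Phi_ST /
   AMOVA, SAShA, Weir–Cockerham theta, Jost's D, shared-allele NJ tree);
4. linearized genetic distance F/(1−F) is regressed on stepping-stone
   transport time and on shortest marine distance, and the models are
   ranked by AIC and adjusted R².

Everything runs on synthetic inputs with known ground truth, so each
stage's statistical behaviour is testable without any data download.

## Seascapes and velocity fields

A `SeascapeGrid` is a regular cell grid (cartesian km for tests,
geographic degrees with `cos(latitude)` zonal scaling for realism) with a
land/sea mask.  **Coastal cells** are sea cells with at least one land
cell among their 8 neighbours, enumerated in row-major order; this
adjacency rule is our convention — gridded-coastline studies rarely state
one — and it is fixed and tested.

Velocity series are composed from analytic ingredients: uniform drift,
zonal jets (u a Gaussian of y, hence divergence-free), gyres derived from
a Gaussian streamfunction by central differences (the discrete divergence
of a discretely-differentiated streamfunction cancels exactly, which the
tests assert at 1e−6 of the field amplitude), and seeded daily Gaussian
cell noise.  Annual amplitude jitter and the noise give inter-annual
variability.  Fields are stored as xarray Datasets (netCDF3 via the scipy
engine) with dims `time × y × x`, variables `u`, `v`, `mask` and unit
attributes.

The **two-gyre study domain** (56 × 32 km, 1-km cells, land in the two
southern rows, 56 coastal cells) plants a dispersal barrier with known
truth: a clockwise western gyre and counter-clockwise eastern gyre
(Gaussian streamfunction, sigma 7 km, 0.4 m/s peak) make the alongshore
flows diverge at mid-shore, so advection alone never crosses the central
break; 0.04 m/s daily noise supplies rare cross-break transport, keeping
the connectivity graph connected while leaving the barrier strong.  These
amplitudes are of the order of real coastal surface currents.

## Lagrangian particle simulation

Particles are released every 12 h (configurable spawning window) from
every coastal cell with a uniform seeded within-cell offset, and advected
with explicit Euler at dt = 1 h (RK4 available) for at most 30 days.
Three conventions that verbal descriptions of such simulations leave open
are made explicit here:

- **Land interpolation**: velocity nodes on land are zero-filled before
  bilinear interpolation.  This is conservative — it slows particles near
  shore and promotes beaching.
- **Beaching** is an *entry event*: a particle beaches when it moves into
  a coastal cell it was not already in, after a 12 h grace period from
  release.  A particle that never leaves its origin cell therefore
  expires rather than instantly re-beaching; transport time is the
  first-entry hour / 24.
- A step that would land on a land cell is cancelled during the grace
  period (the particle holds position) and otherwise beaches the particle
  at the nearest coastal cell.

Trajectory positions never lie in land cells (asserted on every stored
path).  Per-release-time RNG streams make per-year runs independent and
order-insensitive.

**Numerical resolution caveat.**  With ~0.4 m/s currents and 1-km cells,
a 1-h Euler step moves a particle up to 1.5 cells; multi-day
recirculating trajectories pass near the gyre separatrix where small
integration differences grow (Lagrangian chaos).  Halving dt therefore
shifts the exact beaching cell of a substantial fraction of long-drifting
particles by 1–2 cells — an intrinsic property of recirculating flow at
this resolution, not of the integrator implementation.  What is stable
under dt refinement, and what region detection actually consumes, is the
fate mix and the shore side of each beaching; the stability test asserts
those at the 95% level.  Users who need cell-exact trajectories should
use the RK4 option or a finer dt.

## Connectivity and regions

`T[i, j]` is the arithmetic mean transport time of particles from cell i
beaching at cell j; `N[i, j]` the count.  Undefined entries are explicit
missing (never 0 or infinity).  Years are combined by the
particle-count-weighted mean (equivalent to pooling; an unweighted
per-year mean is available behind a flag).

Stepping-stone connectivity is all-pairs shortest paths over the directed
transport-time graph (Floyd–Warshall via `scipy.sparse.csgraph`).
Region detection then operates on the stepping-stone matrix: edge
strength is 1/T on the graph symmetrized by taking the minimum transport
time per unordered pair (mean-time symmetrization is a config option);
percolation removes the weakest edges up to the maximal threshold that
keeps one connected component, realised deterministically as the
bottleneck strength of the maximum spanning tree (bridges can never be
removed).  Newman's leading-eigenvector algorithm splits the modularity
matrix recursively by the sign of its dominant eigenvector; recursion
stops when the gain is ≤ 1e−10, near-zero eigenvector entries join the
side of the group's lowest node id, and the number of regions is
emergent (a cap is available but off by default).  Significance comes
from size-preserving random membership assignments with the +1/(n+1)
permutation correction.  Barrier strength from region i to j is
`100 · (1 − connect_ij / within_i)` where `connect_ij` counts cells of i
with at least one beaching into j and `within_i` counts cells of i
connected (self-recruitment included) to their own region; rows with no
internal connectivity are undefined with a warning.

## Genetic statistics

The synthetic genetic generator is a forward Wright–Fisher finite-island
model: demes of N diploids exchange migrants at per-copy rate m (uniform
source among the other demes).  The mitochondrial locus is haploid (N
copies per deme, 615 bp, per-site mutation 2e−5 per generation, chosen so
per-population haplotype and nucleotide diversities fall in the range
typical of marine mtDNA surveys, h ≈ 0.5–0.9 and pi ≈ 0.001–0.006);
microsatellites are diploid (7 loci, strict stepwise ±1 mutation at 5e−4
per copy).  Defaults are 4 demes × 50 diploids, 500 generations (10 N,
enough for drift–migration equilibrium at these sizes), 30 sampled
individuals per deme on a ~2,000 km coastal transect.  One master seed
fans out through `numpy.random.SeedSequence`.  The generator emulates
equilibrium island-model structure only — no selection, recombination,
demographic history, or realistic spatial migration kernels — so passing
calibration tests demonstrates correct statistical behaviour under those
idealised conditions, not robustness to demographic complications in
real data.

Sequence statistics: haplotypes are exact normalized-string classes
(ambiguity codes included); polymorphic sites count columns with ≥ 2
unambiguous nucleotides; h and pi follow Nei (1987) with his variance
formulas; pairwise distances are counts of differences with pairwise
deletion of non-ACGT sites (a Tamura–Nei-style model distance is
deliberately out of scope; for the distance-based statistics used here
the difference is marginal).  Phi_ST is the among-population fraction of
the distance-based variance decomposition; two-population values are
tested by permuting individuals between the pair, and the p matrix gets
Benjamini–Hochberg FDR (parameter-free and conservative relative to
Storey's q-value).  Negative Phi_ST is reported unclipped.  The
hierarchical AMOVA uses the three-level sums of squared deviations with
unequal-size coefficients and stratum-specific permutation schemes
(individuals among populations; individuals among populations within
groups; whole populations among groups).  When the total variance is
exactly zero the convention is 100% within populations and Phi = 0.
SAShA compares the mean geographic distance between same-haplotype pairs
(OM) with the all-pairs mean (EM); the permutation test reassigns
haplotypes to individuals and is two-sided on OM − EM.  Distances are
great-circle km (Euclidean in cartesian mode); permutation p-values are
made row-order invariant by canonicalising individual order before
permuting.

Microsatellite statistics: unbiased expected heterozygosity with the
2n/(2n−1) correction; F_IS = 1 − Ho/He (0 when He = 0; the
Weir–Cockerham f estimator is not used for the per-population table),
tested against HWE by permuting allele copies within population and
locus with a two-sided multi-locus F_IS statistic; allelic richness by
hypergeometric rarefaction on gene copies; Weir & Cockerham's theta as
the multi-locus, multi-allelic ratio of sums of the a/(a+b+c) variance
components; Jost's D_est per locus with Nei–Chesser small-sample
estimators, combined across loci by the harmonic mean (falling back to
the arithmetic mean when any per-locus D ≤ 0, where a harmonic mean is
undefined).  Both differentiation statistics get 95% percentile CIs from
bootstrapping loci; a pair is called non-significantly differentiated
when its CI spans 0.  The shared-allele distance between populations is
1 − mean over loci of Σ_a min(p1_a, p2_a), and the NJ tree comes from
scikit-bio.  Loci with more than 5% missing genotypes are flagged for
exclusion (a logged filter, never silent).

## Isolation by distance

Marine distances are shortest over-sea paths on the 8-connected sea graph
(orthogonal steps cost one cell, diagonals √2 cells; geographic mode uses
great-circle edge lengths), by Dijkstra from snapped sites.  The
stepping-stone predictor between sites is the minimum of the two directed
path times between their nearest coastal cells.  OLS fits of F/(1−F) on
each predictor report slope, adjusted R² and Gaussian AIC (statsmodels
conventions); models are ranked by AIC.  Pairwise distances are not
independent observations — the plain linear fit mirrors standard seascape
practice, and a Mantel permutation option for the slope is available but
off by default.

## Problem sizes and defaults

Resampling defaults mirror the standard protocol for these analyses:
10,100 permutations for Phi_ST and AMOVA, 1,000 for SAShA, 10,000 for the
HWE test and the modularity randomization, 1,000 bootstraps for theta /
Jost's D and 999 for the NJ tree.  The demo configuration and the
calibration runs shrink the resampling counts and the particle budget
(two years of a 60-day season, two particles per 12-h release, ~9,400
particles) so the whole chain completes in minutes on one CPU; the
statistical conclusions they support (type-I error, parameter recovery,
barrier detection) are all scale-robust and asserted over 20 seeds where
distributional claims are made.

## Known limitations

- The island model has no geography in its migration matrix, so the
  structured genetic datasets carry no isolation-by-distance signal; the
  model-comparison power property is therefore established on synthetic
  responses generated from the transport-time matrix directly.
- Percolation assumes the connectivity support graph is connected and
  errors otherwise (naming the components) rather than analysing
  components separately.
- Beaching, land-interpolation and release-offset conventions are choices
  (documented above); real-world beaching behaviour is biological, not
  numerical.
- Substitution-model selection, Bayesian clustering, median-joining
  networks and null-allele diagnostics are out of scope.
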