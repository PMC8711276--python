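# Methods

## The occupancy model

The core of the package is a hierarchical Bayesian occupancy model for a
species observed on a raster grid. For each valid cell *i*,

    Z_i ~ Bernoulli(pi_i)
    logit(pi_i) = X_i beta + rho_j(i)

where `X_i` is a row of standardized environmental covariates (intercept
first), `beta` the fixed effects, and `rho` an intrinsic conditional
autoregressive (iCAR) spatial random effect on the cell-adjacency graph.
The iCAR is an improper Gaussian Markov random field with precision
`L / V_rho`, `L` the graph Laplacian: conditionally, each cell's effect is
normal around the mean of its neighbors with variance `V_rho / n_j`
(`n_j` = neighbor count). Because the density is invariant to adding a
constant, `rho` is identified by a sum-to-zero constraint, enforced by
re-centering each MCMC sweep. Adjacency is rook (4-neighbor) by default,
queen optional; the graph must be connected (a flag keeps the largest
component otherwise).

Priors: `beta ~ N(0, 100 I)` (weakly informative, centered at zero with a
fixed large variance); `V_rho ~ Uniform(0, V_max)`. `V_max` defaults to ten
times the squared empirical logit of the observed prevalence, floored at
10 — a scale that comfortably dominates any spatial variance the data can
support — and is configurable.

### Sampler

The fit uses Polya-Gamma data augmentation (Polson-Scott-Windle): with
latent `omega_i ~ PG(1, psi_i)` the conditionals of `beta` and `rho` are
Gaussian, so the sampler is a pure Gibbs scheme with no tuning parameters:

1. `omega | beta, rho` — exact PG(1, z) draws via the Devroye
   alternating-series method (hand-implemented, numba-compiled; validated
   against the closed-form mean `tanh(z/2)/(2z)` and variance at z = 0).
2. `beta | omega, rho` — multivariate normal, dense Cholesky (p is small).
3. `rho | omega, beta, V_rho` — one block draw of all cells. The precision
   `diag(omega) + L / V_rho` is banded under row-major cell ordering
   (bandwidth = number of grid columns), so the update is an O(n b^2)
   banded Cholesky, then re-centering to sum zero.
4. `V_rho | rho` — inverse gamma with shape `(n-1)/2 - 1` and scale
   `rho' L rho / 2` (the iCAR has rank n-1), truncated to `(0, V_max)`,
   sampled by inverse CDF through the regularized incomplete gamma
   function.

Defaults: 2 chains, 20,000 iterations each, 25% burn-in, thinning 10
(1,500 retained draws per chain). All randomness flows from explicit
integer seeds; the per-iteration PG seeds are pre-generated from the chain
seed, so fits are bit-reproducible. Convergence is monitored by split
R-hat over the fixed effects and `V_rho`; `posterior_summary` refuses to
summarize when max R-hat exceeds 1.1 unless forced. The deviance
`-2 sum[y log pi + (1-y) log(1-pi)]` (logs clamped at 1e-12) is stored per
retained draw; DIC = D_bar + pD with pD = D_bar − D(posterior means).
Summary tables also carry the minimum bulk effective sample size (via
ArviZ) in their metadata, and fits serialize to compressed CSV draw tables
plus a JSON sidecar (`IcarFit.save` / `IcarFit.load`).

### Response construction

Occurrence records are reduced to a cell-level response: every valid cell
containing at least one presence point is 1, every other valid cell is 0
(presence/background at cell level). The cell size at which this happens is
a free parameter of the grid; nothing in the model ties it to a particular
resolution.

## Screening

Occurrences are spatially thinned by a greedy first-come rule: a record is
kept iff its great-circle (haversine, R = 6371.0088 km) distance to every
already-kept record is at least the minimum distance (default 1 km). The
retained count is order-dependent, which is why a specific count is not a
test target. Collinearity is screened by variance inflation factors,
`VIF_j = 1/(1 - R_j^2)`; exactly collinear columns are flagged undefined
(inf), and `select_predictors` drops the worst predictor and recomputes
until all VIFs fall below the threshold (default 10).

## Projection and change accounting

Suitability surfaces are the cellwise posterior **median** of
`inverse-logit(X beta + rho)` across retained draws. For the fitting grid
the fitted `rho` draws are reused; for novel grids (future scenarios) the
spatial effect is zeroed by default, since there is no principled transfer
of an intrinsic field to a new support. Coefficients without a matching
layer in the projection stack (e.g. anthropogenic predictors with no
future projection) must be dropped explicitly (`allow_dropped=True`),
mirroring the practice of projecting on the climate subset only.

Binarization uses the threshold maximizing sensitivity + specificity
(max SSS) over the observed scores, ties broken toward the smallest
threshold (the more inclusive range — conservation-conservative). Change
maps cross-classify present/future binary maps into gain (0→1), loss
(1→0), no-change (1→1) and no-occupancy (0→0); the four categories
partition the valid cells exactly. Areas are sums of per-cell projected
areas under a spherical South American Albers equal-area conic
(central meridian −60°, origin −32°, standard parallels −5°/−42°,
configurable), computed by the shoelace formula on projected cell corners
and cross-checked against a spherical-excess graticule oracle.

## Dispersal-constrained colonization

Suitability is rescaled to the integer 0–1000 scale; a configurable
threshold (conventionally 300/500/700) separates suitable from unsuitable.
Each step first decolonizes occupied cells that became unsuitable, then
colonizes unoccupied suitable non-barrier cells within the
short-distance-dispersal radius of an occupied cell with a
distance-indexed kernel probability. Distance is breadth-first rook
distance **through non-barrier cells only**: "strong" barriers are both
uncolonizable and opaque. Long-distance dispersal is deliberately absent
(the modelled species is highly philopatric). Recolonization of recovered
cells is allowed. Defaults: kernel (1.0,) at one cell, one step per
raster period, no maturity delay; every parameter is recorded in the run
log. Candidate cells consume seeded uniforms in row-major order, so runs
are reproducible.

Reference scenarios: *no dispersal* counts initially occupied cells that
remain suitable at **every** period (without dispersal a cell lost to
unsuitability cannot be regained); *unlimited dispersal* counts all
suitable non-barrier cells at the final period. These bracket the
simulated occupied count, and occupied + absent always equals the cell
total. Best/worst scenario selection ranks lexicographically on
(occupied desc, absent asc, unlimited desc, no-dispersal desc).

## Haplotype summaries and network

All genetic summaries use complete deletion: columns containing a gap or
any non-ACGT symbol are excluded from haplotype collapsing, the count of
segregating sites S, and nucleotide diversity alike, matching DnaSP's
default treatment. Haplotype diversity is Nei's unbiased estimator
`H = n/(n-1) (1 - sum p_i^2)`; its sampling variance (Nei 1987, eq. 8.12)
is also reported, because small mitochondrial surveys conventionally quote
H ± variance. Nucleotide diversity is the mean pairwise Hamming distance
over analyzed sites divided by their number.

The median-joining network starts from the epsilon-relaxed minimum
spanning network on Hamming distances (default epsilon 0, unit character
weights), then repeatedly adds the majority-consensus median of a node
triplet when it shortens the minimum spanning-tree length of the node set,
finally pruning medians whose removal leaves the length unchanged.
Determinism: triplets are visited in lexicographic label order, and
three-way per-site ties resolve to the first label's state. The network's
total length never exceeds the observed-haplotype MST length, with
equality exactly when no median is added.

## The synthetic generator

The generator emulates the study design, not real geography:

- **Landscapes** are Gaussian-smoothed white noise layers (kernel width =
  the autocorrelation range in cells, default 3), standardized to mean
  0 / SD 1, on a georeferenced grid (default 2.5-arc-minute cells). They
  reproduce the spatial smoothness of bioclim-style predictors but none of
  their physical semantics, cross-correlations, or coastline masks.
- **Spatial effects** are exact iCAR draws via the Laplacian
  eigendecomposition (zero mass on the constant eigenvector), centered to
  sum zero — O(n^3), intended for grids up to a few thousand cells.
- **Occurrences** are per-cell Bernoulli draws at the truth probabilities,
  i.e. the model's own sampling process; real occurrence data add
  detection error and sampling bias that these tests do not probe.
- **Alignments** are built from explicit haplotype definitions (site,
  state, count), so S, counts, H and pi are known by construction. The
  study-like fixture (14 sequences, 955 bp, counts (5,5,3,1), 17 variant
  sites in three clades) is a synthetic stand-in whose summary statistics
  — 4 haplotypes, S = 17, H = 0.747 with Nei variance 0.004 — mirror a
  small ND1 survey; its sequence content is random.

Passing tests on these fixtures demonstrates the estimators and
simulators are correct on data generated by their own assumed processes;
they say nothing about covariate measurement error, detection, or
phylogenetic signal in real surveys.

## Study conditions and problem sizes

The calibration study fits 20 replicate datasets on a 20 x 30 grid
(600 cells) with 4 covariates, beta = (−1, 2, −2, 1, 0.5), V_rho = 2, and
20,000 iterations per chain — small enough to run on one CPU in minutes,
large enough that the strong coefficients (|beta| = 2) are well identified.
Observed behavior at these conditions: 95% credible intervals cover each
true coefficient in ≥ 90% of replicates, and the sign of every coefficient
with |beta| ≥ 2 is recovered in all replicates. Coverage for smooth
covariates runs slightly below nominal because the iCAR field and
spatially autocorrelated predictors compete for the same signal (spatial
confounding); the posterior for V_rho is accordingly biased upward. This
is a property of the model class, not of the sampler: with the spatial
field suppressed, coverage is nominal.

## Numerical choices

- Logs in the deviance clamped at 1e-12; probabilities in [0, 1] enforced.
- Exact collinearity in VIF flagged at R^2 > 1 − 1e-10.
- max-SSS candidates are the distinct observed scores; classification is
  `score >= t`.
- Quantiles are numpy's default (type-7 linear interpolation).
- The banded Cholesky bandwidth is the maximum index offset between
  adjacent cells; masked grids remain banded under row-major ordering.
- Degenerate inputs: single-cell graphs give a zero spatial effect;
  all-0/all-1 responses warn and proceed; one-class responses are invalid
  for max-SSS.

## Known limitations

- The iCAR transfer to novel grids is by design unavailable (zeroed);
  nearest-cell resampling of `rho` is not implemented.
- The dispersal simulator has no propagule-production or age-structure
  sub-model beyond the hook for a maturity delay, and no long-distance
  dispersal.
- The median-joining implementation targets the small haplotype counts of
  mitochondrial surveys (tens of haplotypes); its median search is
  exhaustive over triplets.
- Albers projection uses the spherical Earth form; ellipsoidal areas
  differ by < 0.3%.
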