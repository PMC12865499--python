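# Methods

This package implements, as a tested pipeline over synthetic landscapes, a
climate-vulnerability analysis for range-restricted mountain plants: coarse
bioclimatic fields are reduced to two principal-component predictors and
statistically downscaled onto fine terrain, an ensemble of
presence/pseudo-absence models projects habitat suitability over four time
slices (current plus 2021–2040, 2041–2060, 2061–2080) under two emission
scenarios (SSP245 and SSP585), and the resulting suitability time series is
classified into persistence-area types — long-term refugia, holdouts and
stepping stones — with distance and positional summaries.

## The synthetic study system

Real analyses of this kind consume CHELSA-style bioclimatic rasters, a
resampled DEM and curated occurrence records. Here a seeded generator
stands in for all of them so that every downstream stage can be tested
against a known truth.

**Terrain.** The DEM is Gaussian-filtered white noise rescaled to a
configurable elevation range (default 0–3000 m) on a fine grid of 300 m
cells. The filter length scale (`relief_smoothness`, default 6 cells)
controls relief autocorrelation; in the infinite-smoothness limit the
terrain degenerates to a constant mid-range surface. The default analysis
grid is 48×48 fine cells — small enough that every test and the full
acceptance run finish in seconds, large enough to carry an elevation
gradient of several thousand metres.

**Climate.** Coarse climate cells are block means of the fine grid (factor
3, emulating ~1 km climate over 300 m terrain). Band 1 is temperature-like:
a 14 °C sea-level baseline plus a linear lapse of −6 K/km, plus a per-slice
warming delta, plus seeded Gaussian noise (sd 0.4 K). Default deltas are
[0.8, 1.4, 1.9] K for the moderate scenario (ssp245) and [1.0, 2.2, 3.6] K
for the pessimistic one (ssp585), i.e. mid-range CMIP6-like regional
anomalies over the three future slices. The remaining bands (19 by default,
mirroring the usual bioclim count) are affine transforms of the temperature
signal plus independent noise; the second half of the bands is additionally
scaled by a per-slice moisture trend (declining under both scenarios, more
under ssp585). Only band 1 carries a mechanistic elevation/warming
structure — that is sufficient to make the pooled PCA non-trivial while
keeping the generator transparent.

A deliberate design choice: the noise fields are derived from
(seed, slice, band) *without* the scenario, so the two scenarios form a
paired design that differs exactly by the configured deltas and trends.
Scenario-ordering properties (the harsh scenario is warmer at end of
century; a cold-adapted species retains at most as many refugia under it)
then hold deterministically per seed instead of only in expectation, which
keeps the property suite free of flaky stochastic comparisons.

**Niche and occurrences.** True suitability is a product of per-predictor
Gaussian kernels, maximal (at `max_prevalence`, default 0.9) at the niche
optimum. For pipeline species the niche lives in temperature space and
truth surfaces are computed from the noise-free fine-grid temperature, so
the truth is independent of the PCA/downscaling path it is later used to
check. Two convenience constructors cover the interesting cases: a *summit
specialist* whose optimum sits 1 K beyond the coldest cell on the map
(every cell is then on the warm side of the optimum and any warming strictly
lowers suitability everywhere), and a species centred at a chosen elevation.
Occurrences are drawn without replacement with probability proportional to
truth (exponential-keys weighted sampling), so the requested count is exact,
each cell appears at most once, and the empirical inclusion frequencies are
proportional to suitability.

**What the generator does not emulate.** No spatial autocorrelation in the
climate noise, no realistic bioclim variable definitions, no GCM structural
spread, no observation bias in the occurrences, no geographic CRS. Passing
tests therefore demonstrate the correctness and internal consistency of the
algorithms under the stated statistical structure — not predictive skill on
real mountain floras.

## Predictor preparation

**Physiography.** Slope and aspect come from the standard Horn 3×3
finite-difference stencil with replicated edges; aspect is measured in
radians clockwise from north and points downslope. Exposure enters as
northness = cos(aspect) and eastness = sin(aspect); flat cells (zero
gradient) have undefined aspect and get northness = eastness = 0, a neutral
convention. The irradiation proxy is a deterministic function of slope and
northness (1600 + 600·sin(slope)·(−northness) kWh/m², i.e. south-facing
steep slopes receive more direct irradiation in the northern hemisphere);
it stands in for a direct-normal-irradiation layer and is swappable via a
callback. Coast distance is planar Euclidean distance from each cell centre
to a coastline polyline (shapely), with the synthetic coastline a straight
line 12 km south of the grid — the study system it emulates is a coastal
mountain range with the sea to the south.

**Pooled PCA.** All slices and scenarios are pooled into one matrix of
valid cells × bands and reduced by a correlation PCA (bands standardised on
pooled mean/sd — bioclim-style bands have heterogeneous units; a covariance
PCA is available behind a switch). Every slice/scenario raster is projected
onto the same two axes, which is what makes current and future climates
comparable in predictor space. Zero-variance bands are dropped with a
warning. Axis signs are fixed so each axis's largest-magnitude loading is
positive.

**GWR downscaling.** Each coarse PC field is interpolated to the fine grid
by geographically weighted regression: for every fine cell, a weighted
least-squares regression of the coarse PC values on the six physiographic
covariates (block-mean aggregated to the coarse grid) with Gaussian kernel
weights w = exp(−d²/2b²) over coarse-cell centres, evaluated at the fine
cell's own covariates. The bandwidth b is fixed at 5 coarse cells by
default and exposed in configuration; no adaptive (AICc) bandwidth
selection is attempted. Covariates are standardised on pooled fine-grid
statistics to keep the local solves well-conditioned, and covariates with
(near-)zero variance are dropped — on a planar or constant landscape the
regression simply uses fewer terms. A singular local normal matrix falls
back to a ridge-stabilised solve (λ = 1e−8·trace), then to the local
weighted mean. Predictions are clipped to the coarse-field range widened by
a configurable fraction (default 1.0, i.e. one full range width on each
side) as a guard against local-regression extrapolation; the guard can be
disabled. Exactness properties hold by construction and are tested: a
constant coarse field reproduces exactly, and a coarse field exactly linear
in elevation reproduces the same linear function of fine elevation to
numerical tolerance.

## Suitability modelling

**Data assembly.** Occurrences are thinned to one record per grid cell
(first record in input order wins — a stable, reproducible tie-break).
Pseudo-absences are sampled uniformly without replacement from all
non-presence, non-nodata cells; no exclusion buffer is applied. The
configured contract is 10 sets of 10,000 locations; on desk-scale grids the
per-set count is automatically reduced to the number of candidate cells
with a warning. Evaluation uses repeated stratified split-sample
cross-validation: presences and absences are split separately, 70%
training (floor) / 30% evaluation, 10 repeats by default.

**Members.** Three member families are implemented:

* *Surface range envelope (SRE)* — per-predictor empirical quantile
  intervals [q, 1−q] of the training presences (default q = 0.025); a cell
  scores 1 iff it falls inside every interval, else 0.
* *logistic_poly2* — maximum-likelihood logistic regression on the degree-2
  polynomial expansion [x₁, x₂, x₁², x₁x₂, x₂²] of the standardised PC
  predictors, fitted by IRLS (statsmodels GLM). Complete or quasi-complete
  separation falls back to a small-L2 penalised fit (scikit-learn, C = 1)
  and is flagged on the model object.
* *boosted_trees* — gradient-boosted classification trees
  (scikit-learn, 100 trees, depth 3), available but off by default.

The original workflow used five algorithm families through an external
modelling framework with automatic hyperparameter tuning; this package
specifies the envelope and logistic members exactly and treats boosted
trees as an established-library contract rather than re-implementing
machine-learning internals.

**Evaluation.** AUC is computed in the Mann–Whitney rank form (ties earn
half credit). TSS is the maximum over candidate thresholds of
sensitivity + specificity − 1, where candidates are the distinct score
values, a cell is predicted present when its score ≥ the threshold, and
ties on the maximum go to the smallest threshold. Both metrics are checked
exactly — including tie handling — against O(n²) pair counting and an
exhaustive threshold sweep.

**Ensemble.** How dozens of member fits collapse to one suitability surface
is not prescribed by the workflow this package mirrors; the committee rule
adopted here, common in the ensemble-SDM literature, is the unweighted mean
over all members whose held-out TSS reaches a cut-off (default 0.4), with
binary members contributing 0/1 and the result clipped to [0,1]. The
cut-off is configurable; if no member passes, the error lists every
member's TSS.

Habitat suitability is reported on the [0,1] scale throughout; multiply by
1000 for the 0–1000 display scale some SDM toolchains print.

## Persistence-area typing

A cell is *suitable* at a slice when HS strictly exceeds the threshold
(default 0.5); HS = 0.5 exactly is unsuitable. Over the three future
slices:

* **refugium** — suitable in all three;
* **holdout** — suitable in exactly two (refugia take precedence, making
  the categories disjoint); current-slice suitability is recorded but not
  required for either;
* **stepping stone** — a non-occurrence cell adjacent (8-neighbour by
  default, 4 configurable) to at least one occurrence cell, suitable at
  the first future slice, with an adjacency chain to a cell suitable at
  the second slice and onward to one suitable at the third. A cell may
  serve consecutive slices itself (self-chains allowed) — the alternative
  reading requiring distinct cells per slice is supported by the same
  machinery but not default.

Per-cell categories partition every valid cell with precedence
refugium > holdout > stepping stone > none. Because stones are by
definition non-occurrence cells, mapping them back to populations requires
a convention: an occurrence whose own cell is neither refugium nor holdout
is counted as *served* by stepping stones when at least one adjacent cell
is a stone. Category percentages are taken over all occurrences of the
species.

Nearest-suitable distances are planar Euclidean between cell centres
(exact distance transform), reported in km, 0 when the occurrence's own
cell is suitable, and missing when no suitable cell exists on the grid.

## Summaries

All figure-level summaries are five-number boxplot statistics (linear
interpolation / type-7 quantiles) on tidy tables: suitability at occurrence
cells per species × slice × scenario (species ordered by mean occurrence
elevation), suitability by elevation band (default 250 m, half-open [lo,hi)
bins so an edge value joins the upper band), and the latitudinal offset
(km, north positive, relative to the median y of current occurrences) and
elevation of category member cells.

## Numerical and reproducibility choices

* Grids are row-major, row 0 north, cell-centre coordinates, planar metric
  CRS; all distances Euclidean metres. Rasters are exchanged as ESRI ASCII
  grids (plain text, one band per file, JSON sidecar for multi-band
  stacks), so every artefact of a run is diffable and GIS-readable.
* Every stochastic stage derives its own seed from the master seed and a
  tuple of stage tokens via SHA-256, so stages are independently re-runnable
  and the full pipeline is byte-reproducible from one integer.
* The desk-scale configuration (24×24 fine grid, 50 presences, 500
  pseudo-absences per set, 2 sets, 3 split repeats, both scenarios) is the
  reference smoke/determinism setting; the analysis scripts use 48×48 with
  two species and 5×5 member grids. These sizes were chosen so the
  pipeline remains a sub-minute object a test suite can run repeatedly.

## Known limitations

* The ensemble combination rule and the TSS inclusion cut-off are
  documented assumptions, not reproductions of the original workflow.
* No dispersal kernels or corridor analysis beyond the 3-link adjacency
  chain; stepping-stone service is a purely geometric notion.
* The GWR kernel form, bandwidth and covariate standardisation are package
  defaults; the workflow this emulates cites the method without
  parameters, so no claim of parameter-level equivalence is made.
* Synthetic truth lives in temperature space only; multi-dimensional
  niches are supported by the kernel machinery but not exercised by the
  default pipeline.
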