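# Methods

This note records the models implemented by `agroscape`, the defaults
and numerical choices behind them, and what the synthetic test fixtures
do and do not demonstrate.

## Spatial substrate

A landscape is a bounded, non-toroidal raster with 0-based (row, col)
indexing, row 0 at the north, and square cells of edge `resolution`
meters (default 10 m, so a 200×200 grid spans 2 km × 2 km). NoData
cells are outside the landscape for every metric and for placement.
Geographic bookkeeping lives only in the I/O layer: ESRI ASCII grids
carry the cell size in their header; GeoTIFFs carry it in the
ModelPixelScale tag and NoData in the GDAL_NODATA tag (written via
tifffile; non-square pixels are rejected on read).

## Potential space

**Pseudo-slope synthesis.** Classic lattice gradient noise (quintic
fade, random unit gradients per lattice node) is summed over `octaves`
layers with frequency multiplied by `lacunarity` (default 2) and
amplitude by `gain` (default 0.5) per layer, then min–max rescaled to
[0, 90]°. Rescaling over the generated grid means every map attains 0°
and 90° somewhere; the map is a terrain *surrogate*, not a
geomorphological model. Defaults (frequency 4, octaves 3) give
landscape-scale structure on grids of 50–200 cells per side.

**Thresholding.** Low values are farmable: `categorize_by_threshold`
keeps cells ≤ the cut-off; `categorize_by_share` keeps the ⌈share·N⌉
flattest valid cells, ties broken by row-major scan order so the
realized cover is deterministic and within one cell of the request
(exact for distinct values).

**Hybrid world.** `fit_hybrid` fits a single cell-wise binomial
logistic regression of the arable indicator on covariate rasters by
iteratively reweighted least squares (gradient-norm tolerance 1e-8,
100 iterations), treating cells as independent observations. A fit
whose coefficients exceed |30| with a vanishing gradient is flagged
non-converged: the optimum sits at infinity (perfect separation) and
finite coefficients are returned with a warning rather than an
exception. `apply_hybrid` draws one independent Bernoulli realization
of the fitted probabilities and applies synchronous strict-majority
smoothing: each sweep, a cell adopts the state held by a strict
majority of its (default 8, default 2 sweeps) in-bounds neighbors and
keeps its state on ties. Strict majority makes homogeneous regions
fixed points. Because the logistic fit is calibrated (expected
realized area equals the arable area), the clustering step is what
makes the potential space exceed current arable land: wherever the
local arable density is above one half — e.g. a suitability zone that
is mostly, but not entirely, farmed — the vote fills the whole zone.

## Linear features

Roads and rivers are least-cost paths on an 8-connected lattice with
per-cell costs in [1, 2]: `1 + slope/90` for roads (avoid steep
terrain) and `1 + (90 − slope)/90` for rivers (the slope map read as a
relief proxy, so rivers follow valleys). A step costs the mean of its
two endpoint cell costs, times √2 for diagonal moves; the search is
`skimage.graph.MCP_Geometric`, which implements exactly this weighting,
and its optimality is verified against an independent Dijkstra in the
tests. Random endpoints are drawn uniformly on a uniformly chosen pair
of opposite grid edges. Paths are widened to an odd width by Chebyshev
dilation and zeroed out of the potential-space mask (idempotent).
Both cost formulas are design choices — only "least cost over slope" is
inherent to the feature model — and are exposed as `cost_kind`.

## Field placement

Both algorithms draw per-field dimensions the same way. The field area
A (hectares) comes from a normal distribution truncated at one cell by
redraw (100 attempts, then clamped) or from a lognormal whose μ, σ are
moment-matched to the requested mean/SD. The shape ratio ρ ≥ 1
(length:width) is a truncated-normal draw. Cells are converted at
10⁴/resolution² cells per hectare, rounded half-up; the long axis is
`segment_length = round(√(A·ρ))` and the short axis
`n_segments = round(A/segment_length)`.

**Place-and-conquer** places fields one at a time (uniform free anchor,
uniform horizontal/vertical orientation) until the requested fraction
of the potential space is covered or no free cell remains. A field is a
stack of 1-cell-wide segments: the first grows through the anchor
(forward, then backward) to at most `segment_length` free cells; each
further segment sits on the next parallel line, at the offset that
maximizes 4-adjacency with the previous segment using only free cells
(ties toward the smaller offset). Growth proceeds on one side of the
first segment and switches to the other when a line offers no adjacent
free cell; the field stops at `n_segments`, at its target size, or when
both sides are blocked. Fields therefore never overlap, never leave the
mask, and are 4-connected by construction; truncated fields are kept,
so realized sizes reflect both the parameters and the constraints of
the space. The coverage stopping rule accepts the field that first
crosses the target, so realized coverage is within one field of the
request (the tests assert exactly this slack).

**Dead leaves** first covers the space with random rectangles
(dimensions from the same draws, uniform center and orientation, later
stamps occluding earlier ones) until every mask cell is covered or 10⁴
consecutive stamps cover nothing new; each surviving 4-connected
same-stamp region becomes one field (occluded fragments split). It then
deletes fields in increasing size order until the remaining cover is at
or below the request — pruning the smallest first avoids
over-fragmentation, and the tests assert min(kept) ≥ max(removed).

If a mask is exhausted before the requested coverage, a partial
landscape is returned with `coverage_shortfall=True` and a warning,
never an exception.

## Enrichment

Farmers are created sequentially; each draws its field count from a
uniform (parameterized as mean ± √3·SD so the stated mean/SD are
honored), normal, or moment-matched lognormal distribution, rounded and
floored at 1. Spatial mode claims a random unassigned field plus its
n−1 nearest unassigned fields by centroid distance; random mode draws
uniformly. The number of farmers is emergent and the last farmer may be
short. Crop allocation shuffles fields (seeded) and gives each field
the crop with the largest remaining area deficit; the per-crop share
error is bounded by the largest field's share of arable area, so finer
mosaics track a portfolio more closely. Raster views code crop/farmer
identities as sorted integer codes with a JSON legend sidecar; a field
cell is a border cell if any 4-neighbor lies outside its field, which
makes 1-cell-wide fields entirely border (conservative for
edge-sensitive analyses).

## Landscape metrics

Patch delineation defaults to 8-connectivity (4 available). Area
metrics use hectares; SDs use the population (N) denominator.
Perimeters count cell faces against anything outside the patch,
including the grid boundary; edge density is class edge length (m) per
landscape hectare. ENN is the minimum cell-center distance between
patches of the class, undefined (missing, never zero) with fewer than
two patches; per-patch shape index is 0.25·p/√a, perimeter–area ratio
p/a, fractal dimension 2·ln(0.25·p)/ln(a). LSI is 0.25·E/√A over the
whole class. Contagion uses the standard adjacency-entropy formula over
all classes present (4-neighbor adjacencies counted in both orders) and
is undefined for a single class. Metric dialects differ between
packages (connectivity rule, ENN edge-to-edge vs center-to-center), so
absolute values are validated against an in-repo direct-definition
oracle to 1e-9 rather than against any external catalogue.

Profile similarity is 1 − mean over metrics of
min(1, |g−r| / max(|r|, 1e-9)); clipping at 1 per metric keeps one wild
metric from dominating. 1 is a perfect match, 0 a complete mismatch.

## Calibration

A chromosome is a real vector over a subset of {noise frequency,
octaves, space share, coverage, mean/SD field size, mean shape} with
per-gene bounds. Fitness decodes the chromosome, generates
`replicates_per_eval` (default 3) landscapes with seeds derived from
(config seed, evaluation index, replicate), and averages the profile
similarity of the arable class against the reference; parameter
combinations that yield no fields or leave a requested metric undefined
score 0. The GA is conventional — population 20, tournament k=3,
uniform crossover 0.8, per-gene Gaussian mutation (p=0.1, σ=10% of the
gene range, clipped), elitism 1 — and elites keep their evaluated
scores, so the best-fitness trace is exactly non-decreasing even though
fitness is stochastic. The default optimized subset is
{np, area_mn, area_sd}: patch count and patch area are the standard
compositional handles. `generate_equivalents` reuses the calibrated
parameters with seeds `seed+i`, so one map with a known evaluation seed
reproduces that evaluation's landscape, and reports quartiles of both
optimized and held-out metrics — the held-out spread is the freedom the
calibration left.

Calibration is degenerate in the statistical sense: several parameter
combinations can match a two- or three-metric profile (e.g. fewer,
larger fields versus more, smaller ones at equal total cover). The
parameter-recovery test therefore fixes the space share, searches
{coverage, mean size} against a reference profile averaged over 20
truth maps (the expected profile, damping single-map noise), and runs
to fitness 0.95: under those conditions the truth coverage is recovered
within 0.1 and mean patch area within 25% in at least 8 of 10 seeds.

## Problem sizes and fixtures

Validation runs use 100×100 grids at 10 m (1 km × 1 km) for
calibration and pipeline checks, 50×50 for placement invariants, 20×20
for metric-oracle equivalence, and 30×30 for path optimality; these
sizes give stable statistics while keeping the whole suite quick, and
all inputs are generated programmatically. The hybrid-world fixture is
synthetic: a circular suitable zone, 70% of it "currently farmed", with
a noisy zone-indicator covariate. It demonstrates the clustering
mechanism, not the realism of any particular region — real covariates
(slope, soil, agricultural limitation classes) are continuous, spatially
autocorrelated and partially redundant, none of which the fixture
emulates. Likewise the gradient-noise terrain reproduces smooth,
isotropic relief only; sharply delimited terrain (fault lines, terraces,
floodplains) is outside what these tests can show, and external masks
or the hybrid route are the intended escape hatch.

## Known limitations

- The logistic suitability model ignores spatial autocorrelation of
  residuals; its standard errors would be optimistic (none are
  reported).
- Majority-vote smoothing is area-biased at probability ≈ 0.5: tiny
  imbalances tip whole regions.
- Place-and-conquer anchors are uniform over free cells, so late fields
  fill awkward remnants; field-size distributions are truncated by the
  space and will undershoot the requested mean at high coverage.
- Dead-leaves phase 1 may stall on masks with many 1–2 cell islands
  (stamp centers rarely hit them); the stall cap then leaves them
  uncovered.
- The GA has no convergence diagnostic beyond its fitness trace; for
  multi-modal targets, run several seeds and compare decoded parameters.
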