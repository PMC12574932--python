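# agroscape

Seeded, fully reproducible generation of agricultural landscape mosaics
for ecological and agro-economic modelling.

Spatially explicit models — pollinator foraging, pest control, farm
agent-based models, bio-economic simulations — need land-cover maps as
input. Real maps are static: you cannot vary the share of seminatural
habitat, the field-size distribution, or the fragmentation of arable
land while holding everything else fixed. `agroscape` synthesizes
landscapes whose composition and configuration are under parametric
control, in three steps:

1. **Potential space** — which cells *could* hold an arable field.
   Either from multi-octave gradient (Perlin) noise rescaled to a
   pseudo-slope map in [0, 90]° and thresholded (by slope cut-off or by
   a requested cover share), or from a *hybrid-world* model: a cell-wise
   logistic regression P(arable | covariates) fitted to a real
   land-cover map, realized by Bernoulli draws and clustered by
   majority-vote smoothing, or simply an external binary raster.
   Roads and rivers can be carved as least-cost paths over the slope map
   and excluded from the space.
2. **Field placement** — tessellating a requested fraction of the
   potential space into discrete fields with a drawn size distribution
   (normal or lognormal, in hectares) and shape ratio. Two algorithms:
   *place-and-conquer* (fields grow segment by segment, adapting to the
   constraints of the space) and *dead leaves* (random occluding
   rectangles, then smallest-first pruning down to the target cover).
3. **Enrichment** — farmer identities (spatially clustered or random,
   the number of farmers emerging from a fields-per-farmer
   distribution) and crop identities tracking a portfolio of area
   shares; categorical raster views (field / crop / farmer /
   arable-without-borders / potential space) with legends.

On top sit FRAGSTATS-style **landscape metrics** (number of patches,
patch area, LPI, edge density, ENN, shape, LSI, fractal dimension,
perimeter–area ratio, contagion) and **pattern-oriented calibration**:
an elitist genetic algorithm searches generator parameters whose
landscapes match a reference metric profile, scored as
1 − mean scaled distance, so that any number of *equivalent* maps can
then be generated — alike in the chosen metrics, free in everything
else.

## Worked example

`examples/generate_landscape.py` builds a 1 km × 1 km landscape
(100×100 cells at 10 m), keeps the flattest 60% of the terrain as
potential space, converts 70% of it to ~1 ha fields, and assigns
farmers and a three-crop portfolio:

```
potential space: 6000 of 10000 cells
fields placed:   57 (realized coverage 0.710 of the space)
farmers:         15
  wheat     realized share 0.496
  maize     realized share 0.298
  rapeseed  realized share 0.206
arable-class metrics: {'np': 6.0, 'area_mn': 7.1, 'lpi': 13.29, 'ed': 128.8}
crop raster codes: {1: 'maize', 2: 'rapeseed', 3: 'wheat'}
```

The realized coverage lands on the request to within one field; the
realized crop shares track the portfolio (0.5/0.3/0.2) to within the
largest field's share of the arable area. The arable land merges into 6
patches of mean area 7.1 ha; the largest covers 13.3% of the landscape,
with 128.8 m of arable edge per landscape hectare.

Other examples: `roads_and_rivers.py` (least-cost linear features),
`hybrid_world.py` (suitability learned from a land-cover map),
`share_gradient.py` (seminatural-habitat profile across a potential
space × arable cover double gradient), and `calibrate_and_reproduce.py`
(GA calibration and equivalent-map generation). A thin CLI mirrors these
workflows: `agroscape generate | gradient | calibrate | equivalents |
metrics`.

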