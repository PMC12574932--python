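"""Generate one fully enriched landscape and summarize it.

A 100x100 grid at 10 m resolution (a 1 km x 1 km landscape): pseudo-slope
terrain from gradient noise, the flattest 60% of cells as potential
agricultural space, 70% of that space converted to fields with the
place-and-conquer algorithm, then farmers (about 4 fields each, spatially
clustered) and a three-crop portfolio.
"""

import numpy as np

from agroscape import (
    CropPortfolio,
    FarmerParams,
    FieldParams,
    PerlinParams,
    categorize_by_share,
    compute_profile,
    distribute_crops,
    distribute_farmers,
    establish_pac,
    extract_view,
    generate_perlin_slope,
    realized_coverage,
)
from agroscape.grid import Grid

slope = generate_perlin_slope(100, 100, PerlinParams(frequency=4, octaves=3, seed=7))
space = categorize_by_share(slope, 0.6)
landscape = establish_pac(space, FieldParams(mean_size=1.0, sd_size=0.3, coverage=0.7, seed=7))
distribute_farmers(landscape, FarmerParams(mean_fields=4, mode="spatial", seed=7))
distribute_crops(landscape, CropPortfolio([("wheat", 0.5), ("maize", 0.3), ("rapeseed", 0.2)]), seed=7)

print(f"potential space: {space.n_available} of 10000 cells")
print(f"fields placed:   {len(landscape.fields)} "
      f"(realized coverage {realized_coverage(landscape):.3f} of the space)")
print(f"farmers:         {len({f.farmer_id for f in landscape.fields})}")
total = landscape.total_field_cells()
for crop in ("wheat", "maize", "rapeseed"):
    share = sum(f.size for f in landscape.fields if f.crop_id == crop) / total
    print(f"  {crop:<9} realized share {share:.3f}")

arable = Grid((landscape.field_id_array() > 0).astype(int), 10.0)
profile = compute_profile(arable, 1, metrics=("np", "area_mn", "ed", "lpi"))
print("arable-class metrics:", {k: round(v, 2) for k, v in profile.values.items()})
# np = number of arable patches; area_mn in hectares; ed in m of edge per ha;
# lpi = % of the landscape taken by the largest patch.

view, legend = extract_view(landscape, "crop")
print(f"crop raster codes: {legend}")
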