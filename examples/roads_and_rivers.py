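"""Carve a road and a river through a landscape by least-cost paths.

Roads avoid steep terrain (cell cost 1 + slope/90), rivers follow the
valleys of the same relief (cell cost 1 + (90 - slope)/90).  Both are
removed from the potential space so fields keep clear of them.
"""

from agroscape import (
    FieldParams,
    PathSpec,
    PerlinParams,
    buffer_path,
    categorize_by_share,
    establish_pac,
    exclude_from_potential,
    generate_perlin_slope,
    least_cost_path,
    path_cost,
)

slope = generate_perlin_slope(80, 80, PerlinParams(frequency=3, seed=12))
space = categorize_by_share(slope, 0.65)
print(f"potential space before features: {space.n_available} cells")

for kind, width in (("road", 3), ("river", 1)):
    spec = PathSpec(cost_kind=kind, width=width, seed=5 if kind == "road" else 9)
    path = least_cost_path(slope, spec)
    cost = path_cost(slope, path, kind)
    cells = buffer_path(path, width, slope.shape)
    space = exclude_from_potential(space, cells)
    print(f"{kind}: {len(path)} path cells, accumulated cost {cost:.1f}, "
          f"{len(cells)} cells at width {width}; space now {space.n_available}")

landscape = establish_pac(space, FieldParams(mean_size=0.8, coverage=0.7, seed=3))
on_features = sum(
    1 for f in landscape.fields for cell in f.cells if space.mask.values[cell] == 0
)
print(f"fields placed: {len(landscape.fields)}; field cells on features: {on_features}")
# cost ~ path length x mean cell cost: a flat route costs ~1 per orthogonal step
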