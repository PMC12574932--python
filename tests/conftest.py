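import numpy as np
import pytest

from agroscape.grid import Grid
from agroscape.placement import FieldParams, establish_pac
from agroscape.potential import PerlinParams, categorize_by_share, generate_perlin_slope


@pytest.fixture(scope="session")
def slope_50():
    """Seeded 50×50 pseudo-slope map."""
    return generate_perlin_slope(50, 50, PerlinParams(frequency=3.0, seed=11))


@pytest.fixture(scope="session")
def space_50(slope_50):
    """50×50 potential space covering 60% of the grid."""
    return categorize_by_share(slope_50, 0.6)


@pytest.fixture(scope="session")
def blob_fixture():
    """Hybrid-world fixture: a suitable zone of which 70% is currently arable.

    The covariate is a noisy indicator of the suitable zone (a coarse
    soil-class map); the arable land cover is a dense random subsample of
    the zone, so a fitted suitability model should flag the whole zone.
    """
    nr = nc = 40
    yy, xx = np.mgrid[0:nr, 0:nc]
    zone = ((yy - 20) ** 2 + (xx - 20) ** 2) < 120
    rng = np.random.default_rng(42)
    arable = (zone & (rng.random((nr, nc)) < 0.7)).astype(np.int8)
    covariate = Grid(zone.astype(float) + rng.normal(0, 0.1, (nr, nc)))
    return Grid(arable), covariate, zone


@pytest.fixture(scope="session")
def many_field_landscape():
    """A landscape with >= 100 small fields on an unconstrained mask."""
    mask = Grid(np.ones((60, 60), dtype=np.int8))
    space = categorize_by_share(Grid(np.zeros((60, 60))), 1.0)
    space.mask.values[:] = mask.values
    params = FieldParams(mean_size=0.2, sd_size=0.05, coverage=0.8, seed=5)
    landscape = establish_pac(space, params)
    assert len(landscape.fields) >= 100
    return landscape
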