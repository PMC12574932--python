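"""Hybrid-world potential space: learn suitability from a land-cover map.

A synthetic "real world": a compact zone of suitable soil of which 70% is
currently farmed.  A cell-wise logistic regression of the arable
indicator on the soil covariate recovers the suitability signal; the
stochastic realization plus majority-vote clustering then flags the whole
suitable zone — including the currently unfarmed 30% — as potential
space, which is the point of the hybrid approach.
"""

import numpy as np

from agroscape import Grid, apply_hybrid, fit_hybrid

nr = nc = 40
yy, xx = np.mgrid[0:nr, 0:nc]
zone = ((yy - 20) ** 2 + (xx - 20) ** 2) < 120
rng = np.random.default_rng(42)
arable = Grid((zone & (rng.random((nr, nc)) < 0.7)).astype(np.int8))
soil = Grid(zone.astype(float) + rng.normal(0, 0.1, (nr, nc)))  # noisy soil-class map

params = fit_hybrid(arable, [soil])
print(f"logistic fit: intercept {params.coefficients[0]:.2f}, "
      f"soil weight {params.coefficients[1]:.2f} (converged: {params.converged})")

space = apply_hybrid(params, [soil], seed=1)
print(f"arable cells in the land-cover map: {int(arable.values.sum())}")
print(f"suitable zone size:                {int(zone.sum())}")
print(f"potential space realized:          {space.n_available}")
inside = int((space.mask.values.astype(bool) & zone).sum())
print(f"  of which inside the zone:        {inside}")
# the potential space exceeds current arable land because the model marks
# the whole suitable zone, not only the cells farmed today
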