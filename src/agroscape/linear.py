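"""Roads and rivers as least-cost paths over a slope map.

Linear features are carved through the landscape by a least-cost-path
search on a cost surface derived from the slope map, then removed from
the potential space so no field is placed on them.  Roads avoid steep
terrain (cell cost ``1 + slope/90``); rivers follow valleys by minimizing
an inverted-relief proxy (cell cost ``1 + (90 - slope)/90``).  A step
between two cells costs the mean of the two cell costs, times √2 for
diagonal moves — the weighting of a geometric minimum-cost-path search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage.graph import MCP_Geometric

from .grid import Grid
from .potential import PotentialSpace

__all__ = [
    "PathSpec",
    "cost_surface",
    "least_cost_path",
    "path_cost",
    "buffer_path",
    "exclude_from_potential",
]


@dataclass
class PathSpec:
    """Endpoints and semantics of one linear feature.

    ``start``/``end`` are (row, col) cells, or ``"random_edge"`` to draw
    both endpoints uniformly from a uniformly chosen pair of opposite
    grid edges (seeded).
    """

    start: tuple[int, int] | Literal["random_edge"] = "random_edge"
    end: tuple[int, int] | Literal["random_edge"] = "random_edge"
    cost_kind: Literal["road", "river"] = "road"
    width: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be odd and >= 1")
        if self.cost_kind not in ("road", "river"):
            raise ValueError("cost_kind must be 'road' or 'river'")


def cost_surface(slope_map: Grid, cost_kind: str) -> np.ndarray:
    """Per-cell traversal cost in [1, 2] derived from slope in degrees."""
    slope = np.asarray(slope_map.values, dtype=float)
    valid = slope_map.valid_mask()
    if (slope[valid] < 0).any():
        raise ValueError("slope values must be >= 0")
    slope = np.where(valid, slope, 0.0)  # nodata handled as barriers downstream
    if cost_kind == "road":
        return 1.0 + slope / 90.0
    if cost_kind == "river":
        return 1.0 + (90.0 - slope) / 90.0
    raise ValueError(f"unknown cost_kind {cost_kind!r}")


def _resolve_endpoints(spec: PathSpec, shape: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    nrow, ncol = shape
    explicit_start = spec.start != "random_edge"
    explicit_end = spec.end != "random_edge"
    if explicit_start and explicit_end:
        return tuple(spec.start), tuple(spec.end)
    rng = np.random.default_rng(spec.seed)
    # pick a pair of opposite edges, then a uniform cell on each
    if rng.integers(2) == 0:  # north/south
        start = (0, int(rng.integers(ncol)))
        end = (nrow - 1, int(rng.integers(ncol)))
    else:  # west/east
        start = (int(rng.integers(nrow)), 0)
        end = (int(rng.integers(nrow)), ncol - 1)
    if explicit_start:
        start = tuple(spec.start)
    if explicit_end:
        end = tuple(spec.end)
    return start, end


def least_cost_path(slope_map: Grid, spec: PathSpec) -> list[tuple[int, int]]:
    """Minimum-accumulated-cost 8-connected path between the endpoints.

    Returns the ordered cell sequence from start to end (both included).
    """
    costs = cost_surface(slope_map, spec.cost_kind)
    start, end = _resolve_endpoints(spec, slope_map.shape)
    for name, cell in (("start", start), ("end", end)):
        if not slope_map.in_bounds(cell):
            raise ValueError(f"{name} cell {cell} out of bounds")
    valid = slope_map.valid_mask()
    work = np.where(valid, costs, -1.0)  # MCP treats negative cells as barriers
    mcp = MCP_Geometric(work, fully_connected=True)
    cum, _ = mcp.find_costs([start], [end])
    if not np.isfinite(cum[end]):
        raise ValueError("no traversable path between the endpoints")
    path = [tuple(int(v) for v in cell) for cell in mcp.traceback(end)]
    return path


def path_cost(slope_map: Grid, path: Sequence[tuple[int, int]], cost_kind: str) -> float:
    """Accumulated cost of an ordered path under the stated edge weighting."""
    costs = cost_surface(slope_map, cost_kind)
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        step = np.hypot(r1 - r0, c1 - c0)
        total += step * 0.5 * (costs[r0, c0] + costs[r1, c1])
    return float(total)


def buffer_path(path: Iterable[tuple[int, int]], width: int, shape: tuple[int, int]) -> set:
    """Dilate a path to the requested odd width (Chebyshev radius)."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    radius = (width - 1) // 2
    nrow, ncol = shape
    out: set = set()
    for r, c in path:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol:
                    out.add((rr, cc))
    return out


def exclude_from_potential(space: PotentialSpace, features: Iterable[tuple[int, int]]) -> PotentialSpace:
    """Zero the potential-space mask on feature cells (idempotent)."""
    out = space.copy()
    vals = out.mask.values
    for r, c in features:
        if 0 <= r < vals.shape[0] and 0 <= c < vals.shape[1]:
            vals[r, c] = 0
    return out
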