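"""Step 2: tessellate the potential space into discrete arable fields.

Two placement algorithms share one parameter set (field size and shape
distributions plus the fraction of potential space to convert):

* **place-and-conquer** builds each field segment by segment: a field is
  a stack of 1-cell-wide runs, each aligned as closely as possible to the
  previous one and truncated by forbidden cells (outside the potential
  space, or already claimed by another field).  Slower, but field shapes
  respond naturally to the constraints of the space.
* **dead leaves** first covers the whole potential space with randomly
  dropped occluding rectangles (later rectangles overwrite earlier ones),
  then prunes fields smallest-first until the requested cover remains —
  pruning small fragments rather than random fields avoids
  over-fragmenting the landscape.

Both are fully deterministic given (mask, parameters, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .grid import Grid
from .potential import PotentialSpace

__all__ = [
    "FieldParams",
    "Field",
    "Landscape",
    "draw_field_dims",
    "establish_pac",
    "establish_dl",
    "realized_coverage",
]

_DL_STALL_LIMIT = 10_000  # consecutive non-covering stamps before phase 1 gives up


@dataclass
class FieldParams:
    """Shared controls for both placement algorithms.

    mean_size / sd_size are in hectares; mean_shape is the target
    length:width ratio (>= 1); coverage is the fraction of potential-space
    cells to convert to fields.
    """

    mean_size: float = 1.0
    sd_size: float = 0.0
    size_distribution: Literal["normal", "lognormal"] = "normal"
    mean_shape: float = 1.0
    sd_shape: float = 0.0
    coverage: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_size > 0:
            raise ValueError("mean_size must be > 0")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.mean_shape < 1:
            raise ValueError("mean_shape must be >= 1")
        if self.size_distribution not in ("normal", "lognormal"):
            raise ValueError("size_distribution must be 'normal' or 'lognormal'")


@dataclass
class Field:
    """One arable field: a 4-connected set of cells plus identity slots."""

    cells: set
    field_id: int
    farmer_id: int | None = None
    crop_id: str | None = None

    @property
    def size(self) -> int:
        return len(self.cells)

    def centroid(self) -> tuple[float, float]:
        arr = np.array(sorted(self.cells), dtype=float)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


@dataclass
class Landscape:
    """Ordered collection of fields plus the potential space they occupy."""

    fields: list
    space: PotentialSpace
    params: FieldParams
    algorithm: str = ""
    coverage_shortfall: bool = False  # mask exhausted before the request was met

    @property
    def resolution(self) -> float:
        return self.space.mask.resolution

    def total_field_cells(self) -> int:
        return sum(f.size for f in self.fields)

    def field_id_array(self) -> np.ndarray:
        out = np.zeros(self.space.mask.shape, dtype=np.int32)
        for f in self.fields:
            for r, c in f.cells:
                out[r, c] = f.field_id
        return out

    # -- JSON round trip (cells run-length encoded row-wise) ---------------

    def to_json(self, path: str | Path | None = None) -> str:
        def encode(cells: set) -> list:
            runs = []
            for r, c in sorted(cells):
                if runs and runs[-1][0] == r and runs[-1][1] + runs[-1][2] == c:
                    runs[-1][2] += 1
                else:
                    runs.append([r, c, 1])
            return runs

        doc = {
            "resolution": self.resolution,
            "algorithm": self.algorithm,
            "coverage_shortfall": self.coverage_shortfall,
            "params": {
                "mean_size": self.params.mean_size,
                "sd_size": self.params.sd_size,
                "size_distribution": self.params.size_distribution,
                "mean_shape": self.params.mean_shape,
                "sd_shape": self.params.sd_shape,
                "coverage": self.params.coverage,
                "seed": self.params.seed,
            },
            "mask": [[int(v) for v in row] for row in self.space.mask.values],
            "fields": [
                {
                    "field_id": f.field_id,
                    "farmer_id": f.farmer_id,
                    "crop_id": f.crop_id,
                    "runs": encode(f.cells),
                }
                for f in self.fields
            ],
        }
        text = json.dumps(doc, separators=(",", ":"), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def load(cls, path: str | Path) -> "Landscape":
        return cls.from_json(Path(path).read_text())

    @classmethod
    def from_json(cls, text: str) -> "Landscape":
        doc = json.loads(text)
        mask = Grid(np.array(doc["mask"], dtype=np.int8), doc["resolution"])
        space = PotentialSpace(mask, provenance="external")
        params = FieldParams(**doc["params"])
        fields = []
        for fd in doc["fields"]:
            cells = set()
            for r, c, n in fd["runs"]:
                for k in range(n):
                    cells.add((r, c + k))
            fields.append(Field(cells, fd["field_id"], fd["farmer_id"], fd["crop_id"]))
        return cls(fields, space, params, doc.get("algorithm", ""), doc.get("coverage_shortfall", False))


# ---------------------------------------------------------------------------
# Field dimension draws
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, minimum: float) -> float:
    """Normal draw truncated at ``minimum`` by redraw (100 tries, then clamp)."""
    if sd == 0:
        return max(mean, minimum)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= minimum:
            return v
    return minimum


def draw_field_dims(
    params: FieldParams, rng: np.random.Generator, resolution: float = 10.0
) -> tuple[int, int, int]:
    """Draw one field's (target_cells, n_segments, segment_length).

    The field area A (hectares) comes from the configured size
    distribution (normal truncated at one cell by redraw, or a lognormal
    moment-matched to the requested mean/sd).  The shape ratio ρ =
    length:width is a truncated-normal draw (ρ >= 1).  The long axis is
    ``segment_length = round(sqrt(A·ρ))`` cells and the short axis
    ``n_segments = round(A / segment_length)``.
    """
    cells_per_ha = 10_000.0 / resolution**2
    one_cell_ha = 1.0 / cells_per_ha
    if params.size_distribution == "normal":
        area_ha = _draw_positive(rng, params.mean_size, params.sd_size, one_cell_ha)
    else:
        if params.sd_size == 0:
            area_ha = params.mean_size
        else:
            sigma2 = np.log(1.0 + (params.sd_size / params.mean_size) ** 2)
            mu = np.log(params.mean_size) - sigma2 / 2.0
            area_ha = rng.lognormal(mu, np.sqrt(sigma2))
        area_ha = max(area_ha, one_cell_ha)
    rho = _draw_positive(rng, params.mean_shape, params.sd_shape, 1.0)

    target_cells = max(1, _round_half_up(area_ha * cells_per_ha))
    segment_length = max(1, _round_half_up(np.sqrt(target_cells * rho)))
    n_segments = max(1, _round_half_up(target_cells / segment_length))
    return target_cells, n_segments, segment_length


# ---------------------------------------------------------------------------
# Place and conquer
# ---------------------------------------------------------------------------


def _lay_first_segment(
    free_line: np.ndarray, pos: int, seg_len: int, limit: int
) -> tuple[int, int]:
    """Grow a run through ``pos`` along a line: forward first, then back.

    Returns the inclusive interval [a, b]; ``limit`` caps the run length.
    """
    n = free_line.size
    max_len = min(seg_len, limit)
    a = b = pos
    while b - a + 1 < max_len and b + 1 < n and free_line[b + 1]:
        b += 1
    while b - a + 1 < max_len and a - 1 >= 0 and free_line[a - 1]:
        a -= 1
    return a, b


def _best_window(
    free_line: np.ndarray, prev: tuple[int, int], seg_len: int, limit: int
) -> tuple[int, int] | None:
    """Best free window on a line: maximize 4-adjacency with the previous
    segment's interval; ties toward the smaller start offset.

    Returns None when no free window touches the previous segment.
    """
    pa, pb = prev
    n = free_line.size
    best = None
    best_overlap = 0
    i = 0
    while i < n:
        if not free_line[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and free_line[j + 1]:
            j += 1
        run_len = j - i + 1
        wlen = min(seg_len, limit, run_len)
        if wlen >= 1:
            for start in range(i, j - wlen + 2):
                end = start + wlen - 1
                overlap = min(end, pb) - max(start, pa) + 1
                if overlap > best_overlap:
                    best_overlap = overlap
                    best = (start, end)
        i = j + 1
    return best


def _grow_field(
    free: np.ndarray,
    anchor: tuple[int, int],
    horizontal: bool,
    target_cells: int,
    n_segments: int,
    seg_len: int,
) -> set:
    """Grow one place-and-conquer field in-place on the free mask.

    Segments run along rows when ``horizontal`` (parallel lines are
    adjacent rows), along columns otherwise.  Growth proceeds on one side
    of the first segment and switches to the other side when a line
    offers no free cell adjacent to the previous segment.
    """
    view = free if horizontal else free.T
    line0, pos0 = (anchor[0], anchor[1]) if horizontal else (anchor[1], anchor[0])
    nlines = view.shape[0]

    cells: set = set()

    def claim(line: int, a: int, b: int) -> None:
        view[line, a : b + 1] = False
        for p in range(a, b + 1):
            cells.add((line, p) if horizontal else (p, line))

    a, b = _lay_first_segment(view[line0], pos0, seg_len, target_cells)
    claim(line0, a, b)
    placed = b - a + 1
    segments = 1

    side = 1
    prev = {1: (line0, a, b), -1: (line0, a, b)}
    blocked = {1: False, -1: False}
    while segments < n_segments and placed < target_cells:
        if blocked[side]:
            side = -side
            if blocked[side]:
                break
        pline, pa, pb = prev[side]
        line = pline + side
        window = None
        if 0 <= line < nlines:
            window = _best_window(view[line], (pa, pb), seg_len, target_cells - placed)
        if window is None:
            blocked[side] = True
            if blocked[-side]:
                break
            side = -side
            continue
        wa, wb = window
        claim(line, wa, wb)
        placed += wb - wa + 1
        prev[side] = (line, wa, wb)
        segments += 1
    return cells


def establish_pac(space: PotentialSpace, params: FieldParams) -> Landscape:
    """Place fields with the place-and-conquer algorithm.

    Fields are placed one after another (uniform-random free anchor,
    uniform-random orientation) until the requested share of the
    potential space is covered or no free cell remains.  The last field
    may overshoot the target by its own size (one-field slack).  If the
    mask is exhausted first, a partial landscape is returned with
    ``coverage_shortfall=True``.
    """
    rng = np.random.default_rng(params.seed)
    free = space.mask.values.astype(bool)
    n_mask = int(free.sum())
    if n_mask == 0:
        raise ValueError("potential space has no available cell")
    target_total = params.coverage * n_mask

    fields: list[Field] = []
    placed_total = 0
    next_id = 1
    shortfall = False
    while placed_total < target_total:
        free_flat = np.flatnonzero(free)
        if free_flat.size == 0:
            shortfall = True
            break
        target_cells, n_segments, seg_len = draw_field_dims(
            params, rng, space.mask.resolution
        )
        pick = int(free_flat[rng.integers(free_flat.size)])
        anchor = (pick // free.shape[1], pick % free.shape[1])
        horizontal = bool(rng.integers(2) == 0)
        cells = _grow_field(free, anchor, horizontal, target_cells, n_segments, seg_len)
        if cells:
            fields.append(Field(cells, next_id))
            next_id += 1
            placed_total += len(cells)
    if shortfall:
        warnings.warn(
            "potential space exhausted before requested coverage was reached",
            RuntimeWarning,
        )
    return Landscape(fields, space, params, algorithm="pac", coverage_shortfall=shortfall)


# ---------------------------------------------------------------------------
# Dead leaves
# ---------------------------------------------------------------------------


def establish_dl(space: PotentialSpace, params: FieldParams) -> Landscape:
    """Place fields with the modified dead-leaves algorithm.

    Phase 1 drops random rectangles (dimensions from the shared size and
    shape draws, uniform-random center and orientation) that occlude
    earlier ones, until every potential-space cell is covered or the
    stamping stalls.  Each surviving 4-connected same-identity region
    becomes one field.  Phase 2 deletes fields smallest-first until the
    remaining cover is at or below the request.
    """
    rng = np.random.default_rng(params.seed)
    mask = space.mask.values.astype(bool)
    nrow, ncol = mask.shape
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("potential space has no available cell")

    id_grid = np.zeros(mask.shape, dtype=np.int32)
    covered = 0
    stale = 0
    stamp_id = 1
    while covered < n_mask and stale < _DL_STALL_LIMIT:
        _, n_segments, seg_len = draw_field_dims(params, rng, space.mask.resolution)
        if rng.integers(2) == 0:
            height, width = n_segments, seg_len
        else:
            height, width = seg_len, n_segments
        cr = int(rng.integers(nrow))
        cc = int(rng.integers(ncol))
        r0 = max(0, cr - height // 2)
        r1 = min(nrow, r0 + height)
        c0 = max(0, cc - width // 2)
        c1 = min(ncol, c0 + width)
        sub_mask = mask[r0:r1, c0:c1]
        sub_ids = id_grid[r0:r1, c0:c1]
        newly = int((sub_mask & (sub_ids == 0)).sum())
        sub_ids[sub_mask] = stamp_id
        covered += newly
        stale = 0 if newly > 0 else stale + 1
        stamp_id += 1

    # split surviving same-id regions into 4-connected fields
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    fields: list[Field] = []
    next_id = 1
    slices = ndimage.find_objects(id_grid)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        region = id_grid[sl] == idx
        labels, k = ndimage.label(region, structure=structure)
        for lab in range(1, k + 1):
            rr, cc = np.nonzero(labels == lab)
            cells = {
                (int(r) + sl[0].start, int(c) + sl[1].start) for r, c in zip(rr, cc)
            }
            fields.append(Field(cells, next_id))
            next_id += 1

    # phase 2: smallest-first removal down to the requested cover
    fields.sort(key=lambda f: (f.size, f.field_id))
    total = sum(f.size for f in fields)
    target_total = params.coverage * n_mask
    kept = list(fields)
    removed = 0
    while kept and total > target_total:
        smallest = kept[0]
        total -= smallest.size
        kept.pop(0)
        removed += 1
    # restore placement order by id and renumber contiguously
    kept.sort(key=lambda f: f.field_id)
    for new_id, f in enumerate(kept, start=1):
        f.field_id = new_id

    shortfall = covered < n_mask and total < target_total
    if shortfall:
        warnings.warn(
            "dead-leaves phase 1 stalled before covering the potential space",
            RuntimeWarning,
        )
    return Landscape(kept, space, params, algorithm="dl", coverage_shortfall=shortfall)


def realized_coverage(landscape: Landscape) -> float:
    """Fraction of potential-space cells occupied by fields."""
    n_mask = landscape.space.n_available
    if n_mask == 0:
        return 0.0
    return landscape.total_field_cells() / n_mask
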