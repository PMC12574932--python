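"""Step 3: enrich fields with farmer and crop identities; extract raster views.

The number of farmers in a landscape is emergent: farmers are created one
at a time, each drawing their number of fields from a configured
distribution, and claim fields until none remain — so the last farmer may
receive fewer fields than drawn.  In *spatial* mode a farmer claims a
random unassigned field plus its nearest unassigned neighbors (field
centroid distance); in *random* mode the fields are drawn uniformly from
the whole landscape.

Crop allocation converts a non-spatial crop portfolio (crop → share of
arable area) into per-field assignments.  Because a field carries exactly
one crop, the realized shares deviate from the targets by at most the
largest field's share of the arable area; landscapes with more, smaller
fields match the portfolio more closely.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .grid import Grid
from .placement import Landscape

__all__ = [
    "FarmerParams",
    "CropPortfolio",
    "distribute_farmers",
    "distribute_crops",
    "assign_farmers_by_table",
    "assign_crops_by_table",
    "extract_view",
    "read_assignment_table",
    "write_legend",
]


@dataclass
class FarmerParams:
    """Distribution of the number of fields held per farmer."""

    mean_fields: float = 4.0
    sd_fields: float = 0.0
    distribution: Literal["uniform", "normal", "lognormal"] = "normal"
    mode: Literal["spatial", "random"] = "spatial"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_fields > 0:
            raise ValueError("mean_fields must be > 0")
        if self.sd_fields < 0:
            raise ValueError("sd_fields must be >= 0")
        if self.distribution not in ("uniform", "normal", "lognormal"):
            raise ValueError("distribution must be uniform, normal or lognormal")
        if self.mode not in ("spatial", "random"):
            raise ValueError("mode must be 'spatial' or 'random'")


@dataclass
class CropPortfolio:
    """Crops and the share of arable land each should occupy.

    Shares must be positive and sum to 1 (within 1e-9).
    """

    entries: Sequence[tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("crop ids must be unique")
        shares = np.array([s for _, s in self.entries], dtype=float)
        if len(shares) == 0:
            raise ValueError("portfolio must contain at least one crop")
        if (shares <= 0).any():
            raise ValueError("crop shares must be > 0")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"crop shares must sum to 1 (got {shares.sum()})")


def _draw_n_fields(params: FarmerParams, rng: np.random.Generator) -> int:
    """One farmer's field count: distribution draw, rounded, floored at 1."""
    mean, sd = params.mean_fields, params.sd_fields
    if params.distribution == "uniform":
        half = np.sqrt(3.0) * sd  # uniform on [mean-h, mean+h] has sd = h/sqrt(3)
        v = rng.uniform(mean - half, mean + half)
    elif params.distribution == "normal":
        v = rng.normal(mean, sd) if sd > 0 else mean
    else:  # lognormal, moment matched to (mean, sd)
        if sd == 0:
            v = mean
        else:
            sigma2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            v = rng.lognormal(mu, np.sqrt(sigma2))
    return max(1, int(np.floor(v + 0.5)))


def distribute_farmers(landscape: Landscape, params: FarmerParams) -> Landscape:
    """Assign every field to exactly one farmer (ids 1, 2, ...).

    Farmers are created sequentially until no field is unassigned; the
    last farmer may receive fewer fields than drawn.
    """
    if not landscape.fields:
        raise ValueError("landscape has no fields to assign")
    rng = np.random.default_rng(params.seed)
    unassigned = list(range(len(landscape.fields)))
    centroids = np.array([f.centroid() for f in landscape.fields])
    farmer_id = 0
    while unassigned:
        farmer_id += 1
        n = min(_draw_n_fields(params, rng), len(unassigned))
        if params.mode == "random":
            picks = rng.choice(len(unassigned), size=n, replace=False)
            chosen = [unassigned[i] for i in sorted(picks, reverse=True)]
        else:  # spatial: random anchor field + its n-1 nearest unassigned
            anchor_pos = int(rng.integers(len(unassigned)))
            anchor = unassigned[anchor_pos]
            rest = [i for i in unassigned if i != anchor]
            if rest and n > 1:
                d = np.linalg.norm(centroids[rest] - centroids[anchor], axis=1)
                order = np.argsort(d, kind="stable")[: n - 1]
                chosen = [anchor] + [rest[i] for i in order]
            else:
                chosen = [anchor]
        for idx in chosen:
            landscape.fields[idx].farmer_id = farmer_id
            unassigned.remove(idx)
    return landscape


def distribute_crops(
    landscape: Landscape, portfolio: CropPortfolio, seed: int = 0
) -> Landscape:
    """Assign one crop per field, tracking the portfolio's area shares.

    Fields are visited in seeded shuffled order; each receives the crop
    with the largest remaining area deficit (target share × total arable
    area − area already planted).  The per-crop share error is bounded by
    the largest field's share of the arable area.
    """
    if not landscape.fields:
        raise ValueError("landscape has no fields to assign")
    rng = np.random.default_rng(seed)
    total = float(sum(f.size for f in landscape.fields))
    crops = [cid for cid, _ in portfolio.entries]
    targets = np.array([s for _, s in portfolio.entries]) * total
    planted = np.zeros(len(crops))
    order = rng.permutation(len(landscape.fields))
    for idx in order:
        f = landscape.fields[int(idx)]
        deficits = targets - planted
        j = int(np.argmax(deficits))  # ties: first (portfolio order)
        f.crop_id = crops[j]
        planted[j] += f.size
    return landscape


def assign_farmers_by_table(landscape: Landscape, table: Mapping[int, int]) -> Landscape:
    """Set farmer ids for the listed field ids; others are untouched."""
    by_id = {f.field_id: f for f in landscape.fields}
    unknown = [fid for fid in table if fid not in by_id]
    if unknown:
        raise KeyError(f"unknown field ids in table: {sorted(unknown)}")
    for fid, farmer in table.items():
        by_id[fid].farmer_id = farmer
    return landscape


def assign_crops_by_table(landscape: Landscape, table: Mapping[int, str]) -> Landscape:
    """Set crop ids for the listed field ids; others are untouched."""
    by_id = {f.field_id: f for f in landscape.fields}
    unknown = [fid for fid in table if fid not in by_id]
    if unknown:
        raise KeyError(f"unknown field ids in table: {sorted(unknown)}")
    for fid, crop in table.items():
        by_id[fid].crop_id = crop
    return landscape


View = Literal["field", "arable_no_borders", "crop", "farmer", "potential_space"]


def extract_view(landscape: Landscape, view: View) -> tuple[Grid, dict]:
    """Extract one categorical raster view of the landscape.

    Returns ``(grid, legend)`` where the legend maps raster codes to
    labels (crop names, farmer ids, ...); 0 is always background.

    * ``field``: cell value = field id.
    * ``arable_no_borders``: 1 on field cells whose four orthogonal
      neighbors all belong to the same field (border cells drop to 0).
    * ``crop`` / ``farmer``: cell value = integer code per identity.
    * ``potential_space``: the binary availability mask.
    """
    res = landscape.resolution
    shape = landscape.space.mask.shape
    if view == "potential_space":
        return Grid(landscape.space.mask.values.copy(), res), {0: "unavailable", 1: "available"}
    if view == "field":
        return Grid(landscape.field_id_array(), res), {
            f.field_id: f"field {f.field_id}" for f in landscape.fields
        }
    if view == "arable_no_borders":
        ids = landscape.field_id_array()
        out = np.zeros(shape, dtype=np.int8)
        same = np.ones(shape, dtype=bool)
        padded = np.pad(ids, 1, constant_values=0)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            shifted = padded[1 + dr : 1 + dr + shape[0], 1 + dc : 1 + dc + shape[1]]
            same &= shifted == ids
        out[(ids > 0) & same] = 1
        return Grid(out, res), {0: "border or non-field", 1: "field interior"}
    if view in ("crop", "farmer"):
        missing = [
            f.field_id
            for f in landscape.fields
            if (f.crop_id if view == "crop" else f.farmer_id) is None
        ]
        if missing:
            raise ValueError(
                f"{view} view requested but fields {missing[:5]}... lack a {view} id"
                if len(missing) > 5
                else f"{view} view requested but fields {missing} lack a {view} id"
            )
        out = np.zeros(shape, dtype=np.int32)
        if view == "farmer":
            codes = {f.farmer_id for f in landscape.fields}
            code_map = {ident: i + 1 for i, ident in enumerate(sorted(codes))}
            legend = {code: f"farmer {ident}" for ident, code in code_map.items()}
            for f in landscape.fields:
                val = code_map[f.farmer_id]
                for r, c in f.cells:
                    out[r, c] = val
        else:
            idents = sorted({f.crop_id for f in landscape.fields})
            code_map = {ident: i + 1 for i, ident in enumerate(idents)}
            legend = {code: str(ident) for ident, code in code_map.items()}
            for f in landscape.fields:
                val = code_map[f.crop_id]
                for r, c in f.cells:
                    out[r, c] = val
        return Grid(out, res), legend
    raise ValueError(f"unknown view {view!r}")


def read_assignment_table(path: str | Path, value_type: type = int) -> dict:
    """Read a two-column CSV (field_id, identity) into a dict."""
    table: dict = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in {"field_id", "field"}:
                continue
            table[int(row[0])] = value_type(row[1].strip())
    return table


def write_legend(legend: Mapping[int, str], path: str | Path) -> None:
    """Write a raster-code → label legend as JSON."""
    Path(path).write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=1))
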