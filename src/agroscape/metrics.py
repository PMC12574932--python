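"""FRAGSTATS-style landscape metrics on categorical rasters.

All metrics use the standard raster formulations: patches are maximal
connected components (8-connectivity by default) of one class; edges are
cell faces between a class cell and anything else, including the grid
boundary; areas are in hectares, perimeters in meters.  NoData cells are
outside the landscape for every metric.

Supported metrics
-----------------
==========  ============================================================
np          number of patches of the class
area_mn/sd  mean / SD of patch area (ha); SD uses the N denominator
lpi         largest patch index: 100 · max patch area / landscape area
contag      contagion (landscape level, all classes, 4-neighbor
            double-count adjacencies), in [0, 100]; needs >= 2 classes
ed          edge density: class edge length (m) per landscape hectare
enn_mn/sd   Euclidean nearest neighbor distance between patches (m,
            cell-center to cell-center); needs >= 2 patches
shape_mn    mean patch shape index 0.25·p/sqrt(a), p in m, a in m²
lsi         landscape shape index 0.25·E/sqrt(A) over the whole class
frac_mn     mean patch fractal dimension 2·ln(0.25·p)/ln(a)
para_mn     mean patch perimeter-area ratio p/a (m per m²)
==========  ============================================================

Metrics whose preconditions fail are *missing* from the profile, never a
silent zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import Grid

__all__ = [
    "ALL_METRICS",
    "MetricProfile",
    "patches",
    "compute_profile",
    "profile_distance",
]

ALL_METRICS = (
    "np",
    "area_mn",
    "area_sd",
    "lpi",
    "contag",
    "ed",
    "enn_mn",
    "enn_sd",
    "shape_mn",
    "lsi",
    "frac_mn",
    "para_mn",
)

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class MetricProfile:
    """Named vector of landscape-metric values; missing metrics absent."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str, default=None):
        return self.values.get(name, default)

    def subset(self, names: Iterable[str]) -> "MetricProfile":
        return MetricProfile({n: self.values[n] for n in names})

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for name, value in self.values.items():
                writer.writerow([name, repr(float(value))])

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetricProfile":
        values = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0] == "metric":
                    continue
                values[row[0]] = float(row[1])
        return cls(values)


def patches(class_map: Grid, class_id, connectivity: int = 8) -> list:
    """Maximal connected components of one class, as cell sets."""
    member = (class_map.values == class_id) & class_map.valid_mask()
    labels, count = ndimage.label(member, structure=_STRUCTURES[connectivity])
    out = []
    for lab in range(1, count + 1):
        rr, cc = np.nonzero(labels == lab)
        out.append({(int(r), int(c)) for r, c in zip(rr, cc)})
    return out


def _patch_stats(member: np.ndarray, connectivity: int):
    """Label the class and return (labels, sizes[cells], perimeters[faces])."""
    labels, count = ndimage.label(member, structure=_STRUCTURES[connectivity])
    if count == 0:
        return labels, np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    sizes = np.bincount(labels.ravel(), minlength=count + 1)[1:]
    # faces between a patch cell and any cell not carrying the same label,
    # grid boundary included
    perims = np.zeros(count + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        shifted = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        differs = (core > 0) & (shifted != core)
        perims += np.bincount(core[differs], minlength=count + 1)
    return labels, sizes, perims[1:]


def _class_edge_faces(member: np.ndarray, valid: np.ndarray) -> int:
    """Faces between class cells and non-class-or-outside, boundary included."""
    padded = np.pad(member, 1, constant_values=False)
    pad_valid = np.pad(valid, 1, constant_values=False)
    core = padded[1:-1, 1:-1]
    edges = 0
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        nb_valid = pad_valid[1 + dr : pad_valid.shape[0] - 1 + dr, 1 + dc : pad_valid.shape[1] - 1 + dc]
        # neighbor is either a valid non-class cell or outside the landscape
        edges += int((core & (~nb | ~nb_valid)).sum())
    return edges


def _enn_distances(labels: np.ndarray, count: int, resolution: float) -> np.ndarray:
    """Per-patch min cell-center distance to another patch of the class (m)."""
    coords = np.nonzero(labels > 0)
    pts = np.column_stack(coords).astype(float)
    labs = labels[coords]
    out = np.full(count, np.inf)
    for lab in range(1, count + 1):
        own = pts[labs == lab]
        other = pts[labs != lab]
        if other.size == 0:
            continue
        tree = cKDTree(other)
        d, _ = tree.query(own, k=1)
        out[lab - 1] = d.min() * resolution
    return out


def _contagion(values: np.ndarray, valid: np.ndarray) -> float | None:
    """Landscape contagion from 4-neighbor double-counted adjacencies."""
    classes = np.unique(values[valid])
    m = len(classes)
    if m < 2:
        return None
    index = {c: i for i, c in enumerate(classes)}
    idx = np.full(values.shape, -1, dtype=np.int64)
    for c, i in index.items():
        idx[(values == c) & valid] = i
    g = np.zeros((m, m), dtype=np.int64)
    # horizontal and vertical neighbor pairs, each counted in both orders
    for a, b in (
        (idx[:, :-1], idx[:, 1:]),
        (idx[:-1, :], idx[1:, :]),
    ):
        ok = (a >= 0) & (b >= 0)
        np.add.at(g, (a[ok], b[ok]), 1)
        np.add.at(g, (b[ok], a[ok]), 1)
    if g.sum() == 0:
        return None
    p_class = np.array([(idx == i).sum() for i in range(m)], dtype=float)
    p_class /= p_class.sum()
    row_tot = g.sum(axis=1, dtype=float)
    s = 0.0
    for i in range(m):
        if row_tot[i] == 0:
            continue
        for k in range(m):
            q = p_class[i] * g[i, k] / row_tot[i]
            if q > 0:
                s += q * np.log(q)
    return float((1.0 + s / (2.0 * np.log(m))) * 100.0)


def compute_profile(
    class_map: Grid,
    class_id,
    resolution: float | None = None,
    connectivity: int = 8,
    metrics: Sequence[str] | None = None,
) -> MetricProfile:
    """Compute the metric profile of one class of a categorical raster.

    ``metrics`` restricts computation to a subset (all by default).
    Metrics whose preconditions fail (single class for contag, fewer than
    two patches for enn) are left out of the profile.
    """
    res = class_map.resolution if resolution is None else resolution
    wanted = set(ALL_METRICS if metrics is None else metrics)
    unknown = wanted - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    valid = class_map.valid_mask()
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("landscape has no valid cells")
    member = (class_map.values == class_id) & valid

    cell_area_m2 = res * res
    cell_area_ha = cell_area_m2 / 1e4
    landscape_ha = n_valid * cell_area_ha

    out: dict[str, float] = {}

    need_patches = wanted & {
        "np", "area_mn", "area_sd", "lpi", "enn_mn", "enn_sd",
        "shape_mn", "frac_mn", "para_mn",
    }
    labels = sizes = perims = None
    if need_patches:
        labels, sizes, perims = _patch_stats(member, connectivity)
        count = len(sizes)
        if "np" in wanted:
            out["np"] = float(count)
        if count > 0:
            areas_ha = sizes * cell_area_ha
            if "area_mn" in wanted:
                out["area_mn"] = float(areas_ha.mean())
            if "area_sd" in wanted:
                out["area_sd"] = float(areas_ha.std())  # population SD
            if "lpi" in wanted:
                out["lpi"] = float(100.0 * areas_ha.max() / landscape_ha)
            p_m = perims * res
            a_m2 = sizes * cell_area_m2
            if "shape_mn" in wanted:
                out["shape_mn"] = float((0.25 * p_m / np.sqrt(a_m2)).mean())
            if "para_mn" in wanted:
                out["para_mn"] = float((p_m / a_m2).mean())
            if "frac_mn" in wanted:
                with np.errstate(divide="ignore"):
                    la = np.log(a_m2)
                if not (la == 0).any():
                    out["frac_mn"] = float((2.0 * np.log(0.25 * p_m) / la).mean())
            if ("enn_mn" in wanted or "enn_sd" in wanted) and count >= 2:
                enn = _enn_distances(labels, count, res)
                enn = enn[np.isfinite(enn)]
                if enn.size:
                    if "enn_mn" in wanted:
                        out["enn_mn"] = float(enn.mean())
                    if "enn_sd" in wanted:
                        out["enn_sd"] = float(enn.std())

    if wanted & {"ed", "lsi"}:
        edge_faces = _class_edge_faces(member, valid)
        edge_m = edge_faces * res
        if "ed" in wanted:
            out["ed"] = float(edge_m / landscape_ha)
        if "lsi" in wanted and member.any():
            class_area_m2 = int(member.sum()) * cell_area_m2
            out["lsi"] = float(0.25 * edge_m / np.sqrt(class_area_m2))

    if "contag" in wanted:
        contag = _contagion(np.asarray(class_map.values), valid)
        if contag is not None:
            out["contag"] = contag

    return MetricProfile(out)


def profile_distance(
    generated: MetricProfile | Mapping,
    reference: MetricProfile | Mapping,
    subset: Sequence[str] | None = None,
    eps: float = 1e-9,
) -> float:
    """Similarity score in [0, 1] between two metric profiles.

    Per metric the scaled distance is ``min(1, |g - r| / max(|r|, eps))``
    (clipped so one wild metric cannot dominate); the score is 1 minus
    the mean — 1 is a perfect match, 0 a complete mismatch.
    """
    gvals = generated.values if isinstance(generated, MetricProfile) else dict(generated)
    rvals = reference.values if isinstance(reference, MetricProfile) else dict(reference)
    names = list(rvals.keys()) if subset is None else list(subset)
    if not names:
        raise ValueError("profile subset is empty")
    missing = [n for n in names if n not in gvals or n not in rvals]
    if missing:
        raise KeyError(f"metrics missing from a profile: {missing}")
    ds = []
    for n in names:
        g, r = float(gvals[n]), float(rvals[n])
        ds.append(min(1.0, abs(g - r) / max(abs(r), eps)))
    return 1.0 - float(np.mean(ds))
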