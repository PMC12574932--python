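"""Independent brute-force oracles used to verify the implementation.

Everything here is written from the metric/algorithm definitions with
plain Python loops and breadth-first search — deliberately sharing no
code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def flood_fill_patches(values, class_id, connectivity=8, valid=None):
    """Maximal connected components of one class by BFS flood fill."""
    values = np.asarray(values)
    nrow, ncol = values.shape
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    seen = np.zeros(values.shape, dtype=bool)
    patches = []
    for r0 in range(nrow):
        for c0 in range(ncol):
            if seen[r0, c0] or not valid[r0, c0] or values[r0, c0] != class_id:
                continue
            patch = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                patch.add((r, c))
                for dr, dc in OFFSETS[connectivity]:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < nrow and 0 <= cc < ncol
                        and not seen[rr, cc] and valid[rr, cc]
                        and values[rr, cc] == class_id
                    ):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            patches.append(patch)
    return patches


def patch_perimeter_faces(patch, shape):
    """Cell faces between the patch and anything else (boundary included)."""
    nrow, ncol = shape
    faces = 0
    for r, c in patch:
        for dr, dc in OFFSETS[4]:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrow and 0 <= cc < ncol) or (rr, cc) not in patch:
                faces += 1
    return faces


def brute_force_profile(values, class_id, resolution, connectivity=8, nodata=None):
    """All twelve landscape metrics computed directly from definitions."""
    values = np.asarray(values)
    nrow, ncol = values.shape
    valid = np.ones(values.shape, dtype=bool) if nodata is None else values != nodata
    n_valid = int(valid.sum())
    cell_ha = resolution**2 / 1e4
    landscape_ha = n_valid * cell_ha

    patches = flood_fill_patches(values, class_id, connectivity, valid)
    out = {"np": float(len(patches))}

    if patches:
        areas = [len(p) * cell_ha for p in patches]
        out["area_mn"] = sum(areas) / len(areas)
        mean = out["area_mn"]
        out["area_sd"] = math.sqrt(sum((a - mean) ** 2 for a in areas) / len(areas))
        out["lpi"] = 100.0 * max(areas) / landscape_ha

        shapes, paras, fracs = [], [], []
        frac_ok = True
        for p in patches:
            perim_m = patch_perimeter_faces(p, values.shape) * resolution
            a_m2 = len(p) * resolution**2
            shapes.append(0.25 * perim_m / math.sqrt(a_m2))
            paras.append(perim_m / a_m2)
            if a_m2 == 1.0:
                frac_ok = False
            else:
                fracs.append(2.0 * math.log(0.25 * perim_m) / math.log(a_m2))
        out["shape_mn"] = sum(shapes) / len(shapes)
        out["para_mn"] = sum(paras) / len(paras)
        if frac_ok:
            out["frac_mn"] = sum(fracs) / len(fracs)

        if len(patches) >= 2:
            enns = []
            for i, p in enumerate(patches):
                other = [c for j, q in enumerate(patches) if j != i for c in q]
                best = min(
                    math.hypot(r - rr, c - cc) for r, c in p for rr, cc in other
                )
                enns.append(best * resolution)
            mean_e = sum(enns) / len(enns)
            out["enn_mn"] = mean_e
            out["enn_sd"] = math.sqrt(sum((e - mean_e) ** 2 for e in enns) / len(enns))

    # class edge: faces between class cells and valid non-class / outside
    edge_faces = 0
    for r in range(nrow):
        for c in range(ncol):
            if not valid[r, c] or values[r, c] != class_id:
                continue
            for dr, dc in OFFSETS[4]:
                rr, cc = r + dr, c + dc
                outside = not (0 <= rr < nrow and 0 <= cc < ncol) or not valid[rr, cc]
                if outside or values[rr, cc] != class_id:
                    edge_faces += 1
    edge_m = edge_faces * resolution
    out["ed"] = edge_m / landscape_ha
    class_cells = int(((values == class_id) & valid).sum())
    if class_cells:
        out["lsi"] = 0.25 * edge_m / math.sqrt(class_cells * resolution**2)

    # contagion over all classes, 4-neighbor adjacencies counted both ways
    classes = sorted(set(values[valid].tolist()))
    if len(classes) >= 2:
        idx = {c: i for i, c in enumerate(classes)}
        m = len(classes)
        g = [[0] * m for _ in range(m)]
        for r in range(nrow):
            for c in range(ncol):
                if not valid[r, c]:
                    continue
                for dr, dc in OFFSETS[4]:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc]:
                        g[idx[values[r, c]]][idx[values[rr, cc]]] += 1
        pi = [int(((values == cls) & valid).sum()) / n_valid for cls in classes]
        s = 0.0
        for i in range(m):
            tot = sum(g[i])
            if tot == 0:
                continue
            for k in range(m):
                q = pi[i] * g[i][k] / tot
                if q > 0:
                    s += q * math.log(q)
        out["contag"] = (1.0 + s / (2.0 * math.log(m))) * 100.0
    return out


def morans_i(values):
    """Moran's I with queen (8-neighbor) binary weights, direct double sum."""
    values = np.asarray(values, dtype=float)
    nrow, ncol = values.shape
    mean = values.mean()
    dev = values - mean
    num = 0.0
    w_sum = 0
    for r in range(nrow):
        for c in range(ncol):
            for dr, dc in OFFSETS[8]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol:
                    num += dev[r, c] * dev[rr, cc]
                    w_sum += 1
    denom = (dev**2).sum()
    n = values.size
    return (n / w_sum) * (num / denom)
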