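"""Configuration-driven orchestration of the three generation steps.

:func:`run_pipeline` turns one YAML-serializable :class:`RunConfig` into
a run directory holding the requested raster views, the serialized
landscape, the arable-class metric profile and a log of effective
parameters.  A single master seed deterministically derives every
sub-seed, so identical configs produce byte-identical outputs.

:func:`run_gradient_experiment` sweeps potential-space share against
arable cover (plus field size/shape and replicate seeds) and profiles
the *seminatural* class — potential space not converted to fields — the
conservation-relevant land in share scenarios.  Cells are partitioned
exactly into three classes: arable fields (1), seminatural habitat (2)
and matrix (3, outside the potential space).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import (
    CropPortfolio,
    FarmerParams,
    distribute_crops,
    distribute_farmers,
    extract_view,
    write_legend,
)
from .grid import Grid, read_raster, write_raster
from .linear import PathSpec, buffer_path, exclude_from_potential, least_cost_path
from .metrics import compute_profile
from .placement import FieldParams, Landscape, establish_dl, establish_pac
from .potential import (
    PerlinParams,
    PotentialSpace,
    categorize_by_share,
    categorize_by_threshold,
    generate_perlin_slope,
    load_external,
)

__all__ = ["RunConfig", "run_pipeline", "run_gradient_experiment", "GRADIENT_METRICS"]

#: Seminatural-class profile reported by the gradient experiment.
GRADIENT_METRICS = ("area_mn", "lpi", "frac_mn", "para_mn", "enn_mn", "np")


@dataclass
class RunConfig:
    """Everything one generator run needs; round-trips through YAML."""

    nrow: int = 100
    ncol: int = 100
    resolution: float = 10.0
    master_seed: int = 0
    # potential space
    space_method: str = "perlin_share"  # perlin_share | perlin_threshold | external
    perlin: dict = field(default_factory=dict)  # PerlinParams overrides
    space_share: float = 0.6
    space_threshold: float = 45.0
    external_mask: str | None = None
    # linear features: list of {cost_kind, width, start?, end?}
    features: list = field(default_factory=list)
    # placement
    algorithm: str = "pac"  # pac | dl
    field_params: dict = field(default_factory=dict)  # FieldParams overrides
    # enrichment (optional)
    farmers: dict | None = None  # FarmerParams overrides
    crops: list | None = None  # [[crop_id, share], ...]
    # outputs
    views: list = field(default_factory=lambda: ["field", "potential_space"])
    raster_format: str = "ascii_grid"

    def validate(self) -> None:
        if self.space_method not in ("perlin_share", "perlin_threshold", "external"):
            raise ValueError(f"unknown space_method {self.space_method!r}")
        if self.algorithm not in ("pac", "dl"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.space_method == "external" and not self.external_mask:
            raise ValueError("space_method 'external' needs external_mask")
        if "crop" in self.views and not self.crops:
            raise ValueError("crop view requested but no crop portfolio configured")
        if "farmer" in self.views and self.farmers is None:
            raise ValueError("farmer view requested but no farmer parameters configured")
        if self.features and self.space_method == "external":
            raise ValueError("linear features need a generated slope map")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).is_file():
            text = Path(text).read_text()
        doc = yaml.safe_load(text)
        return cls(**doc)


def _subseeds(master_seed: int, n: int = 8) -> list:
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _build_space(cfg: RunConfig, seeds: list) -> tuple[PotentialSpace, Grid | None]:
    if cfg.space_method == "external":
        mask = read_raster(cfg.external_mask)
        return load_external(mask), None
    perlin = PerlinParams(**{**cfg.perlin, "seed": seeds[0]})
    slope = generate_perlin_slope(cfg.nrow, cfg.ncol, perlin)
    slope.resolution = cfg.resolution
    if cfg.space_method == "perlin_share":
        return categorize_by_share(slope, cfg.space_share), slope
    return categorize_by_threshold(slope, cfg.space_threshold), slope


def build_landscape(cfg: RunConfig) -> Landscape:
    """Run the three generation steps for one config (no file output)."""
    cfg.validate()
    seeds = _subseeds(cfg.master_seed, 8 + len(cfg.features))
    space, slope = _build_space(cfg, seeds)

    for i, feat in enumerate(cfg.features):
        spec = PathSpec(
            start=tuple(feat["start"]) if "start" in feat else "random_edge",
            end=tuple(feat["end"]) if "end" in feat else "random_edge",
            cost_kind=feat.get("cost_kind", "road"),
            width=feat.get("width", 1),
            seed=seeds[8 + i],
        )
        path = least_cost_path(slope, spec)
        cells = buffer_path(path, spec.width, slope.shape)
        space = exclude_from_potential(space, cells)

    fp = FieldParams(**{**cfg.field_params, "seed": seeds[1]})
    place = establish_pac if cfg.algorithm == "pac" else establish_dl
    landscape = place(space, fp)

    if cfg.farmers is not None and landscape.fields:
        landscape = distribute_farmers(
            landscape, FarmerParams(**{**cfg.farmers, "seed": seeds[2]})
        )
    if cfg.crops and landscape.fields:
        portfolio = CropPortfolio([(str(c), float(s)) for c, s in cfg.crops])
        landscape = distribute_crops(landscape, portfolio, seed=seeds[3])
    return landscape


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute a config and write all requested artifacts to ``outdir``.

    Writes: one raster per requested view (plus a JSON legend), the
    serialized landscape, the arable-class metric profile, the effective
    config and a parameter log.  Identical configs produce byte-identical
    outputs.
    """
    cfg.validate()  # fail before any computation on inconsistent configs
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = build_landscape(cfg)

    ext = ".tif" if cfg.raster_format == "geotiff" else ".asc"
    for view in cfg.views:
        grid, legend = extract_view(landscape, view)
        write_raster(grid, outdir / f"{view}{ext}", cfg.raster_format)
        write_legend(legend, outdir / f"{view}_legend.json")

    landscape.to_json(outdir / "landscape.json")
    arable = Grid((landscape.field_id_array() > 0).astype(np.int8), cfg.resolution)
    if landscape.fields:
        compute_profile(arable, 1).to_csv(outdir / "profile.csv")
    cfg.to_yaml(outdir / "config.yaml")

    lines = [
        "agroscape run log",
        f"master_seed: {cfg.master_seed}",
        f"grid: {cfg.nrow}x{cfg.ncol} at {cfg.resolution} m",
        f"space_method: {cfg.space_method}",
        f"algorithm: {cfg.algorithm}",
        f"fields placed: {len(landscape.fields)}",
        f"realized coverage: {landscape.total_field_cells() / max(landscape.space.n_available, 1):.6f}",
        f"coverage shortfall: {landscape.coverage_shortfall}",
    ]
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# Double-gradient experiment
# ---------------------------------------------------------------------------


def three_class_map(landscape: Landscape) -> Grid:
    """Partition cells into arable (1), seminatural (2) and matrix (3)."""
    mask = landscape.space.mask.values.astype(bool)
    arable = landscape.field_id_array() > 0
    out = np.full(mask.shape, 3, dtype=np.int8)
    out[mask] = 2
    out[arable] = 1
    return Grid(out, landscape.resolution)


def run_gradient_experiment(
    space_shares,
    arable_shares,
    sizes,
    shapes,
    seeds,
    nrow: int = 100,
    ncol: int = 100,
    resolution: float = 10.0,
    latin_hypercube: int | None = None,
    perlin: PerlinParams | None = None,
    target_class: int = 2,
) -> pd.DataFrame:
    """Sweep potential-space share × arable cover (× size × shape × seed).

    For every combination a landscape is generated, cells are classified
    into arable / seminatural / matrix, and the seminatural class (or
    ``target_class``) is profiled with :data:`GRADIENT_METRICS`.  With
    ``latin_hypercube=n`` a seeded n-point subsample of the full
    factorial is evaluated instead.  Returns a long-format table with one
    row per (combination, metric).
    """
    for name, lst in (
        ("space_shares", space_shares),
        ("arable_shares", arable_shares),
        ("sizes", sizes),
        ("shapes", shapes),
        ("seeds", seeds),
    ):
        if not len(lst):
            raise ValueError(f"{name} must be non-empty")
    combos = list(product(space_shares, arable_shares, sizes, shapes, seeds))
    if latin_hypercube is not None and latin_hypercube < len(combos):
        rng = np.random.default_rng(int(seeds[0]))
        idx = rng.choice(len(combos), size=latin_hypercube, replace=False)
        combos = [combos[int(i)] for i in sorted(idx)]

    base_perlin = PerlinParams() if perlin is None else perlin
    rows = []
    for space_share, arable_share, size, shape, seed in combos:
        sub = _subseeds(int(seed), 2)
        slope = generate_perlin_slope(
            nrow, ncol, dataclasses.replace(base_perlin, seed=sub[0])
        )
        slope.resolution = resolution
        space = categorize_by_share(slope, float(space_share))
        if float(arable_share) == 0.0:
            # no arable conversion: the seminatural class is the whole space
            fp = FieldParams(mean_size=float(size), mean_shape=float(shape), seed=sub[1])
            landscape = Landscape([], space, fp)
        else:
            fp = FieldParams(
                mean_size=float(size),
                mean_shape=float(shape),
                coverage=float(arable_share),
                seed=sub[1],
            )
            landscape = establish_pac(space, fp)
        classes = three_class_map(landscape)
        if (classes.values == target_class).any():
            profile = compute_profile(classes, target_class, metrics=GRADIENT_METRICS)
        else:
            profile = None
        for metric in GRADIENT_METRICS:
            value = profile[metric] if profile is not None and metric in profile else np.nan
            rows.append(
                {
                    "space_share": float(space_share),
                    "arable_share": float(arable_share),
                    "mean_size": float(size),
                    "mean_shape": float(shape),
                    "seed": int(seed),
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
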