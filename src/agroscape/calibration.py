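"""Pattern-oriented calibration of the generator with a genetic algorithm.

A chromosome encodes a searchable subset of generator parameters (noise
frequency and octaves, potential-space share, field coverage, field size
and shape).  Fitness of a chromosome is the metric-profile similarity
(:func:`agroscape.metrics.profile_distance`, 1 = perfect match) between
landscapes generated from the decoded parameters and a reference profile,
averaged over a few replicate landscapes to damp generator noise.  The GA
is a conventional elitist scheme: tournament selection (k = 3), uniform
crossover, per-gene Gaussian mutation clipped to the gene bounds.

Once calibrated, any number of *equivalent* landscapes — alike in the
optimized metrics, free in everything else — can be generated from the
best chromosome with fresh seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .grid import Grid
from .metrics import MetricProfile, compute_profile, profile_distance
from .placement import FieldParams, Landscape, establish_dl, establish_pac
from .potential import PerlinParams, categorize_by_share, generate_perlin_slope

__all__ = [
    "GENE_NAMES",
    "Chromosome",
    "GAConfig",
    "GeneratorSetup",
    "simulate_landscape",
    "arable_class_grid",
    "landscape_profile",
    "evaluation_seed",
    "fitness",
    "run_ga",
    "generate_equivalents",
]

#: Parameters a chromosome may expose, in canonical order.
GENE_NAMES = (
    "frequency",
    "octaves",
    "share",
    "coverage",
    "mean_size",
    "sd_size",
    "mean_shape",
)


@dataclass
class Chromosome:
    """Real-valued parameter vector with per-gene bounds."""

    genes: np.ndarray
    names: tuple
    bounds: tuple

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        self.names = tuple(self.names)
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if not (len(self.genes) == len(self.names) == len(self.bounds)):
            raise ValueError("genes, names and bounds must have equal length")
        unknown = set(self.names) - set(GENE_NAMES)
        if unknown:
            raise ValueError(f"unknown gene names: {sorted(unknown)}")
        for g, (lo, hi) in zip(self.genes, self.bounds):
            if not lo <= g <= hi:
                raise ValueError(f"gene value {g} outside bounds ({lo}, {hi})")

    def as_dict(self) -> dict:
        return dict(zip(self.names, (float(g) for g in self.genes)))


@dataclass
class GAConfig:
    population: int = 20
    generations: int = 30
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism: int = 1
    replicates_per_eval: int = 3
    metric_subset: tuple = ("np", "area_mn", "area_sd")
    seed: int = 0
    stop_at_fitness: float | None = None  # optional early stop on best fitness

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be < population")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class GeneratorSetup:
    """Fixed context the chromosome is decoded into."""

    nrow: int = 100
    ncol: int = 100
    resolution: float = 10.0
    perlin: PerlinParams = field(default_factory=PerlinParams)
    share: float = 0.6
    field_params: FieldParams = field(default_factory=FieldParams)
    algorithm: str = "pac"
    connectivity: int = 8


def decode(chrom: Chromosome, setup: GeneratorSetup) -> GeneratorSetup:
    """Apply chromosome genes onto a copy of the fixed setup."""
    genes = chrom.as_dict()
    perlin = replace(setup.perlin)
    fp = replace(setup.field_params)
    out = replace(setup, perlin=perlin, field_params=fp)
    if "frequency" in genes:
        perlin.frequency = max(genes["frequency"], 1e-6)
    if "octaves" in genes:
        perlin.octaves = max(1, int(round(genes["octaves"])))
    if "share" in genes:
        out.share = float(np.clip(genes["share"], 1e-6, 1.0))
    if "coverage" in genes:
        fp.coverage = float(np.clip(genes["coverage"], 1e-6, 1.0))
    if "mean_size" in genes:
        fp.mean_size = max(genes["mean_size"], 1e-6)
    if "sd_size" in genes:
        fp.sd_size = max(genes["sd_size"], 0.0)
    if "mean_shape" in genes:
        fp.mean_shape = max(genes["mean_shape"], 1.0)
    return out


def simulate_landscape(setup: GeneratorSetup, seed: int) -> Landscape:
    """One full generator run: noise → share categorization → placement."""
    ss = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    perlin = replace(setup.perlin, seed=int(ss[0]))
    slope = generate_perlin_slope(setup.nrow, setup.ncol, perlin)
    slope.resolution = setup.resolution
    space = categorize_by_share(slope, setup.share)
    fp = replace(setup.field_params, seed=int(ss[1]))
    place = establish_pac if setup.algorithm == "pac" else establish_dl
    return place(space, fp)


def arable_class_grid(landscape: Landscape) -> Grid:
    """Binary raster of arable (field) cells."""
    arr = (landscape.field_id_array() > 0).astype(np.int8)
    return Grid(arr, landscape.resolution)


def landscape_profile(
    landscape: Landscape,
    metrics: Sequence[str] | None = None,
    connectivity: int = 8,
) -> MetricProfile:
    """Metric profile of the arable class of a generated landscape."""
    return compute_profile(
        arable_class_grid(landscape), 1, connectivity=connectivity, metrics=metrics
    )


def evaluation_seed(cfg: GAConfig, eval_index: int, replicate: int) -> int:
    """Deterministic sub-seed for one fitness replicate (< 2^31)."""
    state = np.random.SeedSequence((cfg.seed, eval_index, replicate)).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


def fitness(
    chrom: Chromosome,
    reference: MetricProfile,
    cfg: GAConfig,
    setup: GeneratorSetup | None = None,
    eval_index: int = 0,
) -> float:
    """Mean profile similarity of replicate landscapes to the reference.

    Degenerate parameter combinations that yield no fields (or leave the
    requested metrics undefined) score 0, never raise.
    """
    setup = GeneratorSetup() if setup is None else setup
    decoded = decode(chrom, setup)
    scores = []
    for rep in range(cfg.replicates_per_eval):
        seed = evaluation_seed(cfg, eval_index, rep)
        try:
            landscape = simulate_landscape(decoded, seed)
        except ValueError:
            scores.append(0.0)
            continue
        if not landscape.fields:
            scores.append(0.0)
            continue
        profile = landscape_profile(
            landscape, metrics=cfg.metric_subset, connectivity=decoded.connectivity
        )
        try:
            scores.append(profile_distance(profile, reference, cfg.metric_subset))
        except KeyError:
            scores.append(0.0)
    return float(np.mean(scores))


def _init_population(
    bounds: Mapping[str, tuple], cfg: GAConfig, rng: np.random.Generator
) -> list:
    names = tuple(bounds.keys())
    bnds = tuple(bounds[n] for n in names)
    pop = []
    for _ in range(cfg.population):
        genes = np.array([rng.uniform(lo, hi) for lo, hi in bnds])
        pop.append(Chromosome(genes, names, bnds))
    return pop


def run_ga(
    reference: MetricProfile,
    bounds: Mapping[str, tuple],
    cfg: GAConfig,
    setup: GeneratorSetup | None = None,
    fitness_fn: Callable | None = None,
) -> tuple[Chromosome, list]:
    """Elitist GA search for generator parameters matching a reference.

    ``bounds`` maps gene names (a subset of :data:`GENE_NAMES`) to
    (low, high).  ``fitness_fn(chromosome, eval_index) -> float`` may be
    injected (benchmarks, tests); the default evaluates
    :func:`fitness` against ``reference``.  Returns the best-ever
    chromosome and the per-generation best-fitness trace.  Fully seeded.
    """
    setup = GeneratorSetup() if setup is None else setup
    rng = np.random.default_rng(cfg.seed)
    if fitness_fn is None:
        def fitness_fn(ch: Chromosome, eval_index: int) -> float:
            return fitness(ch, reference, cfg, setup, eval_index)

    names = tuple(bounds.keys())
    bnds = tuple((float(lo), float(hi)) for lo, hi in (bounds[n] for n in names))
    ranges = np.array([hi - lo for lo, hi in bnds])

    population = _init_population(bounds, cfg, rng)
    scores: list[float | None] = [None] * cfg.population
    eval_counter = 0
    best_chrom: Chromosome | None = None
    best_score = -np.inf
    trace: list[float] = []

    for _generation in range(cfg.generations):
        for i, ch in enumerate(population):
            if scores[i] is None:
                scores[i] = fitness_fn(ch, eval_counter)
                eval_counter += 1
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_score = float(scores[gen_best])
            best_chrom = population[gen_best]
        trace.append(best_score)
        if cfg.stop_at_fitness is not None and best_score >= cfg.stop_at_fitness:
            break

        order = np.argsort(scores)[::-1]
        elites = [(population[int(i)], float(scores[int(i)])) for i in order[: cfg.elitism]]

        def tournament() -> Chromosome:
            picks = rng.integers(cfg.population, size=3)
            winner = max(picks, key=lambda i: scores[int(i)])
            return population[int(winner)]

        children: list[Chromosome] = []
        child_scores: list[float | None] = []
        for ch, sc in elites:
            children.append(ch)
            child_scores.append(sc)  # elites keep their evaluated fitness
        while len(children) < cfg.population:
            pa = np.array(tournament().genes)
            pb = np.array(tournament().genes)
            if rng.random() < cfg.crossover_prob:
                swap = rng.random(len(pa)) < 0.5
                pa[swap], pb[swap] = pb[swap], pa[swap].copy()
            for genes in (pa, pb):
                if len(children) >= cfg.population:
                    break
                mutate = rng.random(len(genes)) < cfg.mutation_prob
                noise = rng.normal(0.0, 0.1 * ranges)
                genes = np.where(mutate, genes + noise, genes)
                genes = np.clip(genes, [lo for lo, _ in bnds], [hi for _, hi in bnds])
                children.append(Chromosome(genes, names, bnds))
                child_scores.append(None)
        population = children
        scores = child_scores

    assert best_chrom is not None
    return best_chrom, trace


def generate_equivalents(
    best: Chromosome,
    n: int,
    seed: int,
    setup: GeneratorSetup | None = None,
    optimized_metrics: Sequence[str] = ("np", "area_mn", "area_sd"),
    heldout_metrics: Sequence[str] = ("contag", "lpi", "frac_mn", "lsi", "shape_mn"),
) -> tuple[list, dict]:
    """Generate n landscapes from the calibrated parameters, distinct seeds.

    Returns the landscapes and a report with quartiles (q1, median, q3)
    of both the optimized and the held-out metrics across the sample —
    held-out metrics show how much freedom the calibration left.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    setup = GeneratorSetup() if setup is None else setup
    decoded = decode(best, setup)
    # n distinct seeds; n=1 with a known evaluation seed reproduces that map
    seeds = [(int(seed) + i) % 2**31 for i in range(n)]
    landscapes = [simulate_landscape(decoded, s) for s in seeds]
    wanted = tuple(optimized_metrics) + tuple(heldout_metrics)
    collected: dict[str, list] = {m: [] for m in wanted}
    for ls in landscapes:
        prof = landscape_profile(ls, metrics=wanted, connectivity=decoded.connectivity)
        for m in wanted:
            if m in prof:
                collected[m].append(prof[m])
    report = {
        "n_maps": n,
        "seeds": seeds,
        "optimized": {},
        "held_out": {},
    }
    for m in wanted:
        vals = np.array(collected[m])
        slot = "optimized" if m in optimized_metrics else "held_out"
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            report[slot][m] = {"q1": float(q1), "median": float(med), "q3": float(q3)}
    return landscapes, report
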