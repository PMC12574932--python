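"""Step 1: outline the potential agricultural space.

Two built-in generators are provided.  The Perlin-noise route synthesizes
a smooth pseudo-slope surface (rescaled to 0–90 degrees) and thresholds it
— either by a slope cut-off or by a requested share of gentle terrain —
into a binary mask of cells available for field placement.  The
hybrid-world route starts from a real (or realistic) land-cover map with a
single arable class, fits a cell-wise logistic regression of arable
membership on covariate rasters (slope, soil, agricultural limitation,
...), draws a stochastic suitability realization, and clusters it with
majority-vote smoothing so the resulting potential space is spatially
coherent and typically larger than the arable land it was fitted to.

An external binary raster can also be adopted directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import Grid

__all__ = [
    "PerlinParams",
    "HybridParams",
    "PotentialSpace",
    "generate_perlin_slope",
    "categorize_by_threshold",
    "categorize_by_share",
    "fit_hybrid",
    "apply_hybrid",
    "load_external",
]


@dataclass
class PerlinParams:
    """Fractal gradient-noise controls.

    frequency: cycles across the grid span of the base octave.
    octaves: number of noise layers summed.
    lacunarity: frequency multiplier per octave (> 1).
    gain: amplitude multiplier per octave (persistence), in (0, 1).
    """

    frequency: float = 4.0
    octaves: int = 3
    lacunarity: float = 2.0
    gain: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if not self.frequency > 0:
            raise ValueError("frequency must be > 0")
        if not self.lacunarity > 1:
            raise ValueError("lacunarity must be > 1")
        if not 0 < self.gain < 1:
            raise ValueError("gain must be in (0, 1)")


@dataclass
class PotentialSpace:
    """Binary availability mask (1 = a field may be placed here)."""

    mask: Grid
    source_map: Grid | None = None
    provenance: str = "external"

    def __post_init__(self) -> None:
        vals = self.mask.values
        if not np.isin(vals, (0, 1)).all():
            bad = np.unique(vals[~np.isin(vals, (0, 1))])
            raise ValueError(f"potential-space mask must be 0/1; found values {bad.tolist()}")
        if self.source_map is not None and self.source_map.shape != self.mask.shape:
            raise ValueError("source_map shape must match mask shape")

    @property
    def n_available(self) -> int:
        return int(self.mask.values.sum())

    def copy(self) -> "PotentialSpace":
        return PotentialSpace(
            self.mask.copy(),
            None if self.source_map is None else self.source_map.copy(),
            self.provenance,
        )


@dataclass
class HybridParams:
    """Fitted cell-wise logistic model plus smoothing controls.

    ``coefficients[0]`` is the intercept; one weight follows per covariate
    grid, in the order the covariates were supplied.
    """

    coefficients: np.ndarray
    smoothing_iterations: int = 2
    smoothing_connectivity: int = 8
    seed: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or self.coefficients.size < 1:
            raise ValueError("coefficients must be a 1-D vector (intercept first)")
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")
        if self.smoothing_connectivity not in (4, 8):
            raise ValueError("smoothing_connectivity must be 4 or 8")


# ---------------------------------------------------------------------------
# Perlin noise
# ---------------------------------------------------------------------------


def _fade(t: np.ndarray) -> np.ndarray:
    # classic quintic smoothstep: 6t^5 - 15t^4 + 10t^3
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def _gradient_layer(nrow: int, ncol: int, freq: float, rng: np.random.Generator) -> np.ndarray:
    """One octave of 2-D lattice gradient noise, sampled at cell centers."""
    y = (np.arange(nrow) + 0.5) / nrow * freq
    x = (np.arange(ncol) + 0.5) / ncol * freq
    yy, xx = np.meshgrid(y, x, indexing="ij")
    y0 = np.floor(yy).astype(int)
    x0 = np.floor(xx).astype(int)
    fy = yy - y0
    fx = xx - x0

    n_lat_y = int(np.floor(y[-1])) + 2
    n_lat_x = int(np.floor(x[-1])) + 2
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(n_lat_y, n_lat_x))
    gy = np.sin(angles)
    gx = np.cos(angles)

    def dot(iy: np.ndarray, ix: np.ndarray, dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
        return gy[iy, ix] * dy + gx[iy, ix] * dx

    d00 = dot(y0, x0, fy, fx)
    d01 = dot(y0, x0 + 1, fy, fx - 1.0)
    d10 = dot(y0 + 1, x0, fy - 1.0, fx)
    d11 = dot(y0 + 1, x0 + 1, fy - 1.0, fx - 1.0)

    uy = _fade(fy)
    ux = _fade(fx)
    top = d00 + ux * (d01 - d00)
    bot = d10 + ux * (d11 - d10)
    return top + uy * (bot - top)


def generate_perlin_slope(nrow: int, ncol: int, params: PerlinParams) -> Grid:
    """Synthesize a pseudo-slope map in degrees.

    Multi-octave gradient noise is summed and min–max rescaled to
    [0, 90]°, so every map attains 0° and 90° somewhere. Deterministic
    given ``params.seed``.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(params.octaves)
    total = np.zeros((nrow, ncol))
    freq = params.frequency
    amp = 1.0
    for ss in seeds:
        total += amp * _gradient_layer(nrow, ncol, freq, np.random.default_rng(ss))
        freq *= params.lacunarity
        amp *= params.gain
    lo, hi = total.min(), total.max()
    if hi - lo < 1e-12:
        scaled = np.zeros_like(total)
    else:
        scaled = (total - lo) / (hi - lo) * 90.0
    return Grid(scaled)


def categorize_by_threshold(slope_map: Grid, threshold: float) -> PotentialSpace:
    """Cells at or below the slope threshold become potential space.

    Gentle terrain is farmable: mask = 1 where value <= threshold.
    """
    if not 0 <= threshold <= 90:
        raise ValueError("threshold must be within [0, 90] degrees")
    mask = (slope_map.values <= threshold).astype(np.int8)
    return PotentialSpace(
        Grid(mask, slope_map.resolution), source_map=slope_map, provenance="perlin_threshold"
    )


def categorize_by_share(slope_map: Grid, share: float) -> PotentialSpace:
    """Mark the flattest ``share`` fraction of valid cells as potential space.

    The ⌈share·N⌉ cells with the lowest map values are selected; ties are
    broken by row-major scan order, so the realized cover is within one
    cell of the request (exact when values are distinct).
    """
    if not 0 < share <= 1:
        raise ValueError("share must be in (0, 1]")
    valid = slope_map.valid_mask()
    n_valid = int(valid.sum())
    k = int(np.ceil(share * n_valid))
    flat_vals = slope_map.values.astype(float).copy()
    flat_vals[~valid] = np.inf
    order = np.argsort(flat_vals.ravel(), kind="stable")
    mask = np.zeros(flat_vals.size, dtype=np.int8)
    mask[order[:k]] = 1
    mask = mask.reshape(slope_map.shape)
    return PotentialSpace(
        Grid(mask, slope_map.resolution), source_map=slope_map, provenance="perlin_share"
    )


# ---------------------------------------------------------------------------
# Hybrid world: cell-wise logistic suitability + majority-vote clustering
# ---------------------------------------------------------------------------


def _design_matrix(covariates: Sequence[Grid], shape: tuple[int, int]) -> np.ndarray:
    n = shape[0] * shape[1]
    X = np.ones((n, 1 + len(covariates)))
    for j, cov in enumerate(covariates):
        if cov.shape != shape:
            raise ValueError("covariate shape mismatch")
        X[:, 1 + j] = cov.values.ravel()
    return X


def fit_hybrid(
    landcover_arable: Grid,
    covariates: Sequence[Grid] = (),
    *,
    smoothing_iterations: int = 2,
    smoothing_connectivity: int = 8,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HybridParams:
    """Fit a cell-wise binomial-logistic model of arable membership.

    Each raster cell is one observation; the response is the binary arable
    indicator and the predictors are the covariate values at that cell.
    Fitting is iteratively-reweighted least squares, stopped at gradient
    norm ``tol`` or ``max_iter`` sweeps.  Perfect separation does not
    raise: the coefficients at the iteration cap are returned with
    ``converged=False`` and a warning.
    """
    y = np.asarray(landcover_arable.values).ravel().astype(float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("arable land-cover grid must be binary 0/1")
    X = _design_matrix(covariates, landcover_arable.shape)

    if len(covariates) == 0:
        p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        beta = np.array([np.log(p / (1 - p))])
        return HybridParams(beta, smoothing_iterations, smoothing_connectivity, seed, True)

    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        beta = beta + step
    # diverging coefficients with a vanishing gradient indicate separation:
    # the likelihood maximum sits at infinity and the fit is not identified
    if converged and np.abs(beta).max() > 30:
        converged = False
    if not converged:
        warnings.warn(
            "logistic fit did not converge to a finite optimum (possible "
            "perfect separation); returning the coefficients reached",
            RuntimeWarning,
        )
    return HybridParams(beta, smoothing_iterations, smoothing_connectivity, seed, converged)


_NEIGH_KERNELS = {
    4: np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float),
    8: np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float),
}


def majority_smooth(mask: np.ndarray, iterations: int, connectivity: int = 8) -> np.ndarray:
    """Synchronous strict-majority-vote smoothing of a binary field.

    Each sweep, every cell adopts the state held by a strict majority of
    its in-bounds neighbors; on a tie the cell keeps its state.
    """
    kernel = _NEIGH_KERNELS[connectivity]
    state = np.asarray(mask, dtype=float)
    n_neigh = ndimage.correlate(np.ones_like(state), kernel, mode="constant", cval=0.0)
    for _ in range(iterations):
        ones = ndimage.correlate(state, kernel, mode="constant", cval=0.0)
        zeros = n_neigh - ones
        state = np.where(ones > zeros, 1.0, np.where(zeros > ones, 0.0, state))
    return state.astype(np.int8)


def apply_hybrid(
    params: HybridParams, covariates: Sequence[Grid], seed: int | None = None
) -> PotentialSpace:
    """Realize a potential space from a fitted hybrid model.

    Per cell: logistic probability → independent Bernoulli draw →
    ``smoothing_iterations`` synchronous majority-vote sweeps.
    Deterministic given the seed.
    """
    if len(covariates) != params.coefficients.size - 1:
        raise ValueError(
            f"model expects {params.coefficients.size - 1} covariates, "
            f"got {len(covariates)}"
        )
    if len(covariates) == 0:
        raise ValueError("apply_hybrid needs at least the grid shape via one covariate")
    shape = covariates[0].shape
    X = _design_matrix(covariates, shape)
    prob = 1.0 / (1.0 + np.exp(-(X @ params.coefficients))).reshape(shape)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    raw = (rng.random(shape) < prob).astype(np.int8)
    mask = majority_smooth(raw, params.smoothing_iterations, params.smoothing_connectivity)
    return PotentialSpace(Grid(mask, covariates[0].resolution), provenance="hybrid")


def load_external(mask: Grid) -> PotentialSpace:
    """Adopt an external binary raster as the potential space.

    NoData cells are treated as unavailable (0); any other non-binary
    value is an error.
    """
    values = np.asarray(mask.values).copy()
    if mask.nodata is not None:
        values = np.where(mask.valid_mask(), values, 0)
    bad = np.unique(values[~np.isin(values, (0, 1))])
    if bad.size:
        raise ValueError(f"external potential space must be binary; found values {bad.tolist()}")
    return PotentialSpace(Grid(values.astype(np.int8), mask.resolution), provenance="external")
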