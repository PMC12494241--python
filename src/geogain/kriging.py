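"""Ordinary kriging over points and regular grids.

Ordinary kriging (OK) is the best linear unbiased predictor of a spatially
correlated variable under an unknown constant mean: the weights lambda_i
solve

    [ Gamma  1 ] [ lambda ]   [ gamma_0 ]
    [ 1^T    0 ] [  mu    ] = [   1     ]

where Gamma[i,j] = gamma(|s_i - s_j|) between training points, gamma_0 the
semivariances to the target, and mu the Lagrange multiplier enforcing
sum(lambda) = 1. The estimate is sum(lambda_i z_i) and the kriging variance
lambda . gamma_0 + mu.

Neighborhoods follow yield-mapping practice: either a global search capped
at ``max_neighbors`` nearest points, or a local search limited additionally
by ``max_search_distance``. Distance ties are broken by lowest point index,
so output is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .errors import ConfigurationError, DegenerateGeometryError, KrigingError
from .io_geodata import RasterGrid
from .variogram import VariogramModel, model_gamma

logger = logging.getLogger(__name__)

DEFAULT_MIN_NEIGHBORS = 16
DEFAULT_MAX_NEIGHBORS = 20
DEFAULT_MAX_DISTANCE = 1000.0


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Search-neighborhood settings for the kriging solver."""

    mode: str = "global"
    max_search_distance: float = DEFAULT_MAX_DISTANCE
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS

    def __post_init__(self):
        if self.mode not in ("global", "local"):
            raise ConfigurationError(f"neighborhood mode must be global|local, got {self.mode!r}")
        if self.min_neighbors < 1 or self.max_neighbors < self.min_neighbors:
            raise ConfigurationError("need 1 <= min_neighbors <= max_neighbors")
        if self.mode == "local" and self.max_search_distance <= 0:
            raise ConfigurationError("local mode needs max_search_distance > 0")


@dataclass(frozen=True)
class GridSpec:
    """Regular-grid geometry: bounds padded up to a whole number of pixels.

    Row 0 sits at the north edge; cell centers are origin + (index+0.5)*pixel.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    pixel: float

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ConfigurationError("grid bounds must have positive extent")
        if self.pixel <= 0:
            raise ConfigurationError("pixel size must be positive")

    @property
    def ncols(self) -> int:
        return int(math.ceil((self.xmax - self.xmin) / self.pixel - 1e-12))

    @property
    def nrows(self) -> int:
        return int(math.ceil((self.ymax - self.ymin) / self.pixel - 1e-12))

    @property
    def origin_x(self) -> float:
        return self.xmin

    @property
    def origin_y(self) -> float:
        """North edge of the grid (ymin padded up to whole pixels)."""
        return self.ymin + self.nrows * self.pixel

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.pixel
        ys = self.origin_y - (np.arange(self.nrows) + 0.5) * self.pixel
        return np.meshgrid(xs, ys)

    @classmethod
    def from_bounds(cls, bounds, pixel: float) -> "GridSpec":
        xmin, ymin, xmax, ymax = bounds
        return cls(xmin, ymin, xmax, ymax, pixel)


def _validate_training(coords: np.ndarray, values: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) != len(values):
        raise ConfigurationError("training data must be (n,2) coords and n values")
    if len(coords) < 2:
        raise DegenerateGeometryError("kriging needs at least 2 training points")
    if np.allclose(coords, coords[0]):
        raise DegenerateGeometryError("all training points are coincident")
    return coords, values


def _select_neighbors(coords: np.ndarray, target: np.ndarray,
                      nb: NeighborhoodConfig) -> np.ndarray:
    """Indices of admissible neighbors, nearest first; ties by lowest index."""
    d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    if nb.mode == "local":
        admissible = np.flatnonzero(d <= nb.max_search_distance)
    else:
        admissible = np.arange(len(coords))
    if admissible.size == 0:
        return admissible
    order = np.lexsort((admissible, d[admissible]))
    sel = admissible[order][: nb.max_neighbors]
    if sel.size < nb.min_neighbors:
        logger.warning("only %d neighbor(s) available (< min_neighbors=%d)",
                       sel.size, nb.min_neighbors)
    return np.sort(sel)


def _ok_matrix(coords: np.ndarray, vm: VariogramModel) -> np.ndarray:
    n = len(coords)
    dx = coords[:, 0][:, None] - coords[:, 0][None, :]
    dy = coords[:, 1][:, None] - coords[:, 1][None, :]
    G = model_gamma(vm, np.hypot(dx, dy).ravel()).reshape(n, n)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = G
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def _ok_rhs(coords: np.ndarray, target: np.ndarray, vm: VariogramModel) -> np.ndarray:
    d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    b = np.empty(len(coords) + 1)
    b[:-1] = model_gamma(vm, d)
    b[-1] = 1.0
    return b


def ok_weights(coords: np.ndarray, vm: VariogramModel, target) -> tuple[np.ndarray, float]:
    """Kriging weights and Lagrange multiplier for one target (full system)."""
    coords = np.asarray(coords, dtype=float)
    target = np.asarray(target, dtype=float)
    A = _ok_matrix(coords, vm)
    b = _ok_rhs(coords, target, vm)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise KrigingError(f"singular kriging system at target {tuple(target)}: {exc}")
    return sol[:-1], float(sol[-1])


def krige_point(coords, values, vm: VariogramModel, target,
                nb: NeighborhoodConfig | None = None) -> tuple[float, float]:
    """OK estimate and kriging variance at one target location.

    Returns (nan, nan) when no admissible neighbor exists (masked result).
    """
    nb = nb or NeighborhoodConfig()
    coords, values = _validate_training(coords, values)
    target = np.asarray(target, dtype=float)
    sel = _select_neighbors(coords, target, nb)
    if sel.size == 0:
        return float("nan"), float("nan")
    w, mu = ok_weights(coords[sel], vm, target)
    est = float(w @ values[sel])
    var = float(w @ _ok_rhs(coords[sel], target, vm)[:-1] + mu)
    return est, var


def krige_grid(coords, values, vm: VariogramModel, spec: GridSpec,
               nb: NeighborhoodConfig | None = None,
               crs: int | None = None) -> RasterGrid:
    """OK estimate at every cell center of the grid; nodata where no neighbors.

    When the whole training set fits inside ``max_neighbors`` (and, in global
    mode, regardless of distance) the kriging matrix is factorised once and
    reused for every cell; otherwise a per-cell neighborhood system is solved.
    """
    nb = nb or NeighborhoodConfig()
    coords, values = _validate_training(coords, values)
    n = len(coords)
    xs, ys = spec.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])
    est = np.full(len(targets), np.nan)

    shared = n <= nb.max_neighbors and (
        nb.mode == "global" or _max_dist_ok(coords, targets, nb.max_search_distance))
    if shared:
        A = _ok_matrix(coords, vm)
        try:
            lu = lu_factor(A)
        except Exception as exc:
            raise KrigingError(f"singular kriging system: {exc}")
        d = np.hypot(targets[:, 0][:, None] - coords[:, 0][None, :],
                     targets[:, 1][:, None] - coords[:, 1][None, :])
        B = np.empty((n + 1, len(targets)))
        B[:n] = model_gamma(vm, d.ravel()).reshape(len(targets), n).T
        B[n] = 1.0
        W = lu_solve(lu, B)
        est = values @ W[:n]
    else:
        k = min(nb.max_neighbors, n)
        all_idx = np.arange(n)
        chunk = max(1, int(4e6) // max(n, 1))
        for start in range(0, len(targets), chunk):
            block = targets[start:start + chunk]
            d = np.hypot(block[:, 0][:, None] - coords[:, 0][None, :],
                         block[:, 1][:, None] - coords[:, 1][None, :])
            for i, t in enumerate(block):
                d_i, n_i = d[i], all_idx
                if nb.mode == "local":
                    keep = d_i <= nb.max_search_distance
                    d_i, n_i = d_i[keep], n_i[keep]
                if n_i.size == 0:
                    continue
                order = np.lexsort((n_i, d_i))
                sel = np.sort(n_i[order][:k])
                w, _ = ok_weights(coords[sel], vm, t)
                est[start + i] = w @ values[sel]

    grid_values = est.reshape(spec.nrows, spec.ncols)
    mask = ~np.isfinite(grid_values)
    grid_values = np.where(mask, 0.0, grid_values)
    return RasterGrid(origin_x=spec.origin_x, origin_y=spec.origin_y,
                      pixel=spec.pixel, values=grid_values, nodata_mask=mask,
                      crs=crs)


def _max_dist_ok(coords, targets, max_search_distance) -> bool:
    """True if every training point is within range of every target."""
    d = np.hypot(targets[:, 0][:, None] - coords[:, 0][None, :],
                 targets[:, 1][:, None] - coords[:, 1][None, :])
    return bool(np.all(d <= max_search_distance))
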