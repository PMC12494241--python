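"""End-to-end gain-mapping pipeline for strip-trial experiments.

For each treatment the samples are split 80/20 into a training and a test
set; the training set drives an ordinary-kriging estimate of the variable
over the study-area grid (the *base* surface). The base surface is sampled
at the held-out points, observed-minus-estimated residuals are kriged into
an *error* surface, and base + error gives the *final* surface, which is
clipped to the study area. Gain surfaces are cellwise differences between
the reference treatment's final surface and each other treatment's, and are
summarised by min/max/sum/mean/std over valid cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from . import crs as crs_mod
from .errors import (
    ConfigurationError,
    EmptyRasterError,
    EvaluationError,
    FitFailureError,
    GridMismatchError,
    HoldoutError,
    InsufficientStructureError,
    MissingTreatmentError,
)
from .io_geodata import (
    RasterGrid,
    SampleSet,
    StudyArea,
    reproject_area,
    reproject_samples,
    write_gain_report,
    write_raster,
)
from .kriging import GridSpec, NeighborhoodConfig, krige_grid
from .variogram import (
    DEFAULT_MAX_DIST,
    DEFAULT_N_LAGS,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GainStats:
    """Summary statistics of a gain surface over its valid cells."""

    minimum: float
    maximum: float
    sum: float
    mean: float
    std: float
    n_valid: int


@dataclass
class PipelineConfig:
    """Run parameters mirroring the tool's input panel."""

    reference_treatment: str = "T1"
    n_treatments: int | None = None
    pixel: float = 1.5
    model: str = "linear"
    target_crs: int | None = None
    holdout_fraction: float = 0.8
    seed: int = 0
    neighborhood: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    n_lags: int = DEFAULT_N_LAGS
    variogram_max_dist: float = DEFAULT_MAX_DIST
    #: bypass variogram fitting entirely (used for preset models)
    fixed_variogram: VariogramModel | None = None
    all_pairs: bool = False
    variable_field: str | None = None
    treatment_field: str | None = None

    def __post_init__(self):
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigurationError("holdout fraction must be in (0, 1)")
        if self.n_treatments is not None and not 2 <= self.n_treatments <= 5:
            raise ConfigurationError("number of treatments must be 2-5")


@dataclass
class TreatmentSurfaces:
    """All per-treatment rasters, sharing one grid geometry."""

    label: str
    base: RasterGrid
    error: RasterGrid
    final: RasterGrid
    final_clipped: RasterGrid
    train: SampleSet
    test: SampleSet
    base_variogram: VariogramModel
    residual_variogram: VariogramModel


@dataclass
class PipelineResult:
    surfaces: dict
    gains: dict
    gain_stats: dict
    run_log: dict


# ---------------------------------------------------------------------------
# individual stages


def split_by_treatment(s: SampleSet) -> dict:
    """Partition the sample set by treatment label (Extract by attribute)."""
    out = {}
    for label in s.treatment_labels:
        sub_mask = np.asarray([t == label for t in s.treatments])
        if not sub_mask.any():
            raise MissingTreatmentError(f"declared treatment {label} has no points")
        out[label] = s.subset(sub_mask)
    return out


def holdout_split(subset: SampleSet, fraction: float = 0.8,
                  seed: int = 0) -> tuple[SampleSet, SampleSet]:
    """Seeded random split into train (round(f*n), ties up) and test sets."""
    n = len(subset)
    if n < 5:
        raise HoldoutError(f"treatment subset has {n} point(s); need at least 5")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return subset.subset(train_idx), subset.subset(test_idx)


def sample_raster_at_points(g: RasterGrid, x, y, *,
                            crs: int | None = None) -> np.ma.MaskedArray:
    """Value of the cell containing each point; masked outside/nodata.

    No interpolation between cells: a point takes the value of its containing
    cell (half-open in x, top-edge-inclusive in y).
    """
    if crs is not None and g.crs is not None and int(crs) != int(g.crs):
        raise ConfigurationError(
            f"point CRS EPSG:{crs} does not match raster CRS EPSG:{g.crs}")
    row, col, inside = g.cell_index(x, y)
    vals = np.zeros(len(row))
    mask = ~inside
    r, c = row[inside], col[inside]
    vals[inside] = g.values[r, c]
    mask[inside] |= g.nodata_mask[r, c]
    return np.ma.MaskedArray(vals, mask=mask)


def residuals(observed, estimated) -> np.ndarray:
    """Observed minus estimated at the held-out points; masked pairs dropped."""
    observed = np.ma.asarray(observed, dtype=float)
    estimated = np.ma.asarray(estimated, dtype=float)
    if observed.shape != estimated.shape:
        raise ConfigurationError("observed and estimated lengths differ")
    pair_mask = np.ma.getmaskarray(observed) | np.ma.getmaskarray(estimated)
    if pair_mask.all():
        raise EvaluationError("all observation/estimate pairs are masked")
    return (np.asarray(observed.data) - np.asarray(estimated.data))[~pair_mask]


def _fit_or_fallback(coords, values, family, n_lags, max_dist,
                     fallback: VariogramModel) -> VariogramModel:
    """Fit a variogram; fall back to a safe model when structure is absent."""
    try:
        ev = empirical_variogram(coords, values, n_lags=n_lags, max_dist=max_dist)
        vm = fit_variogram(ev, family)
    except (InsufficientStructureError, FitFailureError) as exc:
        logger.warning("residual variogram fit failed (%s); using fallback", exc)
        return fallback
    # a fit that collapsed to zero variance would make the kriging
    # system singular; krige with a nugget-only model instead
    scale = vm.nugget + vm.partial_sill + vm.slope * max(np.ptp(coords), 1.0)
    if scale <= 1e-15:
        c0 = max(float(np.var(values)), 1e-12)
        return VariogramModel(vm.family if vm.family != "linear" else "spherical",
                              nugget=c0, partial_sill=0.0, range_=max_dist)
    return vm


def corrected_surface(base: RasterGrid, res_coords, res_values,
                      vm: VariogramModel, nb: NeighborhoodConfig, *,
                      refit: bool = True,
                      n_lags: int = DEFAULT_N_LAGS,
                      max_dist: float = DEFAULT_MAX_DIST
                      ) -> tuple[RasterGrid, RasterGrid]:
    """Krige the residuals onto the base grid and add them to the base.

    Returns (error surface, final surface). The residual variogram is
    refitted to the residuals with the same model family unless ``refit``
    is False, in which case ``vm`` is used directly.
    """
    res_coords = np.asarray(res_coords, dtype=float)
    res_values = np.asarray(res_values, dtype=float)
    if refit:
        res_vm = _fit_or_fallback(res_coords, res_values, vm.family,
                                  n_lags, max_dist, fallback=vm)
    else:
        res_vm = vm
    spec = GridSpec(base.origin_x, base.origin_y - base.nrows * base.pixel,
                    base.origin_x + base.ncols * base.pixel, base.origin_y,
                    base.pixel)
    error = krige_grid(res_coords, res_values, res_vm, spec, nb, crs=base.crs)
    mask = base.nodata_mask | error.nodata_mask
    final_vals = np.where(mask, 0.0, base.values + error.values)
    final = base.copy_with(final_vals, mask)
    return error, final


def clip_to_area(g: RasterGrid, a: StudyArea) -> RasterGrid:
    """Mask cells whose centers fall outside the study-area polygon."""
    if g.crs is not None and a.crs is not None and int(g.crs) != int(a.crs):
        raise ConfigurationError(
            f"raster CRS EPSG:{g.crs} does not match area CRS EPSG:{a.crs}")
    xs, ys = g.cell_centers()
    inside = shapely.intersects_xy(a.polygon, xs.ravel(), ys.ravel())
    inside = inside.reshape(g.values.shape)
    mask = g.nodata_mask | ~inside
    if mask.all():
        logger.warning("study area polygon is disjoint from the raster; "
                       "clip produced an all-masked grid")
    return g.copy_with(np.where(mask, 0.0, g.values), mask)


def gain_surface(ref: RasterGrid, other: RasterGrid) -> RasterGrid:
    """Cellwise reference minus other treatment; masked where either is."""
    if not ref.same_grid(other):
        raise GridMismatchError("gain requires two rasters on an identical grid")
    mask = ref.nodata_mask | other.nodata_mask
    vals = np.where(mask, 0.0, ref.values - other.values)
    return ref.copy_with(vals, mask)


def raster_stats(g: RasterGrid) -> GainStats:
    """Min/max/sum/mean/population-std over valid cells."""
    v = g.valid_values()
    if v.size == 0:
        raise EmptyRasterError("raster has no valid cells to summarise")
    return GainStats(
        minimum=float(v.min()), maximum=float(v.max()), sum=float(v.sum()),
        mean=float(v.mean()), std=float(v.std(ddof=0)), n_valid=int(v.size),
    )


# ---------------------------------------------------------------------------
# full run


def _grid_spec_for(area: StudyArea, pixel: float) -> GridSpec:
    return GridSpec.from_bounds(area.polygon.bounds, pixel)


def run_pipeline(s: SampleSet, a: StudyArea, cfg: PipelineConfig) -> PipelineResult:
    """Execute the full per-treatment estimation and gain computation."""
    if cfg.target_crs is not None:
        s = reproject_samples(s, cfg.target_crs)
        a = reproject_area(a, cfg.target_crs)
    elif s.crs is not None and crs_mod.is_geographic(s.crs):
        raise ConfigurationError(
            "samples are in a geographic CRS; supply target_crs to reproject")

    labels = list(s.treatment_labels)
    n_t = cfg.n_treatments or len(labels)
    if n_t != len(labels):
        raise ConfigurationError(
            f"configured {n_t} treatments but data declares {len(labels)}")
    if cfg.reference_treatment not in labels:
        raise ConfigurationError(
            f"reference treatment {cfg.reference_treatment!r} not among {labels}")

    subsets = split_by_treatment(s)
    spec = _grid_spec_for(a, cfg.pixel)
    nb = cfg.neighborhood

    surfaces: dict[str, TreatmentSurfaces] = {}
    for label in labels:
        train, test = holdout_split(subsets[label], cfg.holdout_fraction, cfg.seed)
        if cfg.fixed_variogram is not None:
            vm = cfg.fixed_variogram
        else:
            ev = empirical_variogram(train.coords(), train.values,
                                     n_lags=cfg.n_lags,
                                     max_dist=cfg.variogram_max_dist)
            vm = fit_variogram(ev, cfg.model)
        base = krige_grid(train.coords(), train.values, vm, spec, nb, crs=s.crs)
        est_at_test = sample_raster_at_points(base, test.x, test.y)
        pair_mask = np.ma.getmaskarray(est_at_test)
        res = residuals(test.values, est_at_test)
        res_coords = test.coords()[~pair_mask]
        if cfg.fixed_variogram is None:
            res_vm = _fit_or_fallback(res_coords, res, vm.family, cfg.n_lags,
                                      cfg.variogram_max_dist, fallback=vm)
        else:
            res_vm = vm
        error, final = corrected_surface(base, res_coords, res, res_vm, nb,
                                         refit=False)
        final_clipped = clip_to_area(final, a)
        surfaces[label] = TreatmentSurfaces(
            label=label, base=base, error=error, final=final,
            final_clipped=final_clipped, train=train, test=test,
            base_variogram=vm, residual_variogram=res_vm)

    ref = cfg.reference_treatment
    pairs = ([(x, y) for x in labels for y in labels if x != y]
             if cfg.all_pairs else [(ref, lb) for lb in labels if lb != ref])
    gains, stats = {}, {}
    for pa, pb in pairs:
        key = f"{pa} - {pb}"
        gains[key] = gain_surface(surfaces[pa].final_clipped,
                                  surfaces[pb].final_clipped)
        stats[key] = raster_stats(gains[key])

    run_log = {
        "seed": cfg.seed,
        "pixel": cfg.pixel,
        "model": cfg.model,
        "reference_treatment": ref,
        "holdout_fraction": cfg.holdout_fraction,
        "crs": s.crs,
        "grid": {"origin_x": spec.origin_x, "origin_y": spec.origin_y,
                 "ncols": spec.ncols, "nrows": spec.nrows, "pixel": spec.pixel},
        "treatments": {
            lb: {
                "n_train": len(ts.train), "n_test": len(ts.test),
                "variogram": _vm_dict(ts.base_variogram),
                "residual_variogram": _vm_dict(ts.residual_variogram),
            } for lb, ts in surfaces.items()
        },
    }
    return PipelineResult(surfaces=surfaces, gains=gains, gain_stats=stats,
                          run_log=run_log)


def _vm_dict(vm: VariogramModel) -> dict:
    return {"family": vm.family, "nugget": vm.nugget,
            "partial_sill": vm.partial_sill, "range": vm.range_,
            "slope": vm.slope}


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write final surfaces, gain rasters, the HTML report and the run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, ts in result.surfaces.items():
        write_raster(ts.final_clipped, out / f"{label}_final.tif")
    for key, g in result.gains.items():
        a, b = [p.strip() for p in key.split("-")]
        write_raster(g, out / f"gain_{a}_vs_{b}.tif")
    meta = {
        "pixel size (m)": result.run_log["pixel"],
        "semivariogram model": result.run_log["model"],
        "reference treatment": result.run_log["reference_treatment"],
        "seed": result.run_log["seed"],
    }
    write_gain_report(result.gain_stats, meta, out / "statistics_of_gain.html")
    (out / "run_log.json").write_text(json.dumps(result.run_log, indent=2))
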