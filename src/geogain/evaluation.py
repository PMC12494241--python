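"""Holdout validation metrics for estimated surfaces.

Surfaces are judged against withheld field observations with two measures:

* RMSE% — root-mean-square error normalised by the observed mean,
  100 * sqrt(sum((y - yhat)^2)/n) / (sum(y)/n); scale-free, so comparable
  across crops and units.
* Pearson's r — linear association between observed and estimated values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EvaluationError
from .io_geodata import RasterGrid
from .pipeline import sample_raster_at_points


@dataclass(frozen=True)
class EvaluationResult:
    rmse_percent: float
    r: float
    n: int


def _paired(observed, estimated):
    observed = np.asarray(observed, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if observed.shape != estimated.shape:
        raise ConfigurationError("observed and estimated lengths differ")
    if observed.size == 0:
        raise EvaluationError("no observation/estimate pairs")
    return observed, estimated


def rmse_percent(observed, estimated) -> float:
    """Root-mean-square error as a percentage of the observed mean."""
    y, yhat = _paired(observed, estimated)
    mean_obs = y.mean()
    if mean_obs == 0:
        raise EvaluationError("observed mean is zero; RMSE%% undefined")
    return float(100.0 * np.sqrt(np.mean((y - yhat) ** 2)) / mean_obs)


def pearson_r(observed, estimated) -> float:
    """Pearson correlation between observed and estimated values."""
    y, yhat = _paired(observed, estimated)
    if y.size < 2:
        raise EvaluationError("Pearson r needs at least 2 pairs")
    dy = y - y.mean()
    dyh = yhat - yhat.mean()
    denom = np.sqrt(np.sum(dy**2) * np.sum(dyh**2))
    if denom == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    return float(np.sum(dy * dyh) / denom)


def evaluate_surface(g: RasterGrid, x, y, observed, *,
                     crs: int | None = None) -> EvaluationResult:
    """Sample the surface at held-out points and compute both metrics.

    Pairs where the surface is nodata (or the point is off-grid) are
    excluded; ``n`` reports the usable count.
    """
    observed = np.asarray(observed, dtype=float)
    est = sample_raster_at_points(g, x, y, crs=crs)
    usable = ~np.ma.getmaskarray(est)
    if usable.sum() < 2:
        raise EvaluationError(
            f"only {int(usable.sum())} evaluation point(s) fall on valid cells")
    y_obs = observed[usable]
    y_est = np.asarray(est.data)[usable]
    return EvaluationResult(rmse_percent=rmse_percent(y_obs, y_est),
                            r=pearson_r(y_obs, y_est), n=int(usable.sum()))
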