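"""Empirical semivariogram estimation and model fitting.

The semivariance gamma(h) summarises how dissimilar the field variable is at
two locations a distance h apart. The classical (Matheron) estimator bins
point pairs by separation distance; a parametric model from one of four
standard families (linear, exponential, Gaussian, spherical) is then fitted
by weighted least squares and handed to the kriging solver.

Model forms, with nugget c0, partial sill c, range a and slope b:

    linear        gamma(h) = c0 + b*h
    exponential   gamma(h) = c0 + c*(1 - exp(-3h/a))
    gaussian      gamma(h) = c0 + c*(1 - exp(-3h^2/a^2))
    spherical     gamma(h) = c0 + c*(1.5(h/a) - 0.5(h/a)^3), h <= a; c0 + c beyond

gamma(0) = 0 by convention in all families (the nugget is a discontinuity at
the origin). The exponential and Gaussian ranges are "effective": the -3h/a
scaling makes gamma reach ~95% of the sill at h = a, matching common
geostatistical software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, lsq_linear
from scipy.spatial.distance import pdist

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    FitFailureError,
    InsufficientStructureError,
)

FAMILIES = ("linear", "exponential", "gaussian", "spherical")

DEFAULT_N_LAGS = 100
DEFAULT_MAX_DIST = 1000.0


@dataclass
class EmpiricalVariogram:
    """Binned Matheron semivariance estimates; zero-pair bins already dropped."""

    lag_centers: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray
    max_dist: float

    def __post_init__(self):
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=float)
        if np.any(np.diff(self.lag_centers) <= 0) or np.any(self.lag_centers <= 0):
            raise ConfigurationError("lag centers must be positive and increasing")
        if np.any(self.gamma_hat < 0):
            raise ConfigurationError("semivariance estimates must be non-negative")


@dataclass(frozen=True)
class VariogramModel:
    """A fitted semivariogram model; only the declared family's parameters apply."""

    family: str
    nugget: float = 0.0
    partial_sill: float = 0.0
    range_: float = 1.0
    slope: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown variogram family {self.family!r}; choose from {FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.slope < 0:
            raise ConfigurationError("variogram variance parameters must be >= 0")
        if self.family != "linear" and self.range_ <= 0:
            raise ConfigurationError("variogram range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def model_gamma(m: VariogramModel, h) -> np.ndarray:
    """Evaluate the model semivariance at distance(s) h (gamma(0) = 0)."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ConfigurationError("separation distance h must be >= 0")
    scalar = h.ndim == 0
    h = np.atleast_1d(h)
    if m.family == "linear":
        g = m.nugget + m.slope * h
    elif m.family == "exponential":
        g = m.nugget + m.partial_sill * (1.0 - np.exp(-3.0 * h / m.range_))
    elif m.family == "gaussian":
        g = m.nugget + m.partial_sill * (1.0 - np.exp(-3.0 * h**2 / m.range_**2))
    else:  # spherical
        hr = np.minimum(h / m.range_, 1.0)
        g = m.nugget + m.partial_sill * (1.5 * hr - 0.5 * hr**3)
    g = np.where(h == 0.0, 0.0, g)
    return float(g[0]) if scalar else g


def empirical_variogram(coords: np.ndarray, values: np.ndarray, *,
                        n_lags: int = DEFAULT_N_LAGS,
                        max_dist: float = DEFAULT_MAX_DIST,
                        skip: int = 1) -> EmpiricalVariogram:
    """Classical Matheron estimator on equal-width lag bins over (0, max_dist].

    ``skip`` > 1 subsamples every skip-th point before pairing (for very
    dense harvester tracks); the default uses every point.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_lags < 3:
        raise ConfigurationError("need at least 3 lag bins")
    if max_dist <= 0:
        raise ConfigurationError("max_dist must be positive")
    if skip > 1:
        coords = coords[::skip]
        values = values[::skip]
    if len(coords) < 2:
        raise DegenerateGeometryError("need at least 2 points for a variogram")
    d = pdist(coords)
    if np.all(d <= 0):
        raise DegenerateGeometryError("all points are coincident")
    dv2 = pdist(values[:, None], metric="sqeuclidean")

    width = max_dist / n_lags
    # pairs at distance 0 or beyond max_dist are excluded; bins are
    # right-closed, ((k-1)*width, k*width]
    in_range = (d > 0) & (d <= max_dist)
    bin_idx = np.ceil(d[in_range] / width).astype(int) - 1
    counts = np.bincount(bin_idx, minlength=n_lags)
    sums = np.bincount(bin_idx, weights=dv2[in_range], minlength=n_lags)
    nonempty = counts > 0
    if not nonempty.any():
        raise InsufficientStructureError(
            "no point pair falls within max_dist; increase max_dist")
    centers = (np.arange(n_lags) + 0.5) * width
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    return EmpiricalVariogram(centers[nonempty], gamma, counts[nonempty], max_dist)


def _fit_linear(ev: EmpiricalVariogram) -> tuple[VariogramModel, float]:
    w = np.sqrt(ev.pair_counts)
    A = np.column_stack([np.ones_like(ev.lag_centers), ev.lag_centers]) * w[:, None]
    b = ev.gamma_hat * w
    res = lsq_linear(A, b, bounds=(0.0, np.inf))
    c0, slope = res.x
    cost = float(np.sum((A @ res.x - b) ** 2))
    return VariogramModel("linear", nugget=c0, slope=slope), cost


def fit_variogram(ev: EmpiricalVariogram, family: str = "linear") -> VariogramModel:
    """Weighted least-squares fit (weights = pair counts) with multistart.

    Five deterministic starts span the empirical sill and lag extent; box
    constraints keep nugget/sill non-negative and the range positive. The
    candidate with the lowest weighted residual wins.
    """
    if family not in FAMILIES:
        raise ConfigurationError(
            f"unknown variogram family {family!r}; choose from {FAMILIES}")
    if len(ev.lag_centers) < 3:
        raise InsufficientStructureError(
            "variogram fit requires at least 3 non-empty bins")
    if family == "linear":
        return _fit_linear(ev)[0]

    h = ev.lag_centers
    g = ev.gamma_hat
    w = np.sqrt(ev.pair_counts)
    sill0 = max(float(np.mean(g[-max(1, len(g) // 4):])), 1e-12)
    h_max = float(h[-1])

    def resid(p):
        m = VariogramModel(family, nugget=p[0], partial_sill=p[1], range_=p[2])
        return (model_gamma(m, h) - g) * w

    best = None
    for frac in (0.1, 0.25, 0.5, 0.75, 1.0):
        x0 = np.array([min(g[0], sill0 / 2), sill0, max(frac * h_max, 1e-6)])
        try:
            sol = least_squares(resid, x0, bounds=([0, 0, 1e-12], np.inf),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("variogram fit failed on all starts", empirical=ev)
    c0, c, a = best.x
    return VariogramModel(family, nugget=float(c0), partial_sill=float(c),
                          range_=float(a))
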