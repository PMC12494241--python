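"""Minimal coordinate-reference-system support.

The pipeline requires all geometry in a projected (metric) CRS before any
variogram or kriging step, because lag distances are Euclidean metres.
This module knows just enough to enforce that precondition and to move
harvester data between WGS84 geographic coordinates (EPSG:4326) and the
WGS84/UTM zones (EPSG:326xx north, 327xx south), which covers the formats
yield monitors export in practice.

The transverse Mercator projection is evaluated with the Krüger series in
the third flattening n, carried to order n^6 (Karney's formulation). At
this order the series is accurate to well under a millimetre anywhere
inside a UTM zone, so forward/inverse round trips close to ~1e-9 degrees.

CRS identifiers are bare EPSG integers throughout the package.
"""

from __future__ import annotations

import numpy as np

from .errors import CRSError

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563

_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_SOUTH = 10000000.0

#: EPSG codes this package treats as geographic (degrees).
GEOGRAPHIC_EPSG = frozenset({4326, 4269, 4258, 4674})


def is_geographic(epsg: int) -> bool:
    """True if the EPSG code denotes a geographic (degree-unit) CRS."""
    return int(epsg) in GEOGRAPHIC_EPSG


def is_projected(epsg: int) -> bool:
    return not is_geographic(epsg)


def utm_epsg(zone: int, north: bool) -> int:
    if not 1 <= zone <= 60:
        raise CRSError(f"UTM zone must be in 1..60, got {zone}")
    return (32600 if north else 32700) + zone


def _utm_zone_of(epsg: int) -> tuple[int, bool]:
    """Return (zone, is_north) for a WGS84/UTM EPSG code, else raise."""
    epsg = int(epsg)
    if 32601 <= epsg <= 32660:
        return epsg - 32600, True
    if 32701 <= epsg <= 32760:
        return epsg - 32700, False
    raise CRSError(
        f"EPSG:{epsg} is not a supported projected CRS "
        "(supported: WGS84/UTM zones EPSG:32601-32660 and 32701-32760)"
    )


def _kruger_coefficients():
    n = _F / (2.0 - _F)
    n2, n3, n4, n5, n6 = n**2, n**3, n**4, n**5, n**6
    # rectifying radius
    A = _A / (1 + n) * (1 + n2 / 4 + n4 / 64 + n6 / 256)
    alpha = np.array([
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180 - 127 * n5 / 288 + 7891 * n6 / 37800,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440 + 281 * n5 / 630 - 1983433 * n6 / 1935360,
        61 * n3 / 240 - 103 * n4 / 140 + 15061 * n5 / 26880 + 167603 * n6 / 181440,
        49561 * n4 / 161280 - 179 * n5 / 168 + 6601661 * n6 / 7257600,
        34729 * n5 / 80640 - 3418889 * n6 / 1995840,
        212378941 * n6 / 319334400,
    ])
    beta = np.array([
        n / 2 - 2 * n2 / 3 + 37 * n3 / 96 - n4 / 360 - 81 * n5 / 512 + 96199 * n6 / 604800,
        n2 / 48 + n3 / 15 - 437 * n4 / 1440 + 46 * n5 / 105 - 1118711 * n6 / 3870720,
        17 * n3 / 480 - 37 * n4 / 840 - 209 * n5 / 4480 + 5569 * n6 / 90720,
        4397 * n4 / 161280 - 11 * n5 / 504 - 830251 * n6 / 7257600,
        4583 * n5 / 161280 - 108847 * n6 / 3991680,
        20648693 * n6 / 638668800,
    ])
    delta = np.array([
        2 * n - 2 * n2 / 3 - 2 * n3 + 116 * n4 / 45 + 26 * n5 / 45 - 2854 * n6 / 675,
        7 * n2 / 3 - 8 * n3 / 5 - 227 * n4 / 45 + 2704 * n5 / 315 + 2323 * n6 / 945,
        56 * n3 / 15 - 136 * n4 / 35 - 1262 * n5 / 105 + 73814 * n6 / 2835,
        4279 * n4 / 630 - 332 * n5 / 35 - 399572 * n6 / 14175,
        4174 * n5 / 315 - 144838 * n6 / 6237,
        601676 * n6 / 22275,
    ])
    return n, A, alpha, beta, delta


_N, _RECT_A, _ALPHA, _BETA, _DELTA = _kruger_coefficients()
_J = np.arange(1, 7)[:, None]


def geographic_to_tm(lon, lat, lon0_deg: float):
    """Forward transverse Mercator (degrees -> metres, unscaled grid)."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    phi = np.radians(lat)
    lam = np.radians(lon - lon0_deg)

    e = np.sqrt(_F * (2 - _F))
    sphi = np.sin(phi)
    # conformal latitude
    t = np.sinh(np.arctanh(sphi) - e * np.arctanh(e * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    xi = xi_p + np.sum(_ALPHA[:, None] * np.sin(2 * _J * xi_p[None, :]) * np.cosh(2 * _J * eta_p[None, :]), axis=0)
    eta = eta_p + np.sum(_ALPHA[:, None] * np.cos(2 * _J * xi_p[None, :]) * np.sinh(2 * _J * eta_p[None, :]), axis=0)
    return _RECT_A * eta, _RECT_A * xi  # x (east), y (north)


def tm_to_geographic(x, y, lon0_deg: float):
    """Inverse transverse Mercator (metres on the unscaled grid -> degrees)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    xi = y / _RECT_A
    eta = x / _RECT_A

    xi_p = xi - np.sum(_BETA[:, None] * np.sin(2 * _J * xi[None, :]) * np.cosh(2 * _J * eta[None, :]), axis=0)
    eta_p = eta - np.sum(_BETA[:, None] * np.cos(2 * _J * xi[None, :]) * np.sinh(2 * _J * eta[None, :]), axis=0)

    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    phi = chi + np.sum(_DELTA[:, None] * np.sin(2 * _J * chi[None, :]), axis=0)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    return np.degrees(lam) + lon0_deg, np.degrees(phi)


def _lonlat_to_utm(lon, lat, zone: int, north: bool):
    lon0 = zone * 6.0 - 183.0
    x, y = geographic_to_tm(lon, lat, lon0)
    easting = _K0 * x + _FALSE_EASTING
    northing = _K0 * y + (0.0 if north else _FALSE_NORTHING_SOUTH)
    return easting, northing


def _utm_to_lonlat(easting, northing, zone: int, north: bool):
    lon0 = zone * 6.0 - 183.0
    x = (np.asarray(easting, dtype=float) - _FALSE_EASTING) / _K0
    y = (np.asarray(northing, dtype=float) - (0.0 if north else _FALSE_NORTHING_SOUTH)) / _K0
    return tm_to_geographic(x, y, lon0)


def transform(x, y, src_epsg: int, dst_epsg: int):
    """Transform coordinate arrays between supported CRSs.

    Supported: identity (any EPSG), WGS84 geographic (4326) <-> WGS84/UTM,
    and UTM <-> UTM (routed through geographic coordinates).
    """
    if src_epsg is None:
        raise CRSError("source CRS unknown; declare an explicit EPSG code")
    src, dst = int(src_epsg), int(dst_epsg)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if src == dst:
        return x.copy(), y.copy()
    if src == 4326:
        zone, north = _utm_zone_of(dst)
        return _lonlat_to_utm(x, y, zone, north)
    if dst == 4326:
        zone, north = _utm_zone_of(src)
        return _utm_to_lonlat(x, y, zone, north)
    if is_geographic(src) or is_geographic(dst):
        raise CRSError(
            f"transformation EPSG:{src} -> EPSG:{dst} not supported "
            "(only WGS84 geographic is handled on the geographic side)"
        )
    sz, sn = _utm_zone_of(src)
    dz, dn = _utm_zone_of(dst)
    lon, lat = _utm_to_lonlat(x, y, sz, sn)
    return _lonlat_to_utm(lon, lat, dz, dn)
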