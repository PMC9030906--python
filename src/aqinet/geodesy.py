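"""Geodesic distances between monitoring sites.

Distances enter the network weights as the denominator of the edge weight
(correlation / normalised distance), so they only need to be accurate to a
fraction of a percent. The default model is the WGS-84 ellipsoid, solved
with Vincenty's inverse formula; a spherical haversine model is available
as a faster alternative and as the fallback for the rare near-antipodal
pairs on which Vincenty's iteration fails to converge.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["geodesic_distance_km", "pairwise_distance_km", "EARTH_RADIUS_KM"]

# WGS-84 ellipsoid
_WGS84_A = 6378137.0          # semi-major axis, metres
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)

#: Mean Earth radius (IUGG), kilometres — used by the spherical model.
EARTH_RADIUS_KM = 6371.0088

_VINCENTY_TOL = 1e-12
_VINCENTY_MAXITER = 200


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _vincenty_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Vincenty inverse solution on WGS-84; raises RuntimeError on non-convergence."""
    if lat1 == lat2 and (lon1 - lon2) % 360.0 == 0.0:
        return 0.0
    u1 = math.atan((1.0 - _WGS84_F) * math.tan(math.radians(lat1)))
    u2 = math.atan((1.0 - _WGS84_F) * math.tan(math.radians(lat2)))
    ell = math.radians(lon2 - lon1)
    sin_u1, cos_u1 = math.sin(u1), math.cos(u1)
    sin_u2, cos_u2 = math.sin(u2), math.cos(u2)

    lam = ell
    for _ in range(_VINCENTY_MAXITER):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cos_u2 * sin_lam, cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident points
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0.0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sin_u1 * sin_u2 / cos2_alpha
        c = _WGS84_F / 16.0 * cos2_alpha * (4.0 + _WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = ell + (1.0 - c) * _WGS84_F * sin_alpha * (
            sigma
            + c
            * sin_sigma
            * (cos_2sigma_m + c * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < _VINCENTY_TOL:
            break
    else:
        raise RuntimeError("Vincenty iteration failed to converge")

    u_sq = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    big_a = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    big_b = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        big_b
        * sin_sigma
        * (
            cos_2sigma_m
            + big_b
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - big_b
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    return _WGS84_B * big_a * (sigma - delta_sigma) / 1000.0


def geodesic_distance_km(
    lat1: float,
    lon1: float,
    lat2: float,
    lon2: float,
    model: str = "ellipsoid",
) -> float:
    """Distance in kilometres between two (latitude, longitude) points.

    Parameters
    ----------
    model
        ``"ellipsoid"`` (WGS-84 Vincenty inverse, default) or ``"sphere"``
        (haversine on the mean Earth radius). Near-antipodal pairs on which
        the ellipsoidal iteration does not converge fall back to the
        spherical value with a warning.
    """
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    if model == "sphere":
        return _haversine_km(lat1, lon1, lat2, lon2)
    if model != "ellipsoid":
        raise ValueError(f"unknown distance model {model!r}")
    try:
        return _vincenty_km(lat1, lon1, lat2, lon2)
    except RuntimeError:
        warnings.warn(
            "ellipsoidal distance did not converge (near-antipodal pair); "
            "using spherical value",
            RuntimeWarning,
            stacklevel=2,
        )
        return _haversine_km(lat1, lon1, lat2, lon2)


def pairwise_distance_km(
    latitudes: np.ndarray, longitudes: np.ndarray, model: str = "ellipsoid"
) -> np.ndarray:
    """Symmetric matrix of pairwise distances (km) with a zero diagonal."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    n = lat.shape[0]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_distance_km(lat[i], lon[i], lat[j], lon[j], model=model)
            out[i, j] = out[j, i] = d
    return out
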