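"""Spherical geodesy primitives used throughout the pipeline.

All distances are great-circle (haversine) on a sphere of mean radius
6371.0088 km; bearings are spherical forward azimuths. At the foraging
ranges of colonial seabirds (tens of km) these differ from ellipsoidal
geodesics by well under 0.5%.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lat_a, lon_a, lat_b, lon_b):
    """Full (n, m) distance matrix between two sets of points, in km."""
    lat_a = np.asarray(lat_a, dtype=float)[:, None]
    lon_a = np.asarray(lon_a, dtype=float)[:, None]
    lat_b = np.asarray(lat_b, dtype=float)[None, :]
    lon_b = np.asarray(lon_b, dtype=float)[None, :]
    return haversine_km(lat_a, lon_a, lat_b, lon_b)


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Forward azimuth from point 1 to point 2, radians in (-pi, pi].

    0 is true north, pi/2 due east (standard navigational convention,
    wrapped to a signed half-open interval).
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    theta = np.arctan2(y, x)
    # arctan2 yields [-pi, pi]; fold -pi onto +pi for the half-open interval
    return np.where(theta == -np.pi, np.pi, theta) if np.ndim(theta) else (
        np.pi if theta == -np.pi else float(theta)
    )


def destination_point(lat, lon, bearing_rad, distance_km):
    """Point reached travelling `distance_km` on initial bearing from (lat, lon)."""
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.asarray(bearing_rad, dtype=float)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lam2 = (lam2 + np.pi) % (2.0 * np.pi) - np.pi
    return np.degrees(phi2), np.degrees(lam2)


def circular_difference_rad(a, b):
    """Minimal absolute angular difference between two bearings, in [0, pi]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % (2.0 * np.pi)
    return np.where(d > np.pi, 2.0 * np.pi - d, d) if np.ndim(d) else (
        float(2.0 * np.pi - d) if d > np.pi else float(d)
    )
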