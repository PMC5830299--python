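"""Spherical-earth geodesy helpers.

All distances are great-circle on a sphere of radius ``EARTH_RADIUS_KM``;
bearings are initial forward azimuths in degrees clockwise from true north.
Error versus an ellipsoid is well under 0.5% at subpolar latitudes, which is
negligible relative to Argos location error.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "initial_bearing_deg",
    "destination_point",
    "unit_vectors",
    "chord_to_arc_km",
]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial forward azimuth in [0, 360) degrees from point 1 to point 2.

    Coincident points map to 0 by convention.
    """
    lon1r, lat1r, lon2r, lat2r = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2r - lon1r
    y = np.sin(dlon) * np.cos(lat2r)
    x = np.cos(lat1r) * np.sin(lat2r) - np.sin(lat1r) * np.cos(lat2r) * np.cos(dlon)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    same = (np.asarray(lon1, dtype=float) == np.asarray(lon2, dtype=float)) & (
        np.asarray(lat1, dtype=float) == np.asarray(lat2, dtype=float)
    )
    return np.where(same, 0.0, brg) if np.ndim(brg) else (0.0 if same else float(brg))


def destination_point(lon, lat, bearing_deg, distance_km):
    """Destination after travelling ``distance_km`` along ``bearing_deg``.

    Returns (lon, lat) in degrees, longitude normalized to (-180, 180].
    """
    lonr = np.radians(np.asarray(lon, dtype=float))
    latr = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(latr) * np.cos(delta) + np.cos(latr) * np.sin(delta) * np.cos(brg))
    lon2 = lonr + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(latr),
        np.cos(delta) - np.sin(latr) * np.sin(lat2),
    )
    lon2d = np.degrees(lon2)
    lon2d = ((lon2d + 180.0) % 360.0) - 180.0
    lon2d = np.where(lon2d == -180.0, 180.0, lon2d) if np.ndim(lon2d) else (180.0 if lon2d == -180.0 else lon2d)
    return lon2d, np.degrees(lat2)


def unit_vectors(lon, lat):
    """(n, 3) unit vectors on the sphere for degree coordinates."""
    lonr = np.radians(np.atleast_1d(np.asarray(lon, dtype=float)))
    latr = np.radians(np.atleast_1d(np.asarray(lat, dtype=float)))
    return np.column_stack(
        (np.cos(latr) * np.cos(lonr), np.cos(latr) * np.sin(lonr), np.sin(latr))
    )


def chord_to_arc_km(chord: np.ndarray) -> np.ndarray:
    """Convert unit-sphere chord lengths to great-circle distances in km.

    The mapping is monotone, so nearest-neighbour queries on 3-D unit vectors
    (e.g. a KD-tree) return the exact great-circle nearest point.
    """
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.clip(np.asarray(chord) / 2.0, 0.0, 1.0))
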