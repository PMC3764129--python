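"""Spherical-earth geometry helpers shared across the package."""

from __future__ import annotations

import numpy as np

#: Mean earth radius (km); 1 degree of latitude = 111.195 km.
EARTH_RADIUS_KM = 6371.0

#: Kilometres per degree of latitude (and of longitude at the equator).
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def wrap_lon(lon):
    """Wrap longitudes into [0, 360) degrees east."""
    return np.asarray(lon, dtype=float) % 360.0


def unwrap_lon(lon):
    """Remove 360-degree jumps from a longitude sequence.

    Needed before smoothing or interpolating tracks that cross the
    antimeridian; invert with :func:`wrap_lon`.
    """
    lon = np.asarray(lon, dtype=float)
    return np.degrees(np.unwrap(np.radians(lon)))


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def local_metric_km(lat):
    """(km per degree lon, km per degree lat) at the given latitude."""
    lat = np.asarray(lat, dtype=float)
    return KM_PER_DEG * np.cos(np.radians(lat)), np.full_like(lat, KM_PER_DEG)
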