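"""Small geographic helpers (great-circle distance, local km projection)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def to_local_km(lon, lat, lon0: float, lat0: float):
    """Equirectangular projection to km around a reference point.

    Adequate for simulating smooth fields at the continental scale used
    here; distances that matter for analysis use :func:`haversine_km`.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    kx = np.pi / 180.0 * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    ky = np.pi / 180.0 * EARTH_RADIUS_KM
    return (lon - lon0) * kx, (lat - lat0) * ky
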