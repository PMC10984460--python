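"""Planar coordinate helper.

All model quantities (Matern range, centre of gravity, cell areas) are
metric, so the package works throughout in planar kilometres.  Longitude /
latitude are carried for I/O only and converted through a single local
equirectangular projection about a reference point, which is accurate to
well under 1% over the few-hundred-km domains this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class LocalProjection:
    """Local equirectangular lon/lat <-> planar-km transform.

    Parameters
    ----------
    lon0, lat0 : float
        Reference point (decimal degrees) mapped to (0, 0) km.
    """

    lon0: float
    lat0: float

    def to_xy(self, lon, lat):
        """Project decimal-degree coordinates to planar km (x east, y north)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        coslat = np.cos(np.deg2rad(self.lat0))
        x = np.deg2rad(lon - self.lon0) * coslat * EARTH_RADIUS_KM
        y = np.deg2rad(lat - self.lat0) * EARTH_RADIUS_KM
        return x, y

    def to_lonlat(self, x, y):
        """Inverse of :meth:`to_xy`."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coslat = np.cos(np.deg2rad(self.lat0))
        lon = self.lon0 + np.rad2deg(x / (EARTH_RADIUS_KM * coslat))
        lat = self.lat0 + np.rad2deg(y / EARTH_RADIUS_KM)
        return lon, lat
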