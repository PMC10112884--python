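"""Local map projection for GPS tracks.

Tracks span a few kilometres, so a spherical transverse-Mercator projection
centred on the track centroid is ample (sub-metre error at these extents).
Formulas follow the standard spherical TM equations; WGS84 mean radius.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


def project(lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float) -> tuple[np.ndarray, np.ndarray]:
    """Project WGS84 degrees to local transverse-Mercator metres.

    ``x`` is east of the central meridian ``lon0``, ``y`` north of ``lat0``.
    """
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(lon0)
    phi0 = np.radians(lat0)
    b = np.cos(phi) * np.sin(lam)
    # guard |b| -> 1 (point 90 deg of longitude away; never happens for tracks)
    b = np.clip(b, -1 + 1e-12, 1 - 1e-12)
    x = 0.5 * EARTH_RADIUS_M * np.log((1 + b) / (1 - b))
    y = EARTH_RADIUS_M * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
    return x, y


def unproject(x: np.ndarray, y: np.ndarray, lat0: float, lon0: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project`."""
    xs = np.asarray(x, dtype=float) / EARTH_RADIUS_M
    d = np.asarray(y, dtype=float) / EARTH_RADIUS_M + np.radians(lat0)
    phi = np.arcsin(np.sin(d) / np.cosh(xs))
    lam = np.arctan2(np.sinh(xs), np.cos(d))
    return np.degrees(phi), np.degrees(lam) + lon0
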