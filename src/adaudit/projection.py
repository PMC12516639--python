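"""Metre-true planar projection for boundary buffering.

Buffer distances (5/10/20 m around neighbourhood boundaries) must be
computed in a projected coordinate system: degree-space distances are
anisotropic at British latitudes. This module implements an ellipsoidal
transverse Mercator forward/inverse pair. The default parameter set is the
British National Grid (the projection underlying EPSG:27700: central
meridian 2°W, scale 0.9996012717, false origin 400000/-100000), applied
directly to WGS84 longitude/latitude on the GRS80 ellipsoid.

No datum transformation is applied. That costs ~100 m of absolute position
against true OSGB36 grid references, but buffering only ever compares
relative distances between points projected the same way, for which the
scale error at city extent is far below 0.1 %. A local transverse Mercator
centred on the data (``local_tm_for``) is available for data far from
Britain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.ops import transform as shapely_transform

__all__ = ["TransverseMercator", "BNG", "local_tm_for", "to_metric", "to_lonlat"]


@dataclass(frozen=True)
class TransverseMercator:
    """Ellipsoidal transverse Mercator (Redfearn series, ~mm accurate)."""

    lon0_deg: float = -2.0
    lat0_deg: float = 49.0
    k0: float = 0.9996012717
    false_easting: float = 400_000.0
    false_northing: float = -100_000.0
    a: float = 6378137.0  # GRS80 semi-major axis, metres
    f: float = 1 / 298.257222101

    @property
    def _e2(self) -> float:
        return self.f * (2 - self.f)

    def _meridian_arc(self, phi: float) -> float:
        """Meridian arc length from lat0 to phi (metres)."""
        a, f = self.a, self.f
        b = a * (1 - f)
        n = (a - b) / (a + b)
        phi0 = math.radians(self.lat0_deg)
        n2, n3 = n * n, n * n * n
        dphi, sphi = phi - phi0, phi + phi0
        m = (
            (1 + n + 1.25 * n2 + 1.25 * n3) * dphi
            - (3 * n + 3 * n2 + 2.625 * n3) * math.sin(dphi) * math.cos(sphi)
            + (1.875 * n2 + 1.875 * n3) * math.sin(2 * dphi) * math.cos(2 * sphi)
            - (35 / 24) * n3 * math.sin(3 * dphi) * math.cos(3 * sphi)
        )
        return b * self.k0 * m

    def forward(self, lon_deg: float, lat_deg: float) -> tuple[float, float]:
        """WGS84 lon/lat (degrees) -> easting/northing (metres)."""
        phi = math.radians(lat_deg)
        lam = math.radians(lon_deg - self.lon0_deg)
        a, k0, e2 = self.a, self.k0, self._e2
        sphi, cphi = math.sin(phi), math.cos(phi)
        nu = a * k0 / math.sqrt(1 - e2 * sphi**2)
        rho = a * k0 * (1 - e2) / (1 - e2 * sphi**2) ** 1.5
        eta2 = nu / rho - 1
        M = self._meridian_arc(phi)
        t = math.tan(phi)
        I = M + self.false_northing
        II = nu / 2 * sphi * cphi
        III = nu / 24 * sphi * cphi**3 * (5 - t**2 + 9 * eta2)
        IIIA = nu / 720 * sphi * cphi**5 * (61 - 58 * t**2 + t**4)
        IV = nu * cphi
        V = nu / 6 * cphi**3 * (nu / rho - t**2)
        VI = nu / 120 * cphi**5 * (5 - 18 * t**2 + t**4 + 14 * eta2 - 58 * t**2 * eta2)
        northing = I + II * lam**2 + III * lam**4 + IIIA * lam**6
        easting = self.false_easting + IV * lam + V * lam**3 + VI * lam**5
        return easting, northing

    def inverse(self, easting: float, northing: float) -> tuple[float, float]:
        """Easting/northing (metres) -> WGS84 lon/lat (degrees)."""
        a, k0, e2 = self.a, self.k0, self._e2
        phi = math.radians(self.lat0_deg) + (northing - self.false_northing) / (a * k0)
        # iterate the footpoint latitude
        for _ in range(20):
            M = self._meridian_arc(phi)
            delta = northing - self.false_northing - M
            if abs(delta) < 1e-10:
                break
            phi += delta / (a * k0)
        sphi, cphi = math.sin(phi), math.cos(phi)
        nu = a * k0 / math.sqrt(1 - e2 * sphi**2)
        rho = a * k0 * (1 - e2) / (1 - e2 * sphi**2) ** 1.5
        eta2 = nu / rho - 1
        t = math.tan(phi)
        sec = 1 / cphi
        de = easting - self.false_easting
        VII = t / (2 * rho * nu)
        VIII = t / (24 * rho * nu**3) * (5 + 3 * t**2 + eta2 - 9 * t**2 * eta2)
        IX = t / (720 * rho * nu**5) * (61 + 90 * t**2 + 45 * t**4)
        X = sec / nu
        XI = sec / (6 * nu**3) * (nu / rho + 2 * t**2)
        XII = sec / (120 * nu**5) * (5 + 28 * t**2 + 24 * t**4)
        XIIA = sec / (5040 * nu**7) * (61 + 662 * t**2 + 1320 * t**4 + 720 * t**6)
        lat = phi - VII * de**2 + VIII * de**4 - IX * de**6
        lam = X * de - XI * de**3 + XII * de**5 - XIIA * de**7
        return self.lon0_deg + math.degrees(lam), math.degrees(lat)


#: British National Grid projection parameters (EPSG:27700 family).
BNG = TransverseMercator()


def local_tm_for(lon_deg: float, lat_deg: float) -> TransverseMercator:
    """A transverse Mercator centred on the data, for non-British extents."""
    return TransverseMercator(
        lon0_deg=lon_deg, lat0_deg=lat_deg, k0=1.0, false_easting=0.0, false_northing=0.0
    )


def to_metric(geom, tm: TransverseMercator = BNG):
    """Project a shapely geometry from lon/lat into metres."""

    def _fwd(xs, ys):
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        pts = [tm.forward(x, y) for x, y in zip(xs, ys)]
        return np.array([p[0] for p in pts]), np.array([p[1] for p in pts])

    return shapely_transform(_fwd, geom)


def to_lonlat(geom, tm: TransverseMercator = BNG):
    """Project a shapely geometry from metres back to lon/lat."""

    def _inv(xs, ys):
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        pts = [tm.inverse(x, y) for x, y in zip(xs, ys)]
        return np.array([p[0] for p in pts]), np.array([p[1] for p in pts])

    return shapely_transform(_inv, geom)
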