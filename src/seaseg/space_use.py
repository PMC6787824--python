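"""Kernel space use: utilization distributions, contours, centroids, overlap.

Positions are projected with a spherical Lambert azimuthal equal-area (LAEA)
projection centred on the data centroid, so that a fixed kernel bandwidth in
kilometres and contour areas in km^2 are exact.  The utilization distribution
is a fixed-bandwidth Gaussian product kernel evaluated on a regular grid
(histogram + Gaussian filter; the 25-km cell is ~bandwidth/7, so the
discretisation error is negligible next to the geolocation error budget).

The 50% density contour is the conventional "core area", the 95% contour the
"general use" area; overlap between two birds/groups is the home-range (HR)
proportion method: area of the intersection over each home range's own area.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

EARTH_RADIUS_KM = 6371.0

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances & projection


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine great-circle distance in km on the R=6371 km sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def laea_project(lon, lat, lon0: float, lat0: float) -> Tuple[np.ndarray, np.ndarray]:
    """Forward spherical Lambert azimuthal equal-area projection (km)."""
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = np.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def laea_inverse(x, y, lon0: float, lat0: float) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse spherical LAEA: projected km back to lon/lat degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    rho = np.sqrt(x * x + y * y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
    phi0 = np.radians(lat0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            rho > 1e-12,
            np.arcsin(np.clip(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / np.maximum(rho, 1e-12), -1, 1)),
            phi0,
        )
        lam = np.where(
            rho > 1e-12,
            np.arctan2(x * np.sin(c), rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)),
            0.0,
        )
    lon = (np.degrees(lam) + lon0 + 180.0) % 360.0 - 180.0
    return lon, np.degrees(phi)


def recenter_lons(lon: np.ndarray) -> Tuple[np.ndarray, float]:
    """Shift longitudes so an antimeridian-crossing cloud becomes contiguous.

    Returns the shifted longitudes and the circular-mean reference longitude.
    """
    lon = np.asarray(lon, dtype=float)
    ang = np.radians(lon)
    ref = np.degrees(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))))
    shifted = (lon - ref + 180.0) % 360.0 - 180.0 + ref
    return shifted, ref


# ---------------------------------------------------------------------------
# kernel utilization distribution


@dataclass
class KernelEstimate:
    """A kernel utilization distribution on a projected equal-area grid."""

    lon0: float
    lat0: float
    cell_km: float
    bandwidth_km: float
    x: np.ndarray          # cell-centre x coordinates (km), shape (nx,)
    y: np.ndarray          # cell-centre y coordinates (km), shape (ny,)
    density: np.ndarray    # shape (ny, nx); sum * cell_km^2 == 1
    pos_lon: np.ndarray
    pos_lat: np.ndarray
    levels: Dict[int, float] = field(default_factory=dict)

    def level_threshold(self, level: int) -> float:
        """Density threshold whose super-level set holds ``level``% of mass."""
        if level not in self.levels:
            cell_area = self.cell_km ** 2
            d = np.sort(self.density.ravel())[::-1]
            mass = np.cumsum(d) * cell_area
            k = int(np.searchsorted(mass, level / 100.0))
            k = min(k, len(d) - 1)
            self.levels[level] = float(d[k])
        return self.levels[level]

    def contour_mask(self, level: int) -> np.ndarray:
        return self.density >= self.level_threshold(level)

    def contour_area_km2(self, level: int) -> float:
        return float(self.contour_mask(level).sum() * self.cell_km ** 2)


class InsufficientPositionsError(ValueError):
    pass


def kernel_ud(
    lon: Sequence[float],
    lat: Sequence[float],
    bandwidth_km: float = 186.0,
    cell_km: float = 25.0,
    center: Optional[Tuple[float, float]] = None,
) -> KernelEstimate:
    """Fixed-bandwidth Gaussian kernel UD of a lon/lat point set.

    The grid extent is the projected bounding box padded by 3x the bandwidth;
    the density is normalised to integrate to one over the grid.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    ok = np.isfinite(lon) & np.isfinite(lat)
    lon, lat = lon[ok], lat[ok]
    if len(lon) < 5:
        raise InsufficientPositionsError(f"kernel needs >= 5 positions, got {len(lon)}")
    lon_shift, _ = recenter_lons(lon)
    if center is None:
        lon0 = float(np.mean(lon_shift))
        lat0 = float(np.mean(lat))
    else:
        lon0, lat0 = center
    px, py = laea_project(lon_shift, lat, lon0, lat0)
    pad = 3.0 * bandwidth_km
    x0, x1 = px.min() - pad, px.max() + pad
    y0, y1 = py.min() - pad, py.max() + pad
    nx = max(int(np.ceil((x1 - x0) / cell_km)), 8)
    ny = max(int(np.ceil((y1 - y0) / cell_km)), 8)
    xe = x0 + np.arange(nx + 1) * cell_km
    ye = y0 + np.arange(ny + 1) * cell_km
    hist, _, _ = np.histogram2d(py, px, bins=[ye, xe])
    sigma_cells = bandwidth_km / cell_km
    dens = ndimage.gaussian_filter(hist, sigma=sigma_cells, mode="constant", truncate=6.0)
    dens /= dens.sum() * cell_km ** 2
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    return KernelEstimate(lon0, lat0, cell_km, bandwidth_km, xc, yc, dens, lon, lat)


def summarize_ud(kernel: KernelEstimate):
    """Areas, centroid and per-polygon day counts of a kernel UD.

    The centroid is the geometric centroid of the 50% polygon holding the most
    positions (days); when the 50% contour splits into several polygons the
    day counts of all of them are returned.
    Returns ``(area50_km2, area95_km2, (centroid_lon, centroid_lat), day_counts)``.
    """
    mask50 = kernel.contour_mask(50)
    area50 = kernel.contour_area_km2(50)
    area95 = kernel.contour_area_km2(95)
    labels, n_poly = ndimage.label(mask50)
    lon_shift, _ = recenter_lons(kernel.pos_lon)
    px, py = laea_project(lon_shift, kernel.pos_lat, kernel.lon0, kernel.lat0)
    ix = np.clip(((px - kernel.x[0]) / kernel.cell_km + 0.5).astype(int), 0, len(kernel.x) - 1)
    iy = np.clip(((py - kernel.y[0]) / kernel.cell_km + 0.5).astype(int), 0, len(kernel.y) - 1)
    pos_labels = labels[iy, ix]
    counts = {int(k): int((pos_labels == k).sum()) for k in range(1, n_poly + 1)}
    if counts and max(counts.values()) > 0:
        best = max(counts, key=counts.get)
    else:  # no position falls in a labelled cell: take the largest polygon
        sizes = {k: int((labels == k).sum()) for k in range(1, n_poly + 1)}
        best = max(sizes, key=sizes.get)
    sel = labels == best
    yy, xx = np.nonzero(sel)
    cx = float(np.mean(kernel.x[xx]))
    cy = float(np.mean(kernel.y[yy]))
    clon, clat = laea_inverse(cx, cy, kernel.lon0, kernel.lat0)
    return area50, area95, (float(clon), float(clat)), counts


@dataclass(frozen=True)
class OverlapResult:
    level: int
    overlap_ab: float
    overlap_ba: float


def hr_overlap(kernelA: KernelEstimate, kernelB: KernelEstimate, level: int = 50) -> OverlapResult:
    """Home-range-proportion overlap of two kernel UDs at a contour level.

    Both point sets are re-evaluated on one shared projection/grid so the
    contour masks align cell-for-cell.
    """
    lon = np.concatenate([kernelA.pos_lon, kernelB.pos_lon])
    lat = np.concatenate([kernelA.pos_lat, kernelB.pos_lat])
    lon_shift, _ = recenter_lons(lon)
    lon0 = float(np.mean(lon_shift))
    lat0 = float(np.mean(lat))
    cell = min(kernelA.cell_km, kernelB.cell_km)
    ka = kernel_ud(kernelA.pos_lon, kernelA.pos_lat, kernelA.bandwidth_km, cell, center=(lon0, lat0))
    kb = kernel_ud(kernelB.pos_lon, kernelB.pos_lat, kernelB.bandwidth_km, cell, center=(lon0, lat0))
    # align the two grids on the union extent
    x0 = min(ka.x[0], kb.x[0])
    y0 = min(ka.y[0], kb.y[0])
    x1 = max(ka.x[-1], kb.x[-1])
    y1 = max(ka.y[-1], kb.y[-1])
    nx = int(round((x1 - x0) / cell)) + 1
    ny = int(round((y1 - y0) / cell)) + 1

    def embed(k: KernelEstimate) -> np.ndarray:
        m = np.zeros((ny, nx), dtype=bool)
        ox = int(round((k.x[0] - x0) / cell))
        oy = int(round((k.y[0] - y0) / cell))
        m[oy:oy + len(k.y), ox:ox + len(k.x)] = k.contour_mask(level)
        return m

    ma, mb = embed(ka), embed(kb)
    inter = float((ma & mb).sum())
    a = float(ma.sum())
    b = float(mb.sum())
    return OverlapResult(level, inter / a if a else 0.0, inter / b if b else 0.0)


# ---------------------------------------------------------------------------
# nonbreeding-area catalog


class EmptyCatalogError(ValueError):
    pass


def load_area_catalog(path=None) -> List[Tuple[str, "object"]]:
    """Named nonbreeding-area polygons from GeoJSON (ordered as in the file).

    Without a path, the bundled schematic Atlantic catalog is used.
    """
    from shapely.geometry import shape

    if path is None:
        from importlib import resources

        source = resources.files("seaseg").joinpath("data/areas.geojson")
        gj = json.loads(source.read_text())
    else:
        with open(path) as fh:
            gj = json.load(fh)
    return [(f["properties"]["name"], shape(f["geometry"])) for f in gj["features"]]


def assign_area(centroid_lonlat: Tuple[float, float], catalog=None) -> str:
    """Label of the catalog polygon containing the centroid.

    Falls back (with a warning) to the nearest polygon when the centroid lies
    in a gap; boundary ties break by catalog order.
    """
    from shapely.geometry import Point

    if catalog is None:
        catalog = load_area_catalog()
    if not catalog:
        raise EmptyCatalogError("area catalog is empty")
    pt = Point(*centroid_lonlat)
    for name, poly in catalog:
        if poly.covers(pt):
            return name
    dists = [(poly.distance(pt), name) for name, poly in catalog]
    d, name = min(dists)
    warnings.warn(
        f"centroid {centroid_lonlat} outside every catalog polygon; "
        f"nearest is {name!r} ({d:.2f} deg away)",
        stacklevel=2,
    )
    return name


def contour_geojson(kernel: KernelEstimate, levels=(50, 95)) -> dict:
    """Contour polygons of a kernel UD as a GeoJSON FeatureCollection."""
    from skimage import measure

    features = []
    for level in levels:
        thr = kernel.level_threshold(level)
        for ring in measure.find_contours(kernel.density, thr):
            gx = kernel.x[0] + ring[:, 1] * kernel.cell_km
            gy = kernel.y[0] + ring[:, 0] * kernel.cell_km
            lon, lat = laea_inverse(gx, gy, kernel.lon0, kernel.lat0)
            coords = [[float(a), float(b)] for a, b in zip(lon, lat)]
            if coords[0] != coords[-1]:
                coords.append(coords[0])
            features.append(
                {
                    "type": "Feature",
                    "properties": {"level": int(level)},
                    "geometry": {"type": "Polygon", "coordinates": [coords]},
                }
            )
    return {"type": "FeatureCollection", "features": features}
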