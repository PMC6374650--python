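"""Per-species spatial rarity indices.

Three indices are computed from a species' occurrence points:

* ``d_max_km`` — the largest distance between any pair of points, a proxy
  for geographic range size;
* ``d_min_km`` — the mean, over points, of each point's distance to its
  nearest conspecific point;
* ``abundance`` — the ratio ``d_max_km / d_min_km``, a proxy for local
  abundance (tightly packed points give small d_min and a large ratio).

Habitat specificity is the count of distinct landcover classes the points
fall in, and a convex-hull range area is kept as a sensitivity alternative
to ``d_max_km``.

Exact coordinate duplicates are collapsed before any distance computation,
which guarantees d_min > 0 and keeps the abundance ratio finite.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .occurrence_io import LandcoverGrid, OccurrenceDataset, _check_coord_mode

logger = logging.getLogger("rarityframe")

#: Mean Earth radius (IUGG) used for great-circle distances.
EARTH_RADIUS_KM = 6371.0088

METRIC_COLUMNS = [
    "species_id", "n_obs", "n_unique_points",
    "d_max_km", "d_min_km", "abundance", "habitat_count", "hull_area_km2",
]


def pairwise_distance(p, q, coord_mode: str) -> float:
    """Distance in km between two points.

    lonlat mode uses the haversine great-circle formula on a sphere of
    radius :data:`EARTH_RADIUS_KM`; planar_km mode is Euclidean.
    """
    _check_coord_mode(coord_mode)
    px, py = float(p[0]), float(p[1])
    qx, qy = float(q[0]), float(q[1])
    if not all(math.isfinite(v) for v in (px, py, qx, qy)):
        raise ValueError("coordinates must be finite")
    if coord_mode == "planar_km":
        return math.hypot(px - qx, py - qy)
    lam1, phi1, lam2, phi2 = map(math.radians, (px, py, qx, qy))
    a = (
        math.sin((phi2 - phi1) / 2.0) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def unique_points(points) -> np.ndarray:
    """Collapse exact coordinate duplicates; returns an (m, 2) array."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return np.unique(pts, axis=0)


def distance_matrix(points, coord_mode: str) -> np.ndarray:
    """Full symmetric pairwise distance matrix in km."""
    _check_coord_mode(coord_mode)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if coord_mode == "planar_km":
        diff = pts[:, None, :] - pts[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])
    lam = np.radians(pts[:, 0])
    phi = np.radians(pts[:, 1])
    sin_dphi = np.sin((phi[None, :] - phi[:, None]) / 2.0)
    sin_dlam = np.sin((lam[None, :] - lam[:, None]) / 2.0)
    a = sin_dphi**2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * sin_dlam**2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def _require_nondegenerate(pts: np.ndarray) -> None:
    if len(pts) < 2:
        raise ValueError("degenerate species: fewer than 2 unique occurrence points")


def compute_dmax(points, coord_mode: str) -> float:
    """Largest distance (km) between any pair of unique occurrence points."""
    pts = unique_points(points)
    _require_nondegenerate(pts)
    return float(distance_matrix(pts, coord_mode).max())


def compute_dmin(points, coord_mode: str) -> float:
    """Mean over unique points of the distance to the nearest other point (km)."""
    pts = unique_points(points)
    _require_nondegenerate(pts)
    dm = distance_matrix(pts, coord_mode)
    np.fill_diagonal(dm, np.inf)
    return float(dm.min(axis=1).mean())


def local_abundance_ratio(d_max_km: float, d_min_km: float) -> float:
    """d_max / d_min; >= 1 by construction once duplicates are collapsed."""
    if d_min_km <= 0:
        raise AssertionError(
            "d_min must be positive after duplicate collapsing; "
            f"got d_min={d_min_km}, d_max={d_max_km}"
        )
    return float(d_max_km) / float(d_min_km)


def habitat_specificity(points, landcover: LandcoverGrid) -> int:
    """Number of distinct non-nodata landcover classes containing the points.

    Points falling off-grid or on nodata cells are excluded (warned about);
    if no point carries habitat information an error is raised.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    codes: set[int] = set()
    n_excluded = 0
    for x, y in pts:
        code = landcover.class_at(x, y)
        if code is None:
            n_excluded += 1
        else:
            codes.add(code)
    if n_excluded:
        logger.warning(
            "habitat_specificity: %d of %d point(s) off-grid or on nodata", n_excluded, len(pts)
        )
    if not codes:
        raise ValueError("no habitat information: all points off-grid or on nodata")
    return len(codes)


def project_azimuthal_equal_area(points, lon0: float, lat0: float) -> np.ndarray:
    """Lambert azimuthal equal-area projection of lon/lat degrees to planar km.

    Centred at (lon0, lat0); area-true, which is what hull areas need.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    lam = np.radians(pts[:, 0])
    phi = np.radians(pts[:, 1])
    lam0 = math.radians(lon0)
    phi0 = math.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    # antipode of the centre is not projectable; clamp for numeric safety
    denom = np.maximum(1.0 + cos_c, 1e-12)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return np.column_stack([x, y])


def convex_hull_area(points, coord_mode: str) -> float:
    """Area (km^2) of the convex hull of the unique points.

    lonlat points are first projected with an azimuthal equal-area
    projection centred at their centroid. Collinear point sets have a
    degenerate hull of area 0. Requires >= 3 unique points.
    """
    _check_coord_mode(coord_mode)
    pts = unique_points(points)
    if len(pts) < 3:
        raise ValueError("convex hull area needs >= 3 unique points")
    if coord_mode == "lonlat":
        pts = project_azimuthal_equal_area(pts, pts[:, 0].mean(), pts[:, 1].mean())
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear
    return float(hull.volume)  # in 2-D, .volume is the enclosed area


def compute_all_metrics(
    ds: OccurrenceDataset, landcover: LandcoverGrid | None = None
) -> pd.DataFrame:
    """One metrics row per species; see :data:`METRIC_COLUMNS`.

    Exact duplicate coordinates are collapsed per species before distances;
    species left with a single unique point are excluded with a warning.
    ``habitat_count`` is NaN when no landcover grid is supplied;
    ``hull_area_km2`` is NaN for species with fewer than 3 unique points.
    """
    rows = []
    excluded: list[str] = []
    for sp in ds.species:
        pts = ds.points_for(sp)
        uniq = unique_points(pts)
        if len(uniq) < 2:
            excluded.append(sp)
            continue
        d_max = compute_dmax(uniq, ds.coord_mode)
        d_min = compute_dmin(uniq, ds.coord_mode)
        habitat = np.nan
        if landcover is not None:
            habitat = habitat_specificity(pts, landcover)
        hull = np.nan
        if len(uniq) >= 3:
            hull = convex_hull_area(uniq, ds.coord_mode)
        rows.append(
            {
                "species_id": sp,
                "n_obs": len(pts),
                "n_unique_points": len(uniq),
                "d_max_km": d_max,
                "d_min_km": d_min,
                "abundance": local_abundance_ratio(d_max, d_min),
                "habitat_count": habitat,
                "hull_area_km2": hull,
            }
        )
    if excluded:
        logger.warning(
            "compute_all_metrics: excluded %d species with a single unique point: %s",
            len(excluded), ", ".join(excluded[:10]),
        )
    if not rows:
        raise ValueError("no species with >= 2 unique points; nothing to compute")
    out = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    out.attrs["excluded_species"] = excluded
    return out
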