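"""Independent brute-force oracles, deliberately written without reusing any
rarityframe internals (own distance formulas, pure-python loops, shapely for
hull areas)."""

import math

from shapely.geometry import MultiPoint

R_EARTH = 6371.0088


def dist(p, q, coord_mode):
    if coord_mode == "planar_km":
        return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)
    lon1, lat1, lon2, lat2 = map(math.radians, (p[0], p[1], q[0], q[1]))
    # spherical law of cosines (different formula than the implementation)
    c = (
        math.sin(lat1) * math.sin(lat2)
        + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
    )
    return R_EARTH * math.acos(max(-1.0, min(1.0, c)))


def brute_dmax(points, coord_mode):
    pts = sorted(set(map(tuple, points)))
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            best = max(best, dist(pts[i], pts[j], coord_mode))
    return best


def brute_dmin(points, coord_mode):
    pts = sorted(set(map(tuple, points)))
    nearest = []
    for i, p in enumerate(pts):
        nearest.append(min(dist(p, q, coord_mode) for j, q in enumerate(pts) if j != i))
    return sum(nearest) / len(nearest)


def hull_area(points):
    return MultiPoint([tuple(p) for p in points]).convex_hull.area


def brute_richness(records, x0, y0, cell, n_rows, n_cols):
    """records: iterable of (species, x, y) -> dict cell -> species set."""
    cells = {}
    for sp, x, y in records:
        col = math.floor((x - x0) / cell)
        row = math.floor((y - y0) / cell)
        if 0 <= row < n_rows and 0 <= col < n_cols:
            cells.setdefault((row, col), set()).add(sp)
    return {cell: len(species) for cell, species in cells.items()}


def brute_top_cells(cell_values, q):
    """cell_values: dict cell -> richness; quantile-threshold selection."""
    occupied = {c: v for c, v in cell_values.items() if v > 0}
    ranked = sorted(occupied.values(), reverse=True)
    n_select = math.ceil(q * len(ranked))
    threshold = ranked[n_select - 1]
    return {c for c, v in occupied.items() if v >= threshold}, threshold


def brute_congruence(cell_sets, n_rows, n_cols):
    levels = {}
    for r in range(n_rows):
        for c in range(n_cols):
            levels[(r, c)] = sum(1 for s in cell_sets if (r, c) in s)
    return levels
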