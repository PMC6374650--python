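"""Gridded species richness, top-quantile cell selection and congruence maps.

Grids are regular, half-open ([x0 + i*s, x0 + (i+1)*s)), stored bottom-up
like :class:`~rarityframe.occurrence_io.LandcoverGrid`. "Top fraction"
selection ranks occupied cells (richness > 0) by value and keeps the
highest ceil(q * n_occupied), including every cell tied with the boundary
value. A congruence grid counts, per cell, how many groups' top sets
contain that cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .occurrence_io import OccurrenceDataset
from .rarity_metrics import project_azimuthal_equal_area

logger = logging.getLogger("rarityframe")


@dataclass(frozen=True)
class GridSpec:
    """Regular grid geometry: lower-left origin, cell size, extent."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size


@dataclass
class RichnessGrid:
    spec: GridSpec
    counts: np.ndarray  # int matrix (n_rows, n_cols), distinct species per cell
    subset_label: str = "all"


@dataclass(frozen=True)
class TopCellSet:
    spec: GridSpec
    cells: frozenset[tuple[int, int]]
    q: float
    threshold_value: int
    subset_label: str = "all"


@dataclass
class CongruenceGrid:
    spec: GridSpec
    levels: np.ndarray  # int matrix: number of top sets containing each cell


def build_grid(extent: Sequence[float], cell_size: float) -> GridSpec:
    """Grid covering (xmin, ymin, xmax, ymax); rows/cols are ceil(span/size).

    A zero-span extent still yields a 1x1 grid.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if xmax < xmin or ymax < ymin:
        raise ValueError("extent must satisfy xmax >= xmin and ymax >= ymin")
    n_cols = max(1, math.ceil((xmax - xmin) / cell_size))
    n_rows = max(1, math.ceil((ymax - ymin) / cell_size))
    return GridSpec(x0=xmin, y0=ymin, cell_size=cell_size, n_rows=n_rows, n_cols=n_cols)


def assign_point_to_cell(x: float, y: float, spec: GridSpec) -> tuple[int, int] | None:
    """Half-open binning; points beyond the upper/right outer edge are outside."""
    col = math.floor((x - spec.x0) / spec.cell_size)
    row = math.floor((y - spec.y0) / spec.cell_size)
    if 0 <= row < spec.n_rows and 0 <= col < spec.n_cols:
        return int(row), int(col)
    return None


def dataset_to_planar(ds: OccurrenceDataset) -> OccurrenceDataset:
    """Project a lonlat dataset once to planar km (azimuthal equal-area,
    centred on the data centroid); planar datasets pass through unchanged."""
    if ds.coord_mode == "planar_km":
        return ds
    xy = ds.coordinates()
    planar = project_azimuthal_equal_area(xy, xy[:, 0].mean(), xy[:, 1].mean())
    table = ds.table.copy()
    table["x"] = planar[:, 0]
    table["y"] = planar[:, 1]
    return OccurrenceDataset(table=table, coord_mode="planar_km", source=ds.source)


def richness_grid(
    ds: OccurrenceDataset,
    spec: GridSpec,
    species_subset: Iterable[str] | None = None,
    subset_label: str = "all",
) -> RichnessGrid:
    """Distinct-species count per cell for the given species subset.

    Multiple records of one species in a cell count once. Points outside
    the grid are ignored (an all-outside dataset yields an all-zero grid
    with a warning).
    """
    table = ds.table
    if species_subset is not None:
        subset = set(species_subset)
        if not subset:
            raise ValueError("species_subset is empty")
        table = table.loc[table["species_id"].isin(subset)]
    counts = np.zeros((spec.n_rows, spec.n_cols), dtype=int)
    seen: set[tuple[int, int, str]] = set()
    n_outside = 0
    for sp, x, y in zip(table["species_id"], table["x"], table["y"]):
        cell = assign_point_to_cell(float(x), float(y), spec)
        if cell is None:
            n_outside += 1
            continue
        key = (cell[0], cell[1], sp)
        if key not in seen:
            seen.add(key)
            counts[cell] += 1
    if len(table) and not seen:
        logger.warning("richness_grid: every point fell outside the grid")
    elif n_outside:
        logger.info("richness_grid: %d point(s) outside the grid ignored", n_outside)
    return RichnessGrid(spec=spec, counts=counts, subset_label=subset_label)


def top_fraction_cells(grid: RichnessGrid, q: float = 0.20) -> TopCellSet:
    """Top-q occupied cells by richness, ties at the boundary included.

    Occupied means richness > 0. Selects the ceil(q * n_occupied) highest
    values, then expands to every occupied cell whose value equals the
    selection boundary, so the returned set may exceed the nominal count.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    rows, cols = np.nonzero(grid.counts > 0)
    if len(rows) == 0:
        raise ValueError("no occupied cells in richness grid")
    values = grid.counts[rows, cols]
    n_select = math.ceil(q * len(values))
    threshold = int(np.sort(values)[::-1][n_select - 1])
    keep = values >= threshold
    cells = frozenset(zip(rows[keep].tolist(), cols[keep].tolist()))
    return TopCellSet(
        spec=grid.spec, cells=cells, q=q, threshold_value=threshold,
        subset_label=grid.subset_label,
    )


def congruence_map(top_sets: Sequence[TopCellSet]) -> CongruenceGrid:
    """Per-cell count of how many top sets contain the cell."""
    if not top_sets:
        raise ValueError("need at least one top set")
    spec = top_sets[0].spec
    if any(ts.spec != spec for ts in top_sets):
        raise ValueError("all top sets must share one GridSpec")
    levels = np.zeros((spec.n_rows, spec.n_cols), dtype=int)
    for ts in top_sets:
        for row, col in ts.cells:
            levels[row, col] += 1
    return CongruenceGrid(spec=spec, levels=levels)


def congruence_area_summary(cg: CongruenceGrid, cell_area_km2: float) -> pd.DataFrame:
    """Per-level area accounting over the selected (level >= 1) cells.

    Columns: level, n_cells, area_km2, percent (unrounded, sums to 100),
    percent_rounded (nearest integer), and the cumulative ">= level"
    equivalents area_km2_ge / percent_ge / percent_ge_rounded.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    selected = cg.levels[cg.levels >= 1]
    if selected.size == 0:
        raise ValueError("congruence grid has no selected cells")
    total_area = selected.size * cell_area_km2
    max_level = int(cg.levels.max())
    rows = []
    for level in range(1, max_level + 1):
        n_cells = int((cg.levels == level).sum())
        n_ge = int((cg.levels >= level).sum())
        area = n_cells * cell_area_km2
        area_ge = n_ge * cell_area_km2
        rows.append(
            {
                "level": level,
                "n_cells": n_cells,
                "area_km2": area,
                "percent": 100.0 * area / total_area,
                "percent_rounded": round(100.0 * area / total_area),
                "area_km2_ge": area_ge,
                "percent_ge": 100.0 * area_ge / total_area,
                "percent_ge_rounded": round(100.0 * area_ge / total_area),
            }
        )
    return pd.DataFrame(rows)


def selected_area_km2(cg: CongruenceGrid, cell_area_km2: float) -> float:
    """Total area of the union of the top sets (cells with level >= 1)."""
    return float((cg.levels >= 1).sum()) * cell_area_km2
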