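"""Reading, validation and writing of occurrence tables, landcover grids and species lists.

All tabular I/O is plain-text (CSV/TSV, UTF-8); rasters use the ESRI ASCII
grid dialect so that every artifact in a pipeline run is diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rarityframe")

COORD_MODES = ("lonlat", "planar_km")


def _check_coord_mode(coord_mode: str) -> str:
    if coord_mode not in COORD_MODES:
        raise ValueError(f"coord_mode must be one of {COORD_MODES}, got {coord_mode!r}")
    return coord_mode


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single presence record: one species seen at one location."""

    species_id: str
    x: float
    y: float
    date: str | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")


@dataclass
class OccurrenceDataset:
    """Point occurrence records sharing one declared coordinate mode.

    The coordinate mode is an explicit dataset-level declaration (``lonlat``
    for degrees, ``planar_km`` for kilometres east/north); it is never
    inferred from coordinate magnitudes, and datasets with different modes
    cannot be mixed.
    """

    table: pd.DataFrame  # columns: species_id, x, y, date
    coord_mode: str
    source: str = ""
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        _check_coord_mode(self.coord_mode)
        required = {"species_id", "x", "y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        if "date" not in self.table.columns:
            self.table = self.table.assign(date=None)
        if len(self.table) == 0:
            raise ValueError("occurrence dataset has no records")

    @classmethod
    def from_records(
        cls, records: Iterable[OccurrenceRecord], coord_mode: str, source: str = ""
    ) -> "OccurrenceDataset":
        rows = [(r.species_id, r.x, r.y, r.date) for r in records]
        table = pd.DataFrame(rows, columns=["species_id", "x", "y", "date"])
        return cls(table=table, coord_mode=coord_mode, source=source)

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species_id"].unique())

    @property
    def n_species(self) -> int:
        return self.table["species_id"].nunique()

    def points_for(self, species_id: str) -> np.ndarray:
        """(n, 2) array of x/y coordinates for one species."""
        sub = self.table.loc[self.table["species_id"] == species_id, ["x", "y"]]
        return sub.to_numpy(dtype=float)

    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def subset_species(self, species: Iterable[str]) -> "OccurrenceDataset":
        keep = self.table["species_id"].isin(set(species))
        return OccurrenceDataset(
            table=self.table.loc[keep].reset_index(drop=True),
            coord_mode=self.coord_mode,
            source=self.source,
        )


@dataclass
class LandcoverGrid:
    """Regular categorical raster with integer class codes.

    ``classes`` is stored bottom-up: row 0 spans ``[y0, y0 + cell_size)``.
    ESRI ASCII files are written/read top-row-first and flipped on the way
    through.
    """

    x0: float
    y0: float
    cell_size: float
    classes: np.ndarray  # int matrix, shape (n_rows, n_cols), row 0 = south
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_classes < 1:
            raise ValueError("no landcover classes: grid is all nodata")

    @property
    def n_rows(self) -> int:
        return self.classes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    @property
    def class_codes(self) -> np.ndarray:
        """Sorted distinct non-nodata codes present in the grid."""
        vals = np.unique(self.classes)
        return vals[vals != self.nodata]

    @property
    def n_classes(self) -> int:
        return len(self.class_codes)

    def cell_index(self, x: float, y: float) -> tuple[int, int] | None:
        """Half-open binning; None when (x, y) falls outside the grid."""
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((y - self.y0) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def class_at(self, x: float, y: float) -> int | None:
        """Class code at a point; None when off-grid or nodata."""
        idx = self.cell_index(x, y)
        if idx is None:
            return None
        code = int(self.classes[idx])
        return None if code == self.nodata else code


@dataclass(frozen=True)
class SpeciesList:
    label: str  # endangered | endemic | iucn | custom
    names: frozenset[str]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"species list {self.label!r} is empty")


@dataclass
class DropReport:
    """Outcome of the minimum-records filter."""

    min_records: int
    dropped_species: list[str]
    n_records_dropped: int
    n_species_kept: int
    n_records_kept: int


def read_occurrences(
    path: str | Path,
    coord_mode: str,
    species_col: str = "species",
    x_col: str = "x",
    y_col: str = "y",
    date_col: str = "date",
    source: str | None = None,
) -> OccurrenceDataset:
    """Read an occurrence CSV into a validated :class:`OccurrenceDataset`.

    Rows with a blank species name, unparseable coordinates, or (in lonlat
    mode) out-of-range coordinates are dropped and counted; a warning is
    logged with the count. Missing required columns raise ``ValueError``.
    """
    _check_coord_mode(coord_mode)
    path = Path(path)
    raw = pd.read_csv(path, dtype={species_col: str}, encoding="utf-8")
    if len(raw) == 0:
        raise ValueError(f"occurrence file {path} is empty")
    for col in (species_col, x_col, y_col):
        if col not in raw.columns:
            raise ValueError(f"occurrence file {path} is missing required column {col!r}")

    table = pd.DataFrame(
        {
            "species_id": raw[species_col].astype("string").str.strip(),
            "x": pd.to_numeric(raw[x_col], errors="coerce"),
            "y": pd.to_numeric(raw[y_col], errors="coerce"),
            "date": raw[date_col] if date_col in raw.columns else None,
        }
    )
    ok = table["species_id"].notna() & (table["species_id"] != "")
    ok &= np.isfinite(table["x"].to_numpy(dtype=float, na_value=np.nan))
    ok &= np.isfinite(table["y"].to_numpy(dtype=float, na_value=np.nan))
    if coord_mode == "lonlat":
        ok &= table["x"].between(-180.0, 180.0) & table["y"].between(-90.0, 90.0)

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("read_occurrences: dropped %d invalid row(s) from %s", n_dropped, path)
    table = table.loc[ok].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError(f"occurrence file {path} has no valid records")
    table["species_id"] = table["species_id"].astype(str)
    ds = OccurrenceDataset(
        table=table, coord_mode=coord_mode, source=source if source is not None else str(path)
    )
    ds.n_dropped_rows = n_dropped
    return ds


def filter_species_min_records(
    ds: OccurrenceDataset, min_n: int = 2
) -> tuple[OccurrenceDataset, DropReport]:
    """Keep only species with at least ``min_n`` occurrence records.

    Returns the filtered dataset and a :class:`DropReport`. Record counts
    are conserved: kept + dropped equals the input size. Raises if every
    species would be dropped.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = ds.table["species_id"].value_counts()
    keep = set(counts.index[counts >= min_n])
    if not keep:
        raise ValueError(f"no species has >= {min_n} records; nothing left to analyse")
    dropped = sorted(set(counts.index) - keep)
    mask = ds.table["species_id"].isin(keep)
    filtered = OccurrenceDataset(
        table=ds.table.loc[mask].reset_index(drop=True),
        coord_mode=ds.coord_mode,
        source=ds.source,
    )
    report = DropReport(
        min_records=min_n,
        dropped_species=dropped,
        n_records_dropped=int((~mask).sum()),
        n_species_kept=len(keep),
        n_records_kept=int(mask.sum()),
    )
    if dropped:
        logger.info(
            "filter_species_min_records: dropped %d species (%d records) below %d records",
            len(dropped), report.n_records_dropped, min_n,
        )
    return filtered, report


# ---------------------------------------------------------------------------
# ESRI ASCII grids

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float, float]:
    """Parse an ESRI ASCII grid; returns (matrix bottom-up, x0, y0, cell, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in _HEADER_KEYS and len(parts) == 2 and not data_lines:
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header line {key!r}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"ASCII grid {path}: header says {n_rows}x{n_cols} = {n_rows * n_cols} "
            f"cells but found {values.size} values"
        )
    matrix = values.reshape(n_rows, n_cols)[::-1]  # file is top-first; store bottom-up
    return matrix, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata


def write_ascii_grid(
    matrix: np.ndarray,
    path: str | Path,
    x0: float,
    y0: float,
    cell_size: float,
    nodata: int | float = -9999,
    fmt: str = "%d",
) -> None:
    """Write a bottom-up matrix as an ESRI ASCII grid (top row first on disk)."""
    matrix = np.asarray(matrix)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {matrix.shape[1]}\n")
        fh.write(f"nrows {matrix.shape[0]}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {y0:.10g}\n")
        fh.write(f"cellsize {cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in matrix[::-1]:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_landcover_grid(path: str | Path) -> LandcoverGrid:
    """Read a categorical landcover raster from an ESRI ASCII grid file."""
    matrix, x0, y0, cell, nodata = read_ascii_grid(path)
    if not np.allclose(matrix, np.round(matrix)):
        raise ValueError(f"landcover grid {path} contains non-integer class codes")
    return LandcoverGrid(
        x0=x0, y0=y0, cell_size=cell, classes=matrix.astype(int), nodata=int(nodata)
    )


def write_landcover_grid(grid: LandcoverGrid, path: str | Path) -> None:
    write_ascii_grid(
        grid.classes, path, grid.x0, grid.y0, grid.cell_size, nodata=grid.nodata
    )


def read_species_list(path: str | Path, label: str = "custom") -> SpeciesList:
    """One name per line; ``#`` comments and blank lines ignored; duplicates collapsed."""
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                names.add(name)
    if not names:
        raise ValueError(f"species list {path} is empty after parsing")
    return SpeciesList(label=label, names=frozenset(names))


def write_table(
    rows: pd.DataFrame | Sequence[dict],
    path: str | Path,
    format: str = "csv",
    float_sig: int = 4,
    sort_by: str | None = None,
) -> None:
    """Write a table deterministically: stable column order, sorted rows,
    floats at ``float_sig`` significant digits, UTF-8.

    Rows are sorted by ``sort_by`` when given, else by the first column.
    An empty row set still yields a header-only file.
    """
    if format not in ("csv", "tsv"):
        raise ValueError("format must be 'csv' or 'tsv'")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if len(df) and len(df.columns):
        key = sort_by if sort_by is not None else df.columns[0]
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    sep = "," if format == "csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=f"%.{float_sig}g", encoding="utf-8")
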