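"""Synthetic landscapes and occurrence point patterns with known rarity labels.

Species are drawn from Thomas-process-style archetypes: a range centre, a
handful of parent points inside the range radius, and offspring scattered
around the parents. Tight offspring scatter compresses nearest-neighbour
distances and therefore inflates the d_max/d_min abundance proxy; the range
radius drives d_max; the size of the allowed landcover-class subset drives
habitat specificity. Each archetype is named after the rarity code it is
built to land in, so pipeline output can be scored against ground truth.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .occurrence_io import LandcoverGrid, OccurrenceDataset
from .rarity_classify import RARITY_CODES, ClassificationResult
from .richness_mapping import GridSpec

_MAX_TRIES_PER_POINT = 1000


@dataclass(frozen=True)
class SyntheticArchetype:
    """Generator parameters for one rarity class.

    range_radius_km: spread of parent points (small -> Narrow range).
    n_clusters / cluster_sd_km: Thomas clustering controls; a small
    cluster_sd packs points tightly and yields Large local abundance.
    n_habitat_classes: size of the allowed landcover-class subset
    (1 -> Restricted specificity).
    """

    label: str
    range_radius_km: float
    n_points: int
    n_clusters: int
    cluster_sd_km: float
    n_habitat_classes: int

    def __post_init__(self) -> None:
        if self.label not in RARITY_CODES:
            raise ValueError(f"label must be one of {RARITY_CODES}")
        if self.range_radius_km <= 0:
            raise ValueError("range_radius_km must be positive")
        if self.cluster_sd_km >= self.range_radius_km:
            raise ValueError("cluster_sd_km must be smaller than range_radius_km")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if self.n_clusters < 1 or self.n_habitat_classes < 1:
            raise ValueError("n_clusters and n_habitat_classes must be >= 1")


# Defaults chosen so that within a 500x500 km domain with 8 landcover
# classes the three index axes are well separated: N vs W range radii
# differ ~7x, Small archetypes scatter offspring across most of the range
# while Large archetypes pack them at sub-km scale, and Restricted
# archetypes occupy a single landcover class.
DEFAULT_DOMAIN = (0.0, 0.0, 500.0, 500.0)
DEFAULT_N_LANDCOVER_CLASSES = 8
DEFAULT_LANDCOVER_CELL_KM = 5.0
DEFAULT_PATCH_SCALE_KM = 25.0


def _archetype(label: str) -> SyntheticArchetype:
    narrow = label.startswith("N")
    restricted = label[2] == "R"
    large = label.endswith("L")
    radius = 30.0 if narrow else 210.0
    return SyntheticArchetype(
        label=label,
        range_radius_km=radius,
        n_points=40,
        n_clusters=6,
        cluster_sd_km=0.3 if large else 0.55 * radius,
        n_habitat_classes=1 if restricted else DEFAULT_N_LANDCOVER_CLASSES,
    )


DEFAULT_ARCHETYPES: dict[str, SyntheticArchetype] = {
    code: _archetype(code) for code in RARITY_CODES
}


@dataclass
class TruthTable:
    """species_id -> archetype label for every generated species."""

    labels: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["species_id", "true_code"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        return cls(labels=dict(zip(df["species_id"].astype(str), df["true_code"])))


def generate_landcover(
    spec: GridSpec,
    n_classes: int,
    patch_scale_km: float = DEFAULT_PATCH_SCALE_KM,
    seed: int | np.random.Generator = 0,
) -> LandcoverGrid:
    """Spatially autocorrelated categorical raster via nearest-seed patches.

    Voronoi-style: seed points are scattered at a density of roughly one
    per patch_scale_km^2 square; each cell takes the class of its nearest
    seed. The first n_classes seeds cycle through all codes, so every class
    is present whenever the grid is reasonably larger than n_classes.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    width = spec.n_cols * spec.cell_size
    height = spec.n_rows * spec.cell_size
    n_seeds = max(n_classes, int(round(width * height / patch_scale_km**2)))
    seeds_xy = rng.uniform((spec.x0, spec.y0), (spec.x0 + width, spec.y0 + height),
                           size=(n_seeds, 2))
    seed_classes = np.concatenate(
        [np.arange(1, n_classes + 1), rng.integers(1, n_classes + 1, size=n_seeds - n_classes)]
    )
    cx = spec.x0 + (np.arange(spec.n_cols) + 0.5) * spec.cell_size
    cy = spec.y0 + (np.arange(spec.n_rows) + 0.5) * spec.cell_size
    gx, gy = np.meshgrid(cx, cy)  # shape (n_rows, n_cols), row 0 = south
    d2 = (gx[..., None] - seeds_xy[:, 0]) ** 2 + (gy[..., None] - seeds_xy[:, 1]) ** 2
    classes = seed_classes[np.argmin(d2, axis=-1)].astype(int)
    return LandcoverGrid(
        x0=spec.x0, y0=spec.y0, cell_size=spec.cell_size, classes=classes
    )


def _allowed_classes(
    arch: SyntheticArchetype,
    landcover: LandcoverGrid,
    center: np.ndarray,
    rng: np.random.Generator,
) -> set[int]:
    """Habitat-class subset the species may occupy.

    Chosen from classes actually present inside the range disk (habitat
    affinity follows where the species lives), most frequent first, so
    rejection sampling against the subset can succeed.
    """
    all_codes = landcover.class_codes
    if arch.n_habitat_classes >= len(all_codes):
        return set(int(c) for c in all_codes)
    n_probe = 256
    theta = rng.uniform(0, 2 * np.pi, n_probe)
    r = arch.range_radius_km * np.sqrt(rng.uniform(0, 1, n_probe))
    probes = center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    found: dict[int, int] = {}
    for x, y in probes:
        code = landcover.class_at(x, y)
        if code is not None:
            found[code] = found.get(code, 0) + 1
    if not found:  # range disk entirely off-grid; fall back to any class
        found = {int(c): 1 for c in all_codes}
    ranked = sorted(found, key=lambda c: (-found[c], c))
    return set(ranked[: arch.n_habitat_classes])


def generate_species_occurrences(
    arch: SyntheticArchetype,
    landcover: LandcoverGrid,
    extent: tuple[float, float, float, float] = DEFAULT_DOMAIN,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one species' (n, 2) planar-km point set.

    A range centre is drawn uniformly in the extent (inset by the range
    radius where possible), parents uniformly in the range disk, offspring
    normally around a random parent. Points landing outside the extent or
    on a disallowed landcover class are rejected and redrawn, up to
    1,000 tries per point; fewer than 2 placeable points is an error.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xmin, ymin, xmax, ymax = extent
    inset = min(arch.range_radius_km, (xmax - xmin) / 2, (ymax - ymin) / 2)
    center = rng.uniform((xmin + inset, ymin + inset), (xmax - inset, ymax - inset))
    allowed = _allowed_classes(arch, landcover, center, rng)

    # Parents sit on allowed landcover, else tight offspring scatter around
    # an off-habitat parent would reject every draw.
    parents = []
    for _ in range(arch.n_clusters):
        for _try in range(_MAX_TRIES_PER_POINT):
            theta = rng.uniform(0, 2 * np.pi)
            r = arch.range_radius_km * np.sqrt(rng.uniform(0, 1))
            p = center + np.array([r * np.cos(theta), r * np.sin(theta)])
            if not (xmin <= p[0] < xmax and ymin <= p[1] < ymax):
                continue
            code = landcover.class_at(p[0], p[1])
            if code is not None and code in allowed:
                parents.append(p)
                break
    if not parents:
        raise RuntimeError(
            f"could not place any cluster parent for archetype {arch.label}"
        )
    parents = np.asarray(parents)

    points = []
    for _ in range(arch.n_points):
        for _try in range(_MAX_TRIES_PER_POINT):
            parent = parents[rng.integers(len(parents))]
            p = parent + rng.normal(0.0, arch.cluster_sd_km, 2)
            if not (xmin <= p[0] < xmax and ymin <= p[1] < ymax):
                continue
            code = landcover.class_at(p[0], p[1])
            if code is not None and code in allowed:
                points.append(p)
                break
    if len(points) < 2:
        raise RuntimeError(
            f"could not place >= 2 points for archetype {arch.label} "
            f"after {_MAX_TRIES_PER_POINT} tries per point"
        )
    return np.asarray(points)


def generate_archetype_dataset(
    archetypes: Mapping[str, SyntheticArchetype] | None = None,
    n_per_class: int = 10,
    seed: int = 0,
    extent: tuple[float, float, float, float] = DEFAULT_DOMAIN,
    n_landcover_classes: int = DEFAULT_N_LANDCOVER_CLASSES,
    landcover_cell_km: float = DEFAULT_LANDCOVER_CELL_KM,
    patch_scale_km: float = DEFAULT_PATCH_SCALE_KM,
) -> tuple[OccurrenceDataset, LandcoverGrid, TruthTable]:
    """Full synthetic scene: occurrences, landcover and ground-truth labels.

    Species are named deterministically (``NRS_0001`` etc.); coordinates
    are planar km. The same seed reproduces the scene bit-for-bit.
    """
    if archetypes is None:
        archetypes = DEFAULT_ARCHETYPES
    xmin, ymin, xmax, ymax = extent
    n_cols = int(np.ceil((xmax - xmin) / landcover_cell_km))
    n_rows = int(np.ceil((ymax - ymin) / landcover_cell_km))
    grid_spec = GridSpec(
        x0=xmin, y0=ymin, cell_size=landcover_cell_km, n_rows=n_rows, n_cols=n_cols
    )
    root = np.random.SeedSequence(seed)
    lc_seed, *species_seeds = root.spawn(1 + len(archetypes) * n_per_class)
    landcover = generate_landcover(
        grid_spec, n_landcover_classes, patch_scale_km, seed=np.random.default_rng(lc_seed)
    )

    rows = []
    labels: dict[str, str] = {}
    i_seed = 0
    for code in RARITY_CODES:
        if code not in archetypes:
            continue
        arch = archetypes[code]
        prefix = code.replace("/", "")
        for i in range(n_per_class):
            sp = f"{prefix}_{i + 1:04d}"
            pts = generate_species_occurrences(
                arch, landcover, extent, seed=np.random.default_rng(species_seeds[i_seed])
            )
            i_seed += 1
            labels[sp] = code
            rows.extend((sp, float(x), float(y)) for x, y in pts)
    table = pd.DataFrame(rows, columns=["species_id", "x", "y"])
    ds = OccurrenceDataset(table=table, coord_mode="planar_km", source=f"synthetic(seed={seed})")
    return ds, landcover, TruthTable(labels=labels)


def recovery_report(
    truth: TruthTable, result: ClassificationResult
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Score pipeline classifications against ground-truth archetype labels.

    Returns (8x8 confusion matrix true x predicted, overall accuracy,
    per-axis binary accuracies for range/specificity/abundance).
    """
    predicted = dict(zip(result.table["species_id"], result.table["code"]))
    truth_species = set(truth.labels)
    pred_species = set(predicted)
    if truth_species != pred_species:
        diff = sorted(truth_species ^ pred_species)
        raise ValueError(f"species mismatch between truth and result: {diff[:20]}")

    confusion = pd.DataFrame(
        0, index=pd.Index(RARITY_CODES, name="true"),
        columns=pd.Index(RARITY_CODES, name="predicted"),
    )
    axis_hits = {"range": 0, "specificity": 0, "abundance": 0}
    for sp, true_code in truth.labels.items():
        pred_code = predicted[sp]
        confusion.loc[true_code, pred_code] += 1
        axis_hits["range"] += true_code[0] == pred_code[0]
        axis_hits["specificity"] += true_code[2] == pred_code[2]
        axis_hits["abundance"] += true_code[4] == pred_code[4]
    total = len(truth.labels)
    accuracy = float(np.trace(confusion.to_numpy())) / total
    per_axis = {axis: hits / total for axis, hits in axis_hits.items()}
    return confusion, accuracy, per_axis
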