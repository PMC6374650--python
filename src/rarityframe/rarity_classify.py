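"""Eight-class rarity assignment from mean-based cutoffs.

Each of the three indices is binarized at an arithmetic-mean cutoff:

* range: Narrow (N) when d_max is below the mean d_max of all species,
  else Wide (W);
* habitat specificity: Restricted (R) below the cutoff, else Broad (B);
* local abundance: Small (S) below the cutoff, else Large (L).

In the default ``within_group`` mode the specificity and abundance cutoffs
are the means computed separately inside the narrow and wide range groups;
``global`` mode uses the mean over all species for every index. Values
exactly equal to a cutoff go to the non-rare side (W/B/L). Seven of the
eight codes are forms of rarity; W/B/L is "common".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .occurrence_io import SpeciesList

RARITY_CODES = (
    "N/R/S", "N/R/L", "N/B/S", "N/B/L",
    "W/R/S", "W/R/L", "W/B/S", "W/B/L",
)
COMMON_CODE = "W/B/L"
CUTOFF_MODES = ("within_group", "global")


@dataclass(frozen=True)
class CutoffSet:
    """Mean-based thresholds binarizing the three indices.

    ``abundance_cutoff`` and ``specificity_cutoff`` map the range group
    (``narrow``/``wide``) to its cutoff; in global mode both entries are
    equal.
    """

    range_cutoff_km: float
    abundance_cutoff: Mapping[str, float]
    specificity_cutoff: Mapping[str, float]
    mode: str = "within_group"

    def __post_init__(self) -> None:
        if self.mode not in CUTOFF_MODES:
            raise ValueError(f"mode must be one of {CUTOFF_MODES}")
        for name, value in [("range_cutoff_km", self.range_cutoff_km)]:
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for mapping in (self.abundance_cutoff, self.specificity_cutoff):
            for group in ("narrow", "wide"):
                if group not in mapping:
                    raise ValueError(f"cutoff mapping missing group {group!r}")
                if not mapping[group] > 0:
                    raise ValueError("cutoffs must be positive")


@dataclass
class ClassificationResult:
    """Per-species class assignments plus class-level counts/percentages."""

    table: pd.DataFrame  # species_id, code, range_label, specificity_label,
    #                      abundance_label, d_max_km, abundance, habitat_count
    cutoffs: CutoffSet

    @property
    def n_classified(self) -> int:
        return len(self.table)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["code"].value_counts()
        return {code: int(counts.get(code, 0)) for code in RARITY_CODES}

    @property
    def class_percent(self) -> dict[str, float]:
        total = self.n_classified
        return {
            code: round(100.0 * n / total, 1) for code, n in self.class_counts.items()
        }

    def summary(self) -> pd.DataFrame:
        counts = self.class_counts
        percent = self.class_percent
        return pd.DataFrame(
            {
                "code": list(RARITY_CODES),
                "n_species": [counts[c] for c in RARITY_CODES],
                "percent": [percent[c] for c in RARITY_CODES],
            }
        )


def _require_metric_columns(metrics: pd.DataFrame) -> None:
    needed = {"species_id", "d_max_km", "abundance", "habitat_count"}
    missing = needed - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")


def compute_cutoffs(metrics: pd.DataFrame, mode: str = "within_group") -> CutoffSet:
    """Arithmetic-mean cutoffs for the three indices.

    The range cutoff is always the mean ``d_max_km`` over all species.
    ``within_group`` then averages abundance and habitat_count separately
    within the narrow (d_max below the range cutoff) and wide groups;
    ``global`` uses the overall means for both groups.
    """
    if mode not in CUTOFF_MODES:
        raise ValueError(f"mode must be one of {CUTOFF_MODES}")
    _require_metric_columns(metrics)
    if len(metrics) < 2:
        raise ValueError("need at least 2 species to compute cutoffs")
    if metrics["habitat_count"].isna().any():
        raise ValueError("habitat_count contains NaN; supply a landcover grid upstream")

    range_cutoff = float(metrics["d_max_km"].mean())
    if mode == "global":
        abundance = float(metrics["abundance"].mean())
        specificity = float(metrics["habitat_count"].mean())
        return CutoffSet(
            range_cutoff_km=range_cutoff,
            abundance_cutoff={"narrow": abundance, "wide": abundance},
            specificity_cutoff={"narrow": specificity, "wide": specificity},
            mode="global",
        )

    narrow = metrics["d_max_km"] < range_cutoff
    groups = {"narrow": metrics.loc[narrow], "wide": metrics.loc[~narrow]}
    for name, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(
                f"the {name} range group is empty; use mode='global' instead"
            )
    return CutoffSet(
        range_cutoff_km=range_cutoff,
        abundance_cutoff={g: float(sub["abundance"].mean()) for g, sub in groups.items()},
        specificity_cutoff={
            g: float(sub["habitat_count"].mean()) for g, sub in groups.items()
        },
        mode="within_group",
    )


def assign_rarity_class(row: Mapping[str, float], cutoffs: CutoffSet) -> str:
    """Assign the 3-letter class code for one species' metrics.

    Strictly-below-cutoff goes to the rare side (Narrow/Restricted/Small);
    ties go to Wide/Broad/Large.
    """
    narrow = float(row["d_max_km"]) < cutoffs.range_cutoff_km
    group = "narrow" if narrow else "wide"
    restricted = float(row["habitat_count"]) < cutoffs.specificity_cutoff[group]
    small = float(row["abundance"]) < cutoffs.abundance_cutoff[group]
    return (
        ("N" if narrow else "W")
        + "/" + ("R" if restricted else "B")
        + "/" + ("S" if small else "L")
    )


def classify_species(metrics: pd.DataFrame, cutoffs: CutoffSet) -> ClassificationResult:
    """Classify every species in the metrics table into one of the 8 codes."""
    _require_metric_columns(metrics)
    codes = [assign_rarity_class(row, cutoffs) for _, row in metrics.iterrows()]
    table = pd.DataFrame(
        {
            "species_id": metrics["species_id"].to_numpy(),
            "code": codes,
            "range_label": [c[0] for c in codes],
            "specificity_label": [c[2] for c in codes],
            "abundance_label": [c[4] for c in codes],
            "d_max_km": metrics["d_max_km"].to_numpy(),
            "abundance": metrics["abundance"].to_numpy(),
            "habitat_count": metrics["habitat_count"].to_numpy(),
        }
    )
    return ClassificationResult(table=table, cutoffs=cutoffs)


def crosstab_with_lists(
    result: ClassificationResult, lists: Iterable[SpeciesList]
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Cross-tabulate class membership against named species lists.

    Returns (table indexed by code with one count column per list, plus an
    ``n_species`` column; mapping of list label -> members absent from the
    classification).
    """
    lists = list(lists)
    counts = result.class_counts
    out = pd.DataFrame({"n_species": [counts[c] for c in RARITY_CODES]},
                       index=pd.Index(RARITY_CODES, name="code"))
    missing: dict[str, set[str]] = {}
    classified = set(result.table["species_id"])
    for sl in lists:
        member = result.table["species_id"].isin(sl.names)
        by_code = result.table.loc[member, "code"].value_counts()
        out[sl.label] = [int(by_code.get(c, 0)) for c in RARITY_CODES]
        missing[sl.label] = set(sl.names) - classified
    return out, missing


def narrow_wide_ratio(crosstab: pd.DataFrame, column: str) -> float:
    """Ratio of a crosstab column summed over N-prefixed codes to the sum
    over W-prefixed codes."""
    idx = crosstab.index.astype(str)
    n_sum = crosstab.loc[idx.str.startswith("N"), column].sum()
    w_sum = crosstab.loc[idx.str.startswith("W"), column].sum()
    if w_sum == 0:
        raise ZeroDivisionError("no members in the wide range classes")
    return float(n_sum) / float(w_sum)


def range_size_agreement(metrics: pd.DataFrame) -> float:
    """Agreement rate between the distance-based and hull-based binary
    narrow/wide labels.

    Only species with a defined hull area (>= 3 unique points) are
    eligible; both cutoffs are means over that same eligible set. Returns
    the fraction of eligible species receiving the same label.
    """
    if "hull_area_km2" not in metrics.columns:
        raise ValueError("metrics table has no hull_area_km2 column")
    eligible = metrics.loc[metrics["hull_area_km2"].notna()]
    if len(eligible) == 0:
        raise ValueError("no species with a defined hull area")
    narrow_by_dmax = eligible["d_max_km"] < eligible["d_max_km"].mean()
    narrow_by_hull = eligible["hull_area_km2"] < eligible["hull_area_km2"].mean()
    return float((narrow_by_dmax == narrow_by_hull).mean())
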