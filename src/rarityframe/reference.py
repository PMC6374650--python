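"""Published reference values from the South Korean national plant survey
application of this pipeline (2006-2013 National Ecosystem Survey plants,
classified against the 2007 Ministry of Environment landcover map).

The underlying occurrence data (EcoBank, ecobank.nie.re.kr) and landcover
map have no scriptable download, so the national-scale numbers cannot be
recomputed offline; they are carried here as reference values for
consistency checks and documentation. Desk-scale pipelines are validated
instead against synthetic data with known ground truth.
"""

from __future__ import annotations

import pandas as pd

# Eight-class summary of the 2,215 classified species; "." entries in the
# published table (no list members in that class) are zeros here.
CLASS_TABLE = pd.DataFrame(
    [
        ("N/R/S", 384, 17.3, 7, 36, 18),
        ("N/R/L", 11, 0.5, 0, 0, 0),
        ("N/B/S", 237, 10.7, 3, 11, 4),
        ("N/B/L", 283, 12.8, 1, 17, 3),
        ("W/R/S", 540, 24.4, 0, 32, 2),
        ("W/R/L", 68, 3.1, 0, 3, 0),
        ("W/B/S", 193, 8.7, 0, 3, 1),
        ("W/B/L", 499, 22.5, 0, 11, 0),
    ],
    columns=["code", "n_species", "percent", "endangered", "endemic", "iucn"],
).set_index("code")

# Survey-wide totals.
RAW_SPECIES = 2_588
RAW_RECORDS = 149_421
CLASSIFIED_SPECIES = 2_215
CLASSIFIED_RECORDS = 149_048
KNOWN_FLORA_SPECIES = 4_130

# Per-species observation counts of the nationally listed endangered
# species recorded by the survey.
ENDANGERED_OBSERVATIONS = {
    "Aconitum coreanum": 11,
    "Aconitum austrokoreense": 9,
    "Cypripedium macranthos": 5,
    "Eleutherococcus senticosus": 5,
    "Echinosophora koreensis": 3,
    "Menyanthes trifoliata": 3,
    "Paeonia obovata": 3,
    "Astilboides tabularis": 2,
    "Drosera peltata var. nipponica": 2,
    "Thalictrum coreanum": 2,
    "Trientalis europaea var. arctica": 2,
}

# National-scale index summaries.
MEAN_DMAX_KM = 315.0            # range cutoff over all species
DMAX_RANGE_KM = (0.01, 496.0)
MEAN_DMIN_KM = 42.0
DMIN_RANGE_KM = (0.01, 439.0)
ABUNDANCE_RANGE = (1.0, 96.8)
MEAN_ABUNDANCE = 19.3
SPECIFICITY_RANGE = (1, 14)
MEAN_SPECIFICITY = 5.3
NARROW_GROUP_MEAN_SPECIFICITY = 3.0
NARROW_GROUP_MEAN_ABUNDANCE = 6.1
HULL_AGREEMENT_RATE = 0.85      # d_max vs convex-hull narrow/wide agreement

# Highest single-cell richness at each grid resolution (km -> species).
RICHNESS_MAX_BY_RESOLUTION = {10: 481, 25: 773, 50: 1_078}

# Congruence of the per-class top-20% richness cells, in km^2.
CONGRUENCE_TOTAL_SELECTED_KM2 = 34_600
CONGRUENCE_LEVEL_AREAS_KM2 = {1: 13_000, 6: 3_600, 7: 1_100}
CONGRUENCE_GE5_AREA_KM2 = 7_100


def narrow_species_total() -> int:
    """Published species count across the four narrow-range classes."""
    idx = CLASS_TABLE.index.str.startswith("N")
    return int(CLASS_TABLE.loc[idx, "n_species"].sum())


def wide_species_total() -> int:
    """Published species count across the four wide-range classes."""
    idx = CLASS_TABLE.index.str.startswith("W")
    return int(CLASS_TABLE.loc[idx, "n_species"].sum())
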