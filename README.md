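# rarityframe

Classify species rarity from presence-only occurrence records and map
where the different forms of rarity concentrate.

For each species with at least two records, three spatial indices are
computed:

* **d_max** — the largest distance (km) between any pair of occurrence
  points, a proxy for geographic range size;
* **d_min** — the mean distance from each point to its nearest
  conspecific point;
* **local abundance** — the ratio `d_max / d_min` (≥ 1 by construction;
  tightly packed records give large values);
* **habitat specificity** — the number of distinct landcover classes the
  records fall in, read from a categorical raster.

Each index is binarized at an arithmetic-mean cutoff (range over all
species; abundance and specificity by default within the narrow and wide
range groups), yielding the 2×2×2 rarity typology: seven rarity classes
plus the common class (`W/B/L`). Downstream, per-class species richness
is gridded at configurable resolutions, the top 20% richest occupied
cells are selected per class, and a congruence map counts how many
classes flag each cell — a simple conservation-prioritization surface.

A synthetic generator (`rarityframe.synthetic_data`) produces landcover
landscapes and Thomas-process-style occurrence patterns with known
class labels, so the full pipeline is testable end-to-end without any
external data; `recovery_report` scores pipeline output against the
ground truth.

## CLI

```bash
# generate a synthetic scene (occurrences.csv, landcover.asc, truth.csv)
rarityframe simulate --seed 42 --n-per-class 10 --out sim/

# metrics + eight-class assignment (metrics.csv, classification.csv, summary.csv)
rarityframe classify --occurrences sim/occurrences.csv \
    --landcover sim/landcover.asc --coord-mode planar_km \
    --cutoff-mode within_group --lists endangered=end.txt --out-dir cls/

# richness rasters, top-20% selection and congruence maps at 10/25/50 km
rarityframe map --occurrences sim/occurrences.csv \
    --classification cls/classification.csv \
    --resolution 10 --resolution 25 --resolution 50 --out-dir maps/
```

Occurrence input is CSV (`species,x,y[,date]`, configurable column
names) in either `lonlat` (degrees; haversine distances, Earth radius
6371.0088 km) or `planar_km` (Euclidean). Landcover and all raster
outputs use the ESRI ASCII grid format. For lon/lat data, gridding and
hull areas use an azimuthal equal-area projection centred on the data.

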