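import numpy as np
import pandas as pd
import pytest

from rarityframe.occurrence_io import LandcoverGrid, OccurrenceDataset


@pytest.fixture
def landcover_4x4():
    """4x4 planar grid, cell 1 km, classes {1,2,3} and one nodata cell.

    Bottom-up rows: row 0 is y in [0, 1).
    """
    classes = np.array(
        [
            [1, 1, 2, 2],
            [1, 1, 2, 2],
            [3, 3, 2, 2],
            [3, 3, -9999, 2],
        ]
    )
    return LandcoverGrid(x0=0.0, y0=0.0, cell_size=1.0, classes=classes, nodata=-9999)


@pytest.fixture
def toy_dataset():
    """Two species with hand-checkable geometry (planar km)."""
    table = pd.DataFrame(
        {
            "species_id": ["A", "A", "A", "B", "B"],
            "x": [0.0, 1.0, 5.0, 0.0, 3.0],
            "y": [0.0, 0.0, 0.0, 0.0, 4.0],
        }
    )
    return OccurrenceDataset(table=table, coord_mode="planar_km", source="toy")


def make_dataset(rows, coord_mode="planar_km"):
    table = pd.DataFrame(rows, columns=["species_id", "x", "y"])
    return OccurrenceDataset(table=table, coord_mode=coord_mode)
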