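import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from rarityframe import rarity_metrics as rm
from conftest import make_dataset
import _oracles

# closed form for one degree of longitude at the equator, computed
# independently of the implementation: pi * R / 180
ONE_DEGREE_KM = math.pi * 6371.0088 / 180.0


class TestPairwiseDistance:
    def test_identical_points(self):
        assert rm.pairwise_distance((3.0, 4.0), (3.0, 4.0), "planar_km") == 0.0
        assert rm.pairwise_distance((10.0, 20.0), (10.0, 20.0), "lonlat") == 0.0

    def test_planar_3_4_5(self):
        assert rm.pairwise_distance((0, 0), (3, 4), "planar_km") == pytest.approx(5.0)

    def test_lonlat_one_degree_equator(self):
        d = rm.pairwise_distance((0.0, 0.0), (1.0, 0.0), "lonlat")
        assert d == pytest.approx(ONE_DEGREE_KM, rel=1e-12)
        assert d == pytest.approx(111.195, abs=1e-3)

    def test_symmetry(self):
        assert rm.pairwise_distance((1, 2), (5, 7), "planar_km") == rm.pairwise_distance(
            (5, 7), (1, 2), "planar_km"
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rm.pairwise_distance((np.nan, 0), (0, 0), "planar_km")


class TestDmaxDmin:
    def test_dmax_hand_enumeration(self):
        pts = [(0, 0), (1, 0), (5, 0)]
        assert rm.compute_dmax(pts, "planar_km") == pytest.approx(5.0)

    def test_dmin_hand_computation(self):
        pts = [(0, 0), (1, 0), (5, 0)]
        # nearest distances: 1, 1, 4 -> mean 2
        assert rm.compute_dmin(pts, "planar_km") == pytest.approx(2.0)

    def test_two_point_species(self):
        pts = [(0, 0), (3, 4)]
        assert rm.compute_dmax(pts, "planar_km") == pytest.approx(5.0)
        assert rm.compute_dmin(pts, "planar_km") == pytest.approx(5.0)

    def test_equilateral_triangle_dmin(self):
        s = 2.0
        pts = [(0, 0), (s, 0), (s / 2, s * math.sqrt(3) / 2)]
        assert rm.compute_dmin(pts, "planar_km") == pytest.approx(s)

    def test_degenerate_species_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rm.compute_dmax([(1, 1), (1, 1)], "planar_km")

    @pytest.mark.parametrize("coord_mode", ["planar_km", "lonlat"])
    def test_against_brute_force(self, coord_mode):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(2, 26)
            if coord_mode == "planar_km":
                pts = rng.uniform(0, 100, (n, 2))
            else:
                pts = np.column_stack(
                    [rng.uniform(125, 130, n), rng.uniform(33, 39, n)]
                )
            assert rm.compute_dmax(pts, coord_mode) == pytest.approx(
                _oracles.brute_dmax(pts, coord_mode), rel=1e-6
            )
            assert rm.compute_dmin(pts, coord_mode) == pytest.approx(
                _oracles.brute_dmin(pts, coord_mode), rel=1e-6
            )


class TestAbundanceRatio:
    def test_two_point_floor(self):
        d = rm.compute_dmax([(0, 0), (1, 1)], "planar_km")
        assert rm.local_abundance_ratio(d, d) == pytest.approx(1.0)

    def test_hand_value(self):
        assert rm.local_abundance_ratio(5.0, 2.0) == pytest.approx(2.5)

    def test_scale_invariance(self):
        pts = np.array([(0, 0), (1, 0), (5, 0)], dtype=float)
        r1 = rm.local_abundance_ratio(
            rm.compute_dmax(pts, "planar_km"), rm.compute_dmin(pts, "planar_km")
        )
        r2 = rm.local_abundance_ratio(
            rm.compute_dmax(pts * 10, "planar_km"), rm.compute_dmin(pts * 10, "planar_km")
        )
        assert r1 == pytest.approx(r2)

    def test_zero_dmin_asserts(self):
        with pytest.raises(AssertionError):
            rm.local_abundance_ratio(5.0, 0.0)


class TestHabitatSpecificity:
    def test_single_class(self, landcover_4x4):
        assert rm.habitat_specificity([(0.5, 0.5), (1.5, 0.5)], landcover_4x4) == 1

    def test_two_classes(self, landcover_4x4):
        # class 1 at (0.5, 0.5); class 3 at (0.5, 2.5)
        assert rm.habitat_specificity([(0.5, 0.5), (0.5, 2.5)], landcover_4x4) == 2

    def test_off_grid_point_excluded_with_warning(self, landcover_4x4, caplog):
        pts = [(100.0, 100.0), (2.5, 0.5), (3.5, 0.5)]  # class 2 twice
        with caplog.at_level("WARNING", logger="rarityframe"):
            count = rm.habitat_specificity(pts, landcover_4x4)
        assert count == 1
        assert "off-grid" in caplog.text

    def test_nodata_cell_excluded(self, landcover_4x4):
        assert rm.habitat_specificity([(2.5, 3.5), (0.5, 0.5)], landcover_4x4) == 1

    def test_all_off_grid_is_error(self, landcover_4x4):
        with pytest.raises(ValueError, match="no habitat information"):
            rm.habitat_specificity([(99, 99), (-5, -5)], landcover_4x4)


class TestConvexHullArea:
    def test_unit_square(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert rm.convex_hull_area(pts, "planar_km") == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        assert rm.convex_hull_area([(0, 0), (1, 1), (2, 2)], "planar_km") == 0.0

    def test_fewer_than_three_unique_rejected(self):
        with pytest.raises(ValueError, match="3 unique"):
            rm.convex_hull_area([(0, 0), (1, 1), (1, 1)], "planar_km")

    def test_against_shapely_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pts = rng.uniform(0, 50, (rng.integers(3, 31), 2))
            assert rm.convex_hull_area(pts, "planar_km") == pytest.approx(
                _oracles.hull_area(pts), rel=1e-9
            )

    def test_lonlat_small_square_matches_planar(self):
        # 0.01 degree square at the equator is essentially planar
        d = 0.01
        pts = [(0, 0), (d, 0), (d, d), (0, d)]
        expected = (d * ONE_DEGREE_KM) ** 2
        assert rm.convex_hull_area(pts, "lonlat") == pytest.approx(expected, rel=1e-4)


class TestComputeAllMetrics:
    def test_toy_dataset_composition(self, toy_dataset, landcover_4x4):
        table = rm.compute_all_metrics(toy_dataset, landcover_4x4)
        assert list(table["species_id"]) == ["A", "B"]
        a = table.iloc[0]
        assert a["d_max_km"] == pytest.approx(5.0)
        assert a["d_min_km"] == pytest.approx(2.0)
        assert a["abundance"] == pytest.approx(2.5)
        assert a["n_obs"] == 3 and a["n_unique_points"] == 3
        b = table.iloc[1]
        assert b["d_max_km"] == pytest.approx(5.0)
        assert b["abundance"] == pytest.approx(1.0)
        assert np.isnan(b["hull_area_km2"])  # only 2 points
        assert a["hull_area_km2"] == 0.0  # collinear

    def test_all_duplicate_species_excluded(self, caplog):
        ds = make_dataset(
            [("A", 1.0, 1.0), ("A", 1.0, 1.0), ("B", 0.0, 0.0), ("B", 1.0, 0.0)]
        )
        with caplog.at_level("WARNING", logger="rarityframe"):
            table = rm.compute_all_metrics(ds)
        assert list(table["species_id"]) == ["B"]
        assert table.attrs["excluded_species"] == ["A"]

    def test_duplicates_collapsed_before_distances(self):
        ds = make_dataset([("A", 0.0, 0.0), ("A", 0.0, 0.0), ("A", 2.0, 0.0)])
        table = rm.compute_all_metrics(ds)
        row = table.iloc[0]
        assert row["n_obs"] == 3 and row["n_unique_points"] == 2
        assert row["d_min_km"] == pytest.approx(2.0)  # no zero distances

    def test_record_order_invariance(self, toy_dataset):
        shuffled = toy_dataset.table.sample(frac=1.0, random_state=3)
        ds2 = make_dataset(list(shuffled[["species_id", "x", "y"]].itertuples(index=False)))
        t1 = rm.compute_all_metrics(toy_dataset).set_index("species_id")
        t2 = rm.compute_all_metrics(ds2).set_index("species_id")
        for col in ("d_max_km", "d_min_km", "abundance"):
            np.testing.assert_allclose(t1[col], t2[col])


points_strategy = st.lists(
    st.tuples(
        st.floats(-500, 500, allow_nan=False, width=32),
        st.floats(-500, 500, allow_nan=False, width=32),
    ),
    min_size=2,
    max_size=20,
    unique=True,
)


@settings(max_examples=60, deadline=None)
@given(points_strategy)
def test_dmin_le_dmax_and_abundance_floor(pts):
    d_max = rm.compute_dmax(pts, "planar_km")
    d_min = rm.compute_dmin(pts, "planar_km")
    assert d_min <= d_max + 1e-12
    assert rm.local_abundance_ratio(d_max, d_min) >= 1.0 - 1e-12


@settings(max_examples=40, deadline=None)
@given(
    points_strategy,
    st.floats(-1000, 1000, allow_nan=False),
    st.floats(-1000, 1000, allow_nan=False),
    st.floats(0, 2 * math.pi, allow_nan=False),
)
def test_planar_rigid_motion_invariance(pts, tx, ty, theta):
    pts = np.asarray(pts, dtype=float)
    # near-coincident points can collapse to identical floats after the
    # rigid motion; the invariance is only meaningful above rounding scale
    assume(rm.compute_dmin(pts, "planar_km") > 1e-6)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    moved = pts @ rot.T + np.array([tx, ty])
    for fn in (rm.compute_dmax, rm.compute_dmin):
        assert fn(moved, "planar_km") == pytest.approx(
            fn(pts, "planar_km"), rel=1e-9, abs=1e-9
        )


@settings(max_examples=40, deadline=None)
@given(points_strategy, st.floats(0.01, 100, allow_nan=False))
def test_planar_linear_scaling(pts, scale):
    pts = np.asarray(pts, dtype=float)
    for fn in (rm.compute_dmax, rm.compute_dmin):
        assert fn(pts * scale, "planar_km") == pytest.approx(
            scale * fn(pts, "planar_km"), rel=1e-9, abs=1e-12
        )


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False, width=32),
            st.floats(-100, 100, allow_nan=False, width=32),
        ),
        min_size=3,
        max_size=15,
        unique=True,
    )
)
def test_hull_fits_in_dmax_circle(pts):
    area = rm.convex_hull_area(pts, "planar_km")
    d_max = rm.compute_dmax(pts, "planar_km")
    assert area <= math.pi / 4 * d_max**2 + 1e-9
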