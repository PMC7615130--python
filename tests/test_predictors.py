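import numpy as np
import pandas as pd
import pytest
import shapely

from deprivmap import predictors as PR
from deprivmap.frames import CoverageError, CRSError, EAFrame, RasterGrid

from .conftest import grid_frame


def _households(rows):
    base = {g: PR.default_category_map().reference[g] for g in PR.default_category_map().groups}
    out = []
    for r in rows:
        rec = dict(base, household_size=4, bedrooms=2)
        rec.update(r)
        out.append(rec)
    return pd.DataFrame(out)


class TestAggregateCensus:
    def test_degenerate_single_category(self):
        cmap = PR.default_category_map()
        h = _households([{"ea_id": "A", "toilet": "flush"} for _ in range(10)])
        tab = PR.aggregate_census(h, cmap)
        for cat in cmap.non_reference("toilet"):
            assert tab.loc["A", f"toilet_{cat}"] == 0.0
        # reference proportion = 1 - sum(non-reference) = 1
        assert 1.0 - sum(tab.loc["A", f"toilet_{c}"] for c in cmap.non_reference("toilet")) == 1.0

    def test_brute_force_count(self):
        cmap = PR.default_category_map()
        h = _households(
            [{"ea_id": "A", "water": "improved"}] * 4 + [{"ea_id": "A", "water": "unimproved"}] * 6
        )
        tab = PR.aggregate_census(h, cmap)
        assert tab.loc["A", "water_unimproved"] == pytest.approx(0.6)
        # improved (reference) proportion = 0.4
        assert 1 - tab.loc["A", "water_unimproved"] == pytest.approx(0.4)

    def test_partition_of_unity(self, small_bundle):
        cmap = PR.default_category_map()
        tab = PR.aggregate_census(small_bundle["households"], cmap)
        h = small_bundle["households"]
        for group in cmap.groups:
            nonref = tab[[f"{group}_{c}" for c in cmap.non_reference(group)]].sum(axis=1)
            ref_share = (
                h.assign(is_ref=(h[group] == cmap.reference[group]).astype(float))
                .groupby("ea_id")["is_ref"]
                .mean()
                .reindex(tab.index)
            )
            np.testing.assert_allclose(nonref + ref_share, 1.0, atol=1e-12)

    def test_unknown_category_named(self):
        cmap = PR.default_category_map()
        h = _households([{"ea_id": "A", "water": "bottled??"}])
        with pytest.raises(PR.MappingError, match="bottled"):
            PR.aggregate_census(h, cmap)

    def test_empty_table(self):
        with pytest.raises(ValueError):
            PR.aggregate_census(_households([]).iloc[0:0], PR.default_category_map())


class TestCrowding:
    def test_single_ratio(self):
        h = _households([{"ea_id": "A", "household_size": 6, "bedrooms": 2}])
        assert PR.crowding(h).loc["A"] == 3.0

    def test_hand_mean(self):
        h = _households(
            [
                {"ea_id": "A", "household_size": 4, "bedrooms": 2},
                {"ea_id": "A", "household_size": 2, "bedrooms": 1},
            ]
        )
        assert PR.crowding(h).loc["A"] == 2.0

    def test_ratio_invariance(self):
        h1 = _households([{"ea_id": "A", "household_size": 3, "bedrooms": 2}])
        h2 = _households([{"ea_id": "A", "household_size": 9, "bedrooms": 6}])
        assert PR.crowding(h1).loc["A"] == PR.crowding(h2).loc["A"]

    def test_zero_bedrooms_rejected(self):
        h = _households([{"ea_id": "A", "household_size": 3, "bedrooms": 0}])
        with pytest.raises(ValueError, match="bedrooms"):
            PR.crowding(h)


class TestPopDensity:
    def test_arithmetic(self):
        # 0.05 km^2 is the mean urban EA size in the study region
        f = grid_frame(1, 1, cell=1.0)
        f.df["geometry"] = [shapely.box(0, 0, 200, 250)]  # 0.05 km^2
        f.df["population"] = 500
        assert PR.pop_density(f).iloc[0] == pytest.approx(10000.0)

    def test_linearity(self):
        f = grid_frame(2, 1)
        d1 = PR.pop_density(f)
        f2 = f.copy()
        f2.df["population"] *= 2
        np.testing.assert_allclose(PR.pop_density(f2), 2 * d1)

    def test_geographic_crs_rejected(self):
        f = grid_frame(1, 2, crs="EPSG:4326")
        with pytest.raises(CRSError):
            PR.pop_density(f)


class TestZonalMean:
    def test_constant(self):
        f = grid_frame(2, 2, cell=1000.0)
        r = RasterGrid(np.full((40, 40), 7.25), -1000.0, 3000.0, 100.0)
        np.testing.assert_allclose(PR.zonal_mean(r, f), 7.25)

    def test_2x2_enumeration(self):
        # brute force: all four cell centres inside one polygon
        r = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.0, 20.0, 10.0)
        f = grid_frame(1, 1, cell=20.0)
        assert PR.zonal_mean(r, f).iloc[0] == pytest.approx(2.5)

    def test_nodata_masked(self):
        r = RasterGrid(np.array([[1.0, -9999.0], [3.0, -9999.0]]), 0.0, 20.0, 10.0)
        f = grid_frame(1, 1, cell=20.0)
        assert PR.zonal_mean(r, f).iloc[0] == pytest.approx(2.0)

    def test_outside_raster_errors(self):
        r = RasterGrid(np.ones((4, 4)), 1e6, 1e6 + 40, 10.0)
        f = grid_frame(1, 1, cell=100.0)
        with pytest.raises(CoverageError):
            PR.zonal_mean(r, f)

    def test_padding_invariance(self):
        f = grid_frame(1, 1, cell=20.0)
        core = np.array([[1.0, 2.0], [3.0, 4.0]])
        r = RasterGrid(core, 0.0, 20.0, 10.0)
        padded = np.full((6, 6), -9999.0)
        padded[2:4, 2:4] = core
        rp = RasterGrid(padded, -20.0, 40.0, 10.0)
        assert PR.zonal_mean(r, f).iloc[0] == PR.zonal_mean(rp, f).iloc[0]

    def test_subcell_polygon_falls_back_to_centroid(self):
        r = RasterGrid(np.array([[5.0, 9.0]]), 0.0, 10.0, 10.0)
        f = grid_frame(1, 1, cell=1.0)
        f.df["geometry"] = [shapely.box(11, 1, 13, 3)]  # inside second cell, no centre
        assert PR.zonal_mean(r, f).iloc[0] == 9.0


class TestNDVI:
    def _pair(self, red_vals, nir_vals):
        red = RasterGrid(np.asarray(red_vals, dtype=float), 0, 10, 10)
        nir = RasterGrid(np.asarray(nir_vals, dtype=float), 0, 10, 10)
        return red, nir

    def test_symmetry_zero(self):
        red, nir = self._pair([[0.4]], [[0.4]])
        assert PR.ndvi(red, nir).values[0, 0] == 0.0

    def test_closed_form(self):
        red, nir = self._pair([[0.2]], [[0.6]])
        assert PR.ndvi(red, nir).values[0, 0] == pytest.approx(0.5)

    def test_zero_sum_nodata(self):
        red, nir = self._pair([[0.0]], [[0.0]])
        out = PR.ndvi(red, nir)
        assert out.values[0, 0] == out.nodata

    def test_misaligned(self):
        red = RasterGrid(np.zeros((2, 2)), 0, 20, 10)
        nir = RasterGrid(np.zeros((2, 2)), 5, 20, 10)
        with pytest.raises(ValueError, match="align"):
            PR.ndvi(red, nir)

    def test_range(self, rng):
        red = RasterGrid(rng.uniform(0, 1, (10, 10)), 0, 100, 10)
        nir = RasterGrid(rng.uniform(0, 1, (10, 10)), 0, 100, 10)
        out = PR.ndvi(red, nir)
        valid = out.values[out.mask()]
        assert valid.min() >= -1 and valid.max() <= 1


def _step_dem(cell=100.0, size=150, plateau=10.0, plain=0.0):
    """DEM: central 1 km square plateau at `plateau` m, `plain` m elsewhere.

    Grid spans [-7.5, 7.5] km in both axes, enough for a 5-km buffer around
    the central EA.
    """
    vals = np.full((size, size), plain)
    # plateau over x,y in [-500, 500] around the centre
    half = size // 2
    k = int(500 / cell)
    vals[half - k : half + k, half - k : half + k] = plateau
    return RasterGrid(vals, -size / 2 * cell, size / 2 * cell, cell)


def _center_ea():
    f = grid_frame(1, 1)
    f.df["geometry"] = [shapely.box(-500, -500, 500, 500)]
    return f


class TestElevationDiff:
    def test_constant_zero(self):
        f = _center_ea()
        dem = RasterGrid(np.full((150, 150), 42.0), -7500, 7500, 100.0)
        assert PR.elevation_diff(dem, f).iloc[0] == pytest.approx(0.0)

    def test_plateau(self):
        f = _center_ea()
        dem = _step_dem(plateau=10.0, plain=0.0)
        assert PR.elevation_diff(dem, f).iloc[0] == pytest.approx(10.0, abs=0.2)

    def test_antisymmetry(self):
        f = _center_ea()
        up = PR.elevation_diff(_step_dem(plateau=10.0, plain=0.0), f).iloc[0]
        down = PR.elevation_diff(_step_dem(plateau=0.0, plain=10.0), f).iloc[0]
        assert up == pytest.approx(-down, abs=1e-9)

    def test_annulus_excludes_ea_by_default(self):
        # with the EA included, a plateau's contrast is diluted
        f = _center_ea()
        dem = _step_dem(plateau=10.0, plain=0.0)
        excl = PR.elevation_diff(dem, f).iloc[0]
        incl = PR.elevation_diff(dem, f, include_self=True).iloc[0]
        assert excl > incl > 0

    def test_insufficient_coverage_names_ea(self):
        f = _center_ea()
        dem = RasterGrid(np.full((20, 20), 1.0), -1000, 1000, 100.0)
        with pytest.raises(CoverageError, match="G0000"):
            PR.elevation_diff(dem, f)


class TestBuildMatrix:
    def test_default_emits_18_columns(self, small_bundle):
        assert len(small_bundle["X"].columns) == 18

    def test_standardization_contract(self, small_bundle):
        X = small_bundle["X"]
        for c in X.continuous_cols:
            assert X.data[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert X.data[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_transform_round_trip(self, small_bundle, small_cfg):
        import deprivmap.synthetic_data as SD

        X = small_bundle["X"]
        again = PR.build_matrix(
            small_bundle["frame"],
            small_bundle["households"],
            PR.default_category_map(),
            small_bundle["dem"],
            small_bundle["ndvi"],
            standardize=False,
            standardization=X.standardization,
        )
        pd.testing.assert_frame_equal(again.data, X.data)

    def test_unknown_predictor_config_error(self, small_bundle):
        with pytest.raises(ValueError, match="not available"):
            PR.build_matrix(
                small_bundle["frame"],
                small_bundle["households"],
                PR.default_category_map(),
                small_bundle["dem"],
                small_bundle["ndvi"],
                predictor_list=["water_unimproved", "nope"],
            )

    def test_zero_household_eas_flagged_not_imputed(self, small_bundle):
        h = small_bundle["households"]
        drop_ea = small_bundle["frame"].df["ea_id"].iloc[0]
        X = PR.build_matrix(
            small_bundle["frame"],
            h[h["ea_id"] != drop_ea],
            PR.default_category_map(),
            small_bundle["dem"],
            small_bundle["ndvi"],
        )
        assert X.flagged_ea_ids == [drop_ea]
        assert drop_ea not in X.data.index
        assert not X.data.isna().any().any()

    def test_pure_function(self, small_bundle):
        args = (
            small_bundle["frame"],
            small_bundle["households"],
            PR.default_category_map(),
            small_bundle["dem"],
            small_bundle["ndvi"],
        )
        pd.testing.assert_frame_equal(PR.build_matrix(*args).data, PR.build_matrix(*args).data)


class TestCollinearity:
    def test_duplicate_column_flagged(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        rep = PR.collinearity_report(df)
        row = rep[(rep.var_a == "a") & (rep.var_b == "b")].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        assert row.flagged

    def test_negation_flagged(self, rng):
        x = rng.normal(size=50)
        rep = PR.collinearity_report(pd.DataFrame({"a": x, "b": -x}))
        assert rep.iloc[0].pearson_r == pytest.approx(-1.0)
        assert rep.iloc[0].flagged

    def test_independent_columns_small_r(self, rng):
        df = pd.DataFrame(rng.normal(size=(10000, 4)), columns=list("abcd"))
        rep = PR.collinearity_report(df)
        assert (rep.pearson_r.abs() < 0.05).all()
        assert not rep.flagged.any()

    def test_zero_variance_excluded_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20), "c": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = PR.collinearity_report(df)
        assert set(rep.var_a) | set(rep.var_b) == {"a", "c"}

    def test_too_small(self):
        with pytest.raises(ValueError):
            PR.collinearity_report(pd.DataFrame({"a": [1.0, 2.0]}))
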