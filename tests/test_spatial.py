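"""Rasterization, bear-day rarefaction, relative-dominance statistic,
subset maps, ice-year classification and utilization distributions."""

import numpy as np
import pandas as pd
import pytest

from icebear.spatial import (SquareGrid, StateRaster, classify_ice_years,
                             dominant_state, make_grid, rarefy_bear_days,
                             subset_maps, thin_daily,
                             utilization_distribution)


def records_df(rows):
    """rows: (ix, iy, animal, date, state) tuples."""
    return pd.DataFrame(rows, columns=["ix", "iy", "animal_id", "date",
                                       "state"]).assign(
        year=lambda d: pd.DatetimeIndex(d["date"]).year,
        month=lambda d: pd.DatetimeIndex(d["date"]).month)


def decoded_df(xs, ys, states, animal="b1", start="2020-02-01", freq="2h"):
    ts = pd.date_range(start, periods=len(xs), freq=freq)
    return pd.DataFrame({"animal_id": animal, "timestamp": ts,
                         "x_km": xs, "y_km": ys, "state": states})


class TestRarefaction:
    def test_same_state_same_day_collapses_to_one(self):
        d = decoded_df(np.full(12, 10.0), np.full(12, 10.0), np.zeros(12))
        grid = SquareGrid(0.0, 0.0)
        rec = rarefy_bear_days(d, grid)
        assert len(rec) == 1

    def test_two_states_same_day_give_two_records(self):
        states = np.array([0] * 6 + [1] * 6)
        d = decoded_df(np.full(12, 10.0), np.full(12, 10.0), states)
        rec = rarefy_bear_days(d, SquareGrid(0.0, 0.0))
        assert len(rec) == 2

    def test_two_cells_give_two_records(self):
        xs = np.array([10.0] * 6 + [80.0] * 6)  # 50-km cells 0 and 1
        d = decoded_df(xs, np.full(12, 10.0), np.zeros(12))
        rec = rarefy_bear_days(d, SquareGrid(0.0, 0.0))
        assert len(rec) == 2
        assert set(rec["ix"]) == {0, 1}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        d = decoded_df(rng.uniform(0, 500, 300), rng.uniform(0, 500, 300),
                       rng.integers(0, 4, 300))
        grid = make_grid(d)
        once = rarefy_bear_days(d, grid)
        twice = once.drop_duplicates(
            subset=["ix", "iy", "animal_id", "date", "state"])
        assert len(once) == len(twice)


class TestDominantState:
    def hand_raster(self):
        # cell A: (3,1,0,0) bear days; cell B supplies the overall balance
        # so overall proportions are (0.5, 0.25, 0.25, 0) across 8 days
        counts = pd.DataFrame(
            {0: [3, 1], 1: [1, 1], 2: [0, 2], 3: [0, 0]},
            index=pd.MultiIndex.from_tuples([(0, 0), (1, 0)],
                                            names=["ix", "iy"]))
        return StateRaster(counts)

    def test_hand_enumeration(self):
        out = dominant_state(self.hand_raster(), min_days=0, hatch_below=0)
        # cell A: ratios (0.75/0.5, 0.25/0.25, 0, -) = (1.5, 1.0, 0) -> D
        assert out.loc[(out.ix == 0), "dominant_state"].item() == 0

    def test_single_state_dataset_dominated_everywhere(self):
        counts = pd.DataFrame(
            {0: [5, 9], 1: [0, 0], 2: [0, 0], 3: [0, 0]},
            index=pd.MultiIndex.from_tuples([(0, 0), (1, 0)],
                                            names=["ix", "iy"]))
        out = dominant_state(StateRaster(counts), min_days=0, hatch_below=0)
        assert (out["dominant_state"] == 0).all()

    def test_masking_thresholds(self):
        counts = pd.DataFrame(
            {0: [6, 7, 30], 1: [0, 0, 0], 2: [0, 0, 0], 3: [0, 0, 0]},
            index=pd.MultiIndex.from_tuples([(0, 0), (1, 0), (2, 0)],
                                            names=["ix", "iy"]))
        out = dominant_state(StateRaster(counts)).set_index("ix")
        assert not out.loc[0, "plotted"]          # 6 < 7 bear days
        assert out.loc[1, "plotted"] and out.loc[1, "low_confidence"]
        assert out.loc[2, "plotted"] and not out.loc[2, "low_confidence"]

    def test_invariant_to_count_scaling(self):
        r = self.hand_raster()
        scaled = StateRaster(r.counts * 13)
        a = dominant_state(r, min_days=0, hatch_below=0)
        b = dominant_state(scaled, min_days=0, hatch_below=0)
        assert np.array_equal(a["dominant_state"], b["dominant_state"])

    def test_equivariant_under_state_permutation(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 20, (6, 4)),
            index=pd.MultiIndex.from_tuples(
                [(i, 0) for i in range(6)], names=["ix", "iy"]),
            columns=[0, 1, 2, 3])
        perm = [2, 0, 3, 1]
        permuted = counts.copy()
        permuted.columns = [perm[c] for c in counts.columns]
        permuted = permuted[[0, 1, 2, 3]]
        a = dominant_state(StateRaster(counts), 0, 0)["dominant_state"]
        b = dominant_state(StateRaster(permuted), 0, 0)["dominant_state"]
        # compare through the permutation; skip cells where the original
        # argmax was a tie broken by index order
        C = counts.to_numpy()
        ratios = np.where(C.sum(0) > 0, (C / C.sum(1)[:, None])
                          / (C.sum(0) / C.sum()), 0)
        tie = [np.isclose(np.sort(r)[-1], np.sort(r)[-2]) for r in ratios]
        for i in range(6):
            if not tie[i]:
                assert perm[a.iloc[i]] == b.iloc[i]


class TestIceYears:
    def test_two_years(self):
        assert classify_ice_years({2018: 80.0, 2019: 90.0}) == \
            {2018: "low", 2019: "high"}

    def test_all_equal_all_high_by_convention(self):
        out = classify_ice_years({2018: 85.0, 2019: 85.0, 2020: 85.0})
        assert set(out.values()) == {"high"}

    def test_seven_year_split(self):
        # seven synthetic years, four below the across-year mean
        means = {2011: 86.0, 2016: 88.0, 2017: 89.0, 2021: 89.5,
                 2018: 92.0, 2019: 92.5, 2020: 93.0}
        out = classify_ice_years(means)
        assert sum(v == "low" for v in out.values()) == 4
        assert sum(v == "high" for v in out.values()) == 3


class TestSubsetMaps:
    def big_records(self):
        rng = np.random.default_rng(2)
        rows = []
        for b, age in [("b1", 8), ("b2", 12), ("b3", 16), ("b4", 19)]:
            for k in range(60):
                rows.append((int(rng.integers(0, 3)), int(rng.integers(0, 3)),
                             b, pd.Timestamp("2020-01-05")
                             + pd.Timedelta(days=int(rng.integers(0, 150))),
                             int(rng.integers(0, 4))))
        return records_df(rows).drop_duplicates(
            subset=["ix", "iy", "animal_id", "date", "state"])

    def test_season_assignment(self):
        rec = self.big_records()
        maps = subset_maps(rec, "season", min_days=0, hatch_below=0)
        april = rec[pd.DatetimeIndex(rec["date"]).month == 4]
        assert len(april) > 0
        # april records only count toward the late-winter subset
        n_late = maps["late"]["n_days"].sum()
        assert n_late == (rec["month"].between(4, 6)).sum()

    def test_age_split_half_and_half(self):
        rec = self.big_records()
        ages = {"b1": 8, "b2": 12, "b3": 16, "b4": 19}
        maps = subset_maps(rec, "age", ages=ages, min_days=0, hatch_below=0)
        assert maps["younger"] is not None and maps["older"] is not None

    def test_fourteen_bear_roster_split(self):
        ages = {f"b{i:02d}": a for i, a in enumerate(
            [6, 7, 9, 10, 11, 13, 14, 15, 16, 17, 18, 19, 20, 20])}
        rows = [(0, 0, b, pd.Timestamp("2020-02-01"), 0) for b in ages]
        maps = subset_maps(records_df(rows), "age", ages=ages,
                           min_days=0, hatch_below=0)
        # youngest seven (6-14) vs oldest seven (15-20)
        assert maps["younger"]["n_days"].sum() == 7
        assert maps["older"]["n_days"].sum() == 7

    def test_constant_attribute_subset_equals_global(self):
        rec = self.big_records()
        maps = subset_maps(rec, "ice_year",
                           ice_year_labels={2020: "high"},
                           min_days=0, hatch_below=0)
        glob = dominant_state(StateRaster.from_records(rec), 0, 0)
        assert maps["low_ice"] is None
        pd.testing.assert_frame_equal(maps["high_ice"], glob)


class TestUtilizationDistribution:
    def test_area_shrinks_with_level(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 50, (2000, 2))
        a20 = utilization_distribution(pts, level=0.2).area_km2
        a50 = utilization_distribution(pts, level=0.5).area_km2
        a80 = utilization_distribution(pts, level=0.8).area_km2
        assert a20 < a50 <= a80

    def test_gaussian_oracle(self):
        rng = np.random.default_rng(4)
        sigma = 60.0
        pts = rng.normal(0, sigma, (10_000, 2))
        res = utilization_distribution(pts, level=0.8, grid_n=256)
        # isotropic Gaussian: the 80% highest-density region is a disc of
        # radius sigma*sqrt(-2 ln 0.2)
        expect = np.pi * sigma ** 2 * (-2.0 * np.log(0.2))
        assert res.area_km2 == pytest.approx(expect, rel=0.10)
        assert res.polygon.area == pytest.approx(res.area_km2, rel=0.02)

    def test_degenerate_points_rejected(self):
        pts = np.column_stack([np.arange(40.0), 2 * np.arange(40.0)])
        with pytest.raises(ValueError, match="degenerate"):
            utilization_distribution(pts)
        with pytest.raises(ValueError):
            utilization_distribution(np.random.default_rng(0)
                                     .normal(size=(10, 2)))

    def test_daily_thinning(self):
        d = decoded_df(np.arange(48.0), np.zeros(48), np.zeros(48))
        out = thin_daily(d)
        assert len(out) == 4  # 48 fixes x 2h = 4 days


class TestExports:
    def test_ud_geojson_roundtrip(self, tmp_path):
        import json
        from icebear.spatial import save_ud_geojson
        rng = np.random.default_rng(5)
        ud = utilization_distribution(rng.normal(0, 30, (500, 2)), level=0.5)
        path = tmp_path / "ud.geojson"
        save_ud_geojson(ud, path, properties={"subset": "demo"})
        gj = json.loads(path.read_text())
        feat = gj["features"][0]
        assert feat["properties"]["level"] == 0.5
        assert feat["geometry"]["type"] in ("Polygon", "MultiPolygon")
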