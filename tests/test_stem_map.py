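"""Stem-map data model, I/O and census arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestspat import (
    StemMap, Window, basal_area, diameter_distribution, quadrat_statistics,
    read_stem_map, summarize_census, write_stem_map,
)
from forestspat.errors import FormatError, GeometryError, ValidationError


def make_map(rows, window=None):
    df = pd.DataFrame(rows, columns=["tag", "species", "x", "y", "dbh",
                                     "status"])
    return StemMap(window or Window(800, 320), df)


class TestBasalArea:
    def test_closed_form(self):
        assert basal_area(100.0) == pytest.approx(np.pi * 0.25)
        assert basal_area(200.0 / np.sqrt(np.pi)) == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            basal_area(0.0)
        with pytest.raises(ValueError):
            basal_area([-3.0, 10.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.5, max_value=500.0))
    def test_monotone_and_invertible(self, dbh):
        ba = basal_area(dbh)
        assert basal_area(dbh * 1.01) > ba
        assert 200.0 * np.sqrt(ba / np.pi) == pytest.approx(dbh)


class TestIO:
    def test_round_trip_identity(self, tmp_path):
        smap = make_map([("a", "TSHE", 1.0, 2.0, 12.5, "live"),
                         ("b", "PSME", 400.0, 100.0, 110.0, "live"),
                         ("c", "ABAM", 799.0, 319.0, 1.0, "live")])
        path = tmp_path / "stems.csv"
        write_stem_map(smap, path)
        back = read_stem_map(path, smap.window)
        pd.testing.assert_frame_equal(back.stems, smap.stems)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("tag,species,x,y\na,TSHE,1,2\n")
        with pytest.raises(FormatError, match="dbh"):
            read_stem_map(path, Window(800, 320))

    def test_undersized_live_stem_rejected(self):
        with pytest.raises(ValidationError, match="tagging threshold"):
            make_map([("a", "TSHE", 1.0, 2.0, 0.5, "live")])

    def test_out_of_window_names_tag(self):
        with pytest.raises(ValidationError, match="'oops'"):
            make_map([("oops", "TSHE", 805.0, 2.0, 12.0, "live")])

    def test_drop_mode_keeps_diagnostics(self, tmp_path):
        path = tmp_path / "mixed.csv"
        path.write_text("tag,species,x,y,dbh,status\n"
                        "ok,TSHE,1,2,5,live\n"
                        "bad,TSHE,805,2,5,live\n")
        smap = read_stem_map(path, Window(800, 320), on_invalid="drop")
        assert len(smap) == 1
        assert any("bad" in d for d in smap.diagnostics)

    def test_snag_invariants(self):
        with pytest.raises(ValidationError, match="snag"):
            make_map([("s", "PSME", 1.0, 1.0, 5.0, "snag")])


class TestCensus:
    def test_empty_map_is_zero_summary(self):
        smap = StemMap(Window(800, 320), pd.DataFrame())
        summary = summarize_census(smap)
        assert summary.totals.loc["live_woody", "stems_ge1"] == 0
        assert summary.totals.loc["live_woody", "ba_ge1_m2_ha"] == 0.0

    def test_large_proportion_zero_without_large_stems(self):
        smap = make_map([("a", "TSHE", 1, 1, 20, "live"),
                         ("b", "TSHE", 2, 2, 99.9, "live")])
        summary = summarize_census(smap)
        row = summary.species.loc[("live_tree", "TSHE")]
        assert row["large_stem_prop_pct"] == 0.0

    def test_totals_match_brute_force_recount(self, desk_map):
        """Independent filter-and-count oracle over the raw stem table."""
        summary = summarize_census(desk_map)
        s = desk_map.stems
        live = s[s["status"] == "live"]
        area = desk_map.window.area_ha
        for thr, count_col, ba_col in [
                (1, "stems_ge1", "ba_ge1_m2_ha"),
                (10, "stems_ge10", "ba_ge10_m2_ha"),
                (100, "stems_ge100", "ba_ge100_m2_ha")]:
            sel = live[live["dbh"] >= thr]
            assert summary.totals.loc["live_woody", count_col] == len(sel)
            assert summary.totals.loc["live_woody", ba_col] == pytest.approx(
                basal_area(sel["dbh"].to_numpy()).sum() / area)

    def test_totals_equal_sum_of_species_rows(self, desk_map):
        summary = summarize_census(desk_map)
        trees = summary.species.loc["live_tree"]
        assert trees["stems_ge1"].sum() == \
            summary.totals.loc["live_tree", "stems_ge1"]
        assert trees["ba_ge1_m2_ha"].sum() == pytest.approx(
            summary.totals.loc["live_tree", "ba_ge1_m2_ha"], abs=0.01)

    def test_threshold_monotonicity(self, reference_map):
        summary = summarize_census(reference_map)
        sp = summary.species
        assert (sp["stems_ge1"].fillna(np.inf) >= sp["stems_ge10"]).all()
        assert (sp["stems_ge10"] >= sp["stems_ge100"]).all()
        assert (sp["ba_ge10_m2_ha"] >= sp["ba_ge100_m2_ha"] - 1e-12).all()

    def test_trace_rendering(self):
        smap = make_map([("a", "ACGL", 1, 1, 2.0, "live")])
        formatted = summarize_census(smap).formatted()
        row = formatted[(formatted["population"] == "live_tree")
                        & (formatted["species"] == "ACGL")]
        assert row["density_per_ha"].iloc[0] == "t"


class TestDiameterDistribution:
    def test_half_open_boundaries(self):
        smap = make_map([("a", "X", 1, 1, 1.0, "live"),
                         ("b", "X", 2, 2, 4.9, "live"),
                         ("c", "X", 3, 3, 5.0, "live")])
        hist = diameter_distribution(smap, "X", bin_width=5)
        assert hist.counts[0] == 2
        assert hist.counts[1] == 1

    def test_counts_and_ba_conserved(self, desk_map):
        hist = diameter_distribution(desk_map, "TSHE")
        sub = desk_map.stems[desk_map.stems["species"] == "TSHE"]
        assert hist.counts.sum() == len(sub)
        assert hist.basal_area_m2.sum() == pytest.approx(
            basal_area(sub["dbh"].to_numpy()).sum())

    def test_unknown_species(self, desk_map):
        with pytest.raises(KeyError):
            diameter_distribution(desk_map, "NOPE")

    def test_negative_exponential_species_decreasing(self, desk_map):
        """Generator property: exponential diameter models yield
        monotone-decreasing counts in the leading bins."""
        hist = diameter_distribution(desk_map, "ABAM", bin_width=5)
        lead = hist.counts[:5].astype(float)
        # steep exponential decay dominates sampling noise
        assert lead[0] > lead[2] > lead[4]
        assert lead[1] > lead[3]


class TestQuadrats:
    def test_corner_convention(self):
        smap = make_map([("a", "X", 0.0, 0.0, 10.0, "live")])
        grid = quadrat_statistics(smap, 400.0)
        assert grid.counts[0, 0] == 1
        assert grid.counts.sum() == 1

    def test_far_edge_clamped(self):
        smap = make_map([("a", "X", 800.0, 320.0, 10.0, "live")])
        grid = quadrat_statistics(smap, 400.0)
        assert grid.counts[-1, -1] == 1

    def test_conservation(self, desk_map):
        total = basal_area(desk_map.stems["dbh"].to_numpy()).sum()
        for grain in (100.0, 400.0, 1600.0, 6400.0):
            grid = quadrat_statistics(desk_map, grain)
            assert grid.counts.sum() == len(desk_map)
            assert grid.basal_area_m2.sum() == pytest.approx(total)

    def test_nested_grains_aggregate(self, desk_map):
        fine = quadrat_statistics(desk_map, 400.0).basal_area_m2
        coarse = quadrat_statistics(desk_map, 1600.0).basal_area_m2
        agg = fine.reshape(fine.shape[0] // 2, 2,
                           fine.shape[1] // 2, 2).sum(axis=(1, 3))
        np.testing.assert_allclose(agg, coarse, rtol=1e-12)

    def test_non_tiling_grain(self, desk_map):
        with pytest.raises(GeometryError):
            quadrat_statistics(desk_map, 300.0)

    def test_large_trees_add_heterogeneity(self, desk_map):
        """Quadrat-BA CV with the large trees exceeds the CV without them."""
        all_grid = quadrat_statistics(desk_map, 400.0,
                                      lambda df: df["status"] == "live")
        small_grid = quadrat_statistics(
            desk_map, 400.0,
            lambda df: (df["status"] == "live") & (df["dbh"] < 100))
        def cv(v):
            return v.std(ddof=1) / v.mean()
        assert cv(all_grid.basal_area_m2.ravel()) > \
            cv(small_grid.basal_area_m2.ravel())

    def test_percentile_table_shape(self, desk_map):
        table = quadrat_statistics(desk_map, 400.0).percentiles()
        assert list(table.index) == [5, 25, 50, 75, 95]
        assert table["basal_area_m2_ha"].is_monotonic_increasing
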