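"""Quadrat heterogeneity statistics and the permutation experiment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestspat import (
    StemMap, Window, cv_skewness, empirical_departure, run_experiment,
    split_by_diameter,
)
from forestspat.errors import ValidationError


def tiny_map(n_small=60, n_large=8, seed=0, dbh_scale=1.0):
    rng = np.random.default_rng(seed)
    window = Window(400.0, 160.0)
    n = n_small + n_large
    df = pd.DataFrame({
        "tag": [f"t{i}" for i in range(n)],
        "species": "X",
        "x": rng.random(n) * 400,
        "y": rng.random(n) * 160,
        "dbh": np.r_[rng.uniform(5, 45, n_small),
                     rng.uniform(105, 160, n_large)] * dbh_scale,
        "status": "live",
    })
    return StemMap(window, df)


class TestSplit:
    def test_threshold_inclusive(self):
        smap = tiny_map()
        smap.stems.loc[0, "dbh"] = 100.0
        large, small = split_by_diameter(smap)
        assert "t0" in set(large.stems["tag"])

    def test_partition_is_exhaustive(self):
        smap = tiny_map()
        large, small = split_by_diameter(smap)
        assert len(large) + len(small) == len(smap.live_trees)
        assert set(large.stems["tag"]).isdisjoint(small.stems["tag"])

    def test_excludes_snags_and_shrubs(self):
        smap = tiny_map()
        df = smap.stems.copy()
        df.loc[0, ["status", "dbh", "snag_height"]] = ["snag", 120.0, 20.0]
        df.loc[1, "growth_form"] = "tall_shrub"
        smap2 = StemMap(smap.window, df)
        large, small = split_by_diameter(smap2)
        assert len(large) + len(small) == len(smap2.live_trees)


class TestCvSkewness:
    def test_constant_values(self):
        cv, sk = cv_skewness([1.0, 1.0, 1.0])
        assert cv == 0.0 and sk == 0.0

    def test_hand_computed_moments(self):
        cv, sk = cv_skewness([0.0, 0.0, 3.0])
        assert cv == pytest.approx(np.sqrt(3))
        assert sk == pytest.approx(2 ** -0.5)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cv_skewness([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            cv_skewness([1.0, 2.0])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=4,
                    max_size=30),
           st.floats(min_value=0.5, max_value=50.0))
    def test_shift_reduces_cv_scale_leaves_both(self, values, shift):
        values = np.asarray(values)
        if values.sum() == 0 or values.std() == 0:
            return
        cv0, sk0 = cv_skewness(values)
        cv1, sk1 = cv_skewness(values + shift)
        assert cv1 < cv0
        cv2, sk2 = cv_skewness(values * 3.0)
        assert cv2 == pytest.approx(cv0)
        assert sk2 == pytest.approx(sk0)


class TestExperiment:
    def test_table_shape(self):
        table = run_experiment(tiny_map(), n_real=3, seed=1)
        assert len(table) == 7 * 4 * 3 + 4
        assert table["is_empirical"].sum() == 4
        assert set(table.columns) >= {"level", "grain_m2", "realization",
                                      "cv", "skewness", "is_empirical"}

    def test_no_large_trees_refused(self):
        table_map = tiny_map(n_large=0)
        with pytest.raises(ValidationError):
            run_experiment(table_map, n_real=2, seed=1)

    def test_deterministic(self):
        a = run_experiment(tiny_map(), n_real=4, seed=9)
        b = run_experiment(tiny_map(), n_real=4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_dbh_doubling_leaves_cv_and_skewness(self):
        """Quadrat basal areas scale by 4 when every dbh doubles; CV and
        skewness are scale-free."""
        a = run_experiment(tiny_map(dbh_scale=1.0), n_real=3, seed=5)
        b = run_experiment(tiny_map(dbh_scale=2.0), n_real=3, seed=5)
        np.testing.assert_allclose(a["cv"], b["cv"], rtol=1e-9)
        np.testing.assert_allclose(a["skewness"], b["skewness"], rtol=1e-9)

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError):
            run_experiment(tiny_map(), levels=["nope"], n_real=2, seed=1)

    def test_basal_area_conservation(self):
        """Permutations move trees, never resize them: the quadrat sums
        reconstructed from any level equal the map total."""
        from forestspat.heterogeneity import _quadrat_ba
        from forestspat.simulators import simulate_level
        smap = tiny_map()
        large, small = split_by_diameter(smap)
        ba_l = np.pi * (large.stems["dbh"].to_numpy() / 200.0) ** 2
        ba_s = np.pi * (small.stems["dbh"].to_numpy() / 200.0) ** 2
        total = ba_l.sum() + ba_s.sum()
        for lvl in ("ssi-10", "random", "matern-15"):
            pat = simulate_level(lvl, len(large), smap.window, seed=3)
            q = _quadrat_ba(pat.points, ba_l, smap.window, [400.0])[400.0] \
                + _quadrat_ba(small.points(), ba_s, smap.window,
                              [400.0])[400.0]
            assert q.sum() == pytest.approx(total, rel=1e-12)

    def test_paired_and_unpaired_agree_in_distribution(self):
        """The paired design changes only the coupling, not the marginal
        means (checked loosely on the CSR level)."""
        smap = tiny_map(n_small=200, n_large=20, seed=3)
        a = run_experiment(smap, levels=["random"], n_real=60,
                           grains=[400.0], seed=11, paired=True)
        b = run_experiment(smap, levels=["random"], n_real=60,
                           grains=[400.0], seed=12, paired=False)
        ma = a[~a.is_empirical]["cv"].mean()
        mb = b[~b.is_empirical]["cv"].mean()
        pooled_se = np.hypot(a[~a.is_empirical]["cv"].std(),
                             b[~b.is_empirical]["cv"].std()) / np.sqrt(60)
        assert abs(ma - mb) < 4 * pooled_se


class TestDeparture:
    def test_single_grain_single_row(self):
        table = run_experiment(tiny_map(), levels=["random"], n_real=10,
                               grains=[400.0], seed=2)
        dep = empirical_departure(table)
        assert len(dep) == 1
        assert {"empirical_cv", "cv_percentile",
                "skewness_percentile"} <= set(dep.columns)

    def test_missing_level(self):
        table = run_experiment(tiny_map(), levels=["ssi-10"], n_real=3,
                               grains=[400.0], seed=2)
        with pytest.raises(KeyError):
            empirical_departure(table, level="random")

    def test_csr_map_is_typical_under_csr_null(self):
        """A map whose large trees are CSR sits well inside the CSR
        realization distribution (percentile not extreme) in most seeds."""
        hits = 0
        for s in range(10):
            smap = tiny_map(n_small=200, n_large=25, seed=100 + s)
            table = run_experiment(smap, levels=["random"], n_real=79,
                                   grains=[1600.0], seed=s)
            dep = empirical_departure(table)
            pct = dep["cv_percentile"].iloc[0]
            hits += (2.5 <= pct <= 97.5)
        assert hits >= 8
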