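import numpy as np
import pandas as pd
import pytest

from sarmap.distances import DistanceMatrix
from sarmap.sac import (SACSeries, build_sac_series, classify_series,
                        exclusion_filter, run_sac_analysis,
                        sac_raw_percentage, scale_series,
                        shared_activity_stats)

from conftest import make_calls


def series_from_xy(x, y, target="t", scaled=True):
    pts = pd.DataFrame({
        "variable_target": [f"v{i}" for i in range(len(x))],
        "raw_percentage": y, "raw_distance": x,
    })
    if scaled:
        pts["scaled_distance"] = x
        pts["scaled_sac_score"] = y
    return SACSeries(target, "variable", pts, scaled=scaled)


def uniform_dm(targets, value=0.5):
    n = len(targets)
    values = np.full((n, n), value)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(tuple(targets), values, "test")


class TestSharedActivityStats:
    def test_concentrations_counted_separately(self):
        # K1 active on c1@1 and c1@10; K2 active on c1@10 only
        calls = make_calls([[True, True, False, False],
                            [False, True, False, False]],
                           targets=["K1", "K2"], compounds=["c1", "c2"])
        stats = shared_activity_stats(calls)
        assert stats.shared_counts.loc["K1", "K2"] == 1
        assert stats.shared_total["K1"] == 1
        assert stats.total_active["K1"] == 2

    def test_zero_active_target_all_zero_stats(self):
        calls = make_calls([[False, False], [True, True]],
                           targets=["dead", "live"], compounds=["c1"])
        stats = shared_activity_stats(calls)
        assert stats.total_active["dead"] == 0
        assert stats.shared_total["dead"] == 0
        assert stats.mean_partners["dead"] == 0.0

    def test_pairwise_counts_match_enumeration(self):
        rng = np.random.default_rng(8)
        grid = rng.random((3, 10)) < 0.5
        calls = make_calls(grid, compounds=[f"c{i}" for i in range(5)])
        stats = shared_activity_stats(calls)
        for i, a in enumerate(calls.target_ids):
            for j, b in enumerate(calls.target_ids):
                if i == j:
                    continue
                expected = int((grid[i] & grid[j]).sum())
                assert stats.shared_counts.loc[a, b] == expected
            shared = {k for k in range(10)
                      if grid[i, k] and grid[:, k].sum() >= 2}
            assert stats.shared_total[calls.target_ids[i]] == len(shared)


class TestRawPercentage:
    @pytest.fixture()
    def stats(self):
        # common actives {c1,c2,c3}; variable actives {c2,c3,c4,c5}
        calls = make_calls(
            [[True, True, True, False, False, False],
             [False, True, True, True, True, False]],
            targets=["common", "variable"],
            compounds=[f"c{i}" for i in range(1, 7)], concentrations=(1.0,))
        return shared_activity_stats(calls)

    def test_three_modes_hand_counts(self, stats):
        assert sac_raw_percentage("common", "variable", stats, "common") == \
            pytest.approx(200 / 3)
        assert sac_raw_percentage("common", "variable", stats, "variable") == 50.0
        assert sac_raw_percentage("common", "variable", stats, "both") == 40.0

    def test_identical_sets_100_every_mode(self):
        calls = make_calls([[True, True], [True, True]],
                           targets=["a", "b"], compounds=["c1"])
        stats = shared_activity_stats(calls)
        for mode in ("common", "variable", "both"):
            assert sac_raw_percentage("a", "b", stats, mode) == 100.0

    def test_disjoint_sets_0_every_mode(self):
        calls = make_calls([[True, False], [False, True]],
                           targets=["a", "b"], compounds=["c1"],
                           concentrations=(1.0, 10.0))
        stats = shared_activity_stats(calls)
        for mode in ("common", "variable", "both"):
            assert sac_raw_percentage("a", "b", stats, mode) == 0.0

    def test_zero_denominator_returns_none(self):
        calls = make_calls([[True, False], [False, False]],
                           targets=["a", "dead"], compounds=["c1"])
        stats = shared_activity_stats(calls)
        assert sac_raw_percentage("a", "dead", stats, "variable") is None


class TestBuildSeries:
    def test_cardinality_and_symmetry(self):
        rng = np.random.default_rng(2)
        grid = rng.random((4, 12)) < 0.6
        calls = make_calls(grid, compounds=[f"c{i}" for i in range(6)])
        stats = shared_activity_stats(calls)
        values = rng.uniform(0.1, 1.0, (4, 4))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        d = DistanceMatrix(tuple(calls.target_ids), values, "t")
        s = build_sac_series("T0", stats, d, "variable")
        assert len(s) == 3
        got = dict(zip(s.points["variable_target"], s.points["raw_distance"]))
        for v, dist in got.items():
            assert dist == d.loc(v, "T0")  # pulled symmetric

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(13)
        grid = rng.random((5, 16)) < 0.5
        calls = make_calls(grid, compounds=[f"c{i}" for i in range(8)])
        stats = shared_activity_stats(calls)
        d = uniform_dm(calls.target_ids)
        s = build_sac_series("T2", stats, d, "variable")
        for _, row in s.points.iterrows():
            vi = calls.target_ids.index(row["variable_target"])
            shared = int((grid[2] & grid[vi]).sum())
            assert row["raw_percentage"] == pytest.approx(
                100 * shared / grid[vi].sum())

    def test_zero_active_common_hard_error(self):
        calls = make_calls([[False, False], [True, True]],
                           targets=["dead", "live"], compounds=["c1"])
        stats = shared_activity_stats(calls)
        with pytest.raises(ValueError, match="no active"):
            build_sac_series("dead", stats, uniform_dm(["dead", "live"]),
                             "variable")


class TestScaleSeries:
    def test_rescales_to_stated_means(self):
        s = scale_series(series_from_xy([0.2, 0.4, 0.6], [20, 40, 60],
                                        scaled=False))
        np.testing.assert_allclose(s.points["scaled_sac_score"], [25, 50, 75])
        np.testing.assert_allclose(s.points["scaled_distance"],
                                   [0.25, 0.5, 0.75])
        assert s.points["scaled_sac_score"].mean() == pytest.approx(50)
        assert s.points["scaled_distance"].mean() == pytest.approx(0.5)

    def test_five_times_mean_gives_sac_250(self):
        # a raw percentage 5x its series mean scales to SAC score 250
        y = [50.0, 2.0, 2.0, 2.0, 2.0, 2.0]  # mean 10, first point 5x mean
        x = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        s = scale_series(series_from_xy(x, y, scaled=False))
        assert s.points["scaled_sac_score"].iloc[0] == pytest.approx(250.0)

    def test_idempotent_on_scaled_series(self):
        s1 = scale_series(series_from_xy([0.2, 0.4], [20, 60], scaled=False))
        s2 = scale_series(s1)
        np.testing.assert_allclose(s2.points["scaled_sac_score"],
                                   s1.points["scaled_sac_score"])

    def test_zero_mean_hard_error(self):
        with pytest.raises(ValueError, match="non-positive mean"):
            scale_series(series_from_xy([0.1, 0.2], [0.0, 0.0], scaled=False))


class TestClassify:
    def test_exact_linear_decrease_is_neighborhood(self):
        x = np.linspace(0, 1.9, 50)
        call = classify_series(series_from_xy(x, 100 - 50 * x))
        assert call.verdict == "neighborhood"
        assert call.slope_at_040 == pytest.approx(-50, abs=1e-6)
        assert call.slope_at_067 == pytest.approx(-50, abs=1e-6)
        assert call.r_squared == pytest.approx(1.0)

    def test_flat_series_is_outlier(self):
        x = np.linspace(0, 1.9, 30)
        call = classify_series(series_from_xy(x, np.full(30, 50.0)))
        assert call.verdict == "outlier"

    def test_too_few_points_is_outlier_with_reason(self):
        call = classify_series(series_from_xy([0.1, 0.9], [80, 20]))
        assert call.verdict == "outlier"
        assert "3 points" in call.reason

    def test_degenerate_x_is_outlier_with_reason(self):
        call = classify_series(series_from_xy([0.5] * 5, [1, 2, 3, 4, 5]))
        assert call.verdict == "outlier"
        assert "degenerate" in call.reason

    def test_noise_rarely_clears_r_squared_threshold(self):
        # i.i.d. noise, n=200: quadratic fit R^2 stays below 0.2
        rng = np.random.default_rng(99)
        outlier = 0
        reps = 100
        for _ in range(reps):
            x = rng.uniform(0, 1.9, 200)
            y = rng.uniform(0, 100, 200)
            if classify_series(series_from_xy(x, y)).verdict == "outlier":
                outlier += 1
        assert outlier >= 0.9 * reps

    def test_verdict_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.05, 1.0, 40)
        y = 90 - 60 * x + rng.normal(0, 5, 40)
        base = classify_series(scale_series(series_from_xy(x, y, scaled=False)))
        scaled = classify_series(scale_series(
            series_from_xy(3.7 * x, 0.2 * y, scaled=False)))
        assert base.verdict == scaled.verdict


class TestExclusionFilter:
    def _stats(self, shared_totals):
        targets = list(shared_totals)
        n = max(shared_totals.values()) + 1
        return type("S", (), {
            "target_ids": targets,
            "shared_total": pd.Series(shared_totals),
        })()

    def test_boundary_16_excluded_17_kept(self):
        stats = self._stats({"a": 16, "b": 17})
        kept, excluded = exclusion_filter(stats, 16)
        assert excluded == ["a"] and kept == ["b"]

    def test_zero_active_always_excluded(self):
        stats = self._stats({"dead": 0, "live": 20})
        _, excluded = exclusion_filter(stats, 16)
        assert "dead" in excluded

    def test_threshold_zero_drops_only_zero_shared(self):
        stats = self._stats({"a": 0, "b": 1})
        kept, excluded = exclusion_filter(stats, 0)
        assert excluded == ["a"] and kept == ["b"]

    def test_monotone_in_threshold(self):
        stats = self._stats({"a": 3, "b": 10, "c": 25})
        kept_sizes = [len(exclusion_filter(stats, t)[0]) for t in (0, 5, 16, 30)]
        assert kept_sizes == sorted(kept_sizes, reverse=True)


class TestRunAnalysis:
    def test_planted_monotone_structure_high_neighborhood_fraction(self):
        # sliding-window actives: overlap (and SAC%) decays linearly with
        # index separation, distances proportional to separation
        n_t, width, step, n_i = 12, 40, 4, 200
        grid = np.zeros((n_t, n_i), dtype=bool)
        for i in range(n_t):
            grid[i, i * step: i * step + width] = True
        calls = make_calls(grid, compounds=[f"c{i}" for i in range(n_i // 2)])
        idx = np.arange(n_t)
        values = np.abs(idx[:, None] - idx[None, :]) / n_t
        d = DistanceMatrix(tuple(calls.target_ids), values.astype(float), "sep")
        analysis = run_sac_analysis(calls, d, "variable")
        assert analysis.neighborhood_fraction >= 0.9

    def test_disjoint_target_is_outlier(self):
        grid = np.zeros((5, 40), dtype=bool)
        grid[0, :8] = True           # loner: actives shared with nobody
        for i in range(1, 5):
            grid[i, 10:30] = True
        calls = make_calls(grid, compounds=[f"c{i}" for i in range(20)])
        rng = np.random.default_rng(6)
        values = rng.uniform(0.2, 1.0, (5, 5))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        d = DistanceMatrix(tuple(calls.target_ids), values, "t")
        analysis = run_sac_analysis(calls, d, "variable")
        assert "T0" in analysis.outliers

    def test_zero_active_target_never_yields_series(self, default_panel,
                                                    default_calls):
        from sarmap.distances import tanimoto_distance_matrix
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = tanimoto_distance_matrix(default_calls)
            analysis = run_sac_analysis(default_calls, d, "variable")
        dead = default_panel.truth["zero_active_target"]
        assert dead in analysis.zero_active
        assert dead not in set(analysis.calls_table["target_id"])
        assert analysis.n_series == len(default_calls.target_ids) - 1

    def test_variable_fraction_at_least_common(self, default_panel,
                                               default_calls):
        from sarmap.chem_features import build_vocabulary
        from sarmap.distances import enrichment_distance_matrix
        from sarmap.enrichment import enrichment_matrix

        profiles = enrichment_matrix(default_calls, default_panel.features)
        d = enrichment_distance_matrix(profiles)
        f_var = run_sac_analysis(default_calls, d, "variable")
        f_com = run_sac_analysis(default_calls, d, "common")
        assert f_var.neighborhood_fraction >= f_com.neighborhood_fraction
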