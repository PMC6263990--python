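"""Error metrics, county aggregation, model ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ndviyield.evaluation import (MetricSet, aggregate_production, metrics,
                                  rank_models, relative_error)
from ndviyield.yield_model import NODATA


class TestMetrics:
    def test_identity_comparison(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0
        assert m.re == 0.0
        assert m.r2 == pytest.approx(1.0)

    def test_relative_error_normalised_by_estimate(self):
        # |P - S| / P: the estimate is the denominator as printed
        assert relative_error([10.0], [8.0]) == pytest.approx(25.0)
        m = metrics([10.0, 10.2, 9.8], [8.0, 8.1, 7.9])
        assert m.re == pytest.approx(relative_error([10.0, 10.2, 9.8],
                                                    [8.0, 8.1, 7.9]))

    def test_relative_error_observed_denominator_switch(self):
        assert relative_error([10.0], [8.0], denominator="observed") == \
            pytest.approx(20.0)

    def test_adjusted_r2_hand_value(self):
        # construct N = 11 vectors with exactly R^2 = 0.5: S = s, P = s + u
        # with s, u zero-mean, orthogonal, equal norm -> corr^2 = 1/2;
        # then adjusted R^2 = 1 - 0.5 * 10/9 = 0.4444
        rng = np.random.default_rng(0)
        ones = np.ones(11)
        s = rng.normal(size=11)
        s -= s.mean()
        u = rng.normal(size=11)
        u -= u.mean()
        u -= (u @ s) / (s @ s) * s
        u *= np.linalg.norm(s) / np.linalg.norm(u)
        m = metrics(10.0 * ones + s, 10.0 * ones + s + u, p=1)
        assert m.r2 == pytest.approx(0.5, abs=1e-12)
        assert m.adj_r2 == pytest.approx(1.0 - 0.5 * 10.0 / 9.0, abs=1e-12)
        assert m.adj_r2 == pytest.approx(0.4444, abs=1e-4)

    def test_rmse_hand_value(self):
        # errors 3, 4, 0 -> sqrt((9 + 16 + 0)/3)
        m = metrics([1.0, 1.0, 2.0], [4.0, 5.0, 2.0])
        assert m.rmse == pytest.approx(np.sqrt(25.0 / 3.0))

    def test_zero_estimate_rejected_for_re(self):
        with pytest.raises(ValueError, match="zero denominator"):
            metrics([1.0, 2.0], [0.0, 2.0])

    def test_zero_variance_rejected_for_r2(self):
        with pytest.raises(ValueError, match="zero-variance"):
            metrics([1.0, 1.0], [1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0], [2.0])

    @given(arrays(np.float64, 12, elements=st.floats(0.5, 50)),
           arrays(np.float64, 12, elements=st.floats(0.5, 50)))
    @settings(max_examples=100, deadline=None)
    def test_r2_symmetric_in_arguments(self, S, P):
        if S.std() == 0 or P.std() == 0:
            return
        assert metrics(S, P).r2 == pytest.approx(metrics(P, S).r2, rel=1e-9)

    def test_adjusted_r2_approaches_r2_for_large_n(self):
        rng = np.random.default_rng(4)
        gaps = []
        for n in (10**2, 10**4, 10**6):
            S = rng.normal(10.0, 2.0, n)
            P = S + rng.normal(0.0, 1.0, n)
            m = metrics(S, P, p=1)
            gaps.append(abs(m.adj_r2 - m.r2))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-6

    def test_rmse_invariant_under_pair_permutation(self):
        rng = np.random.default_rng(9)
        S, P = rng.normal(10, 2, 30), rng.normal(10, 2, 30)
        perm = rng.permutation(30)
        assert metrics(S, P).rmse == pytest.approx(metrics(S[perm], P[perm]).rmse)


class TestAggregation:
    def test_uniform_yield_arithmetic(self):
        ymap = np.full((10, 10), 10.0)
        mask = np.ones((10, 10), dtype=int)
        county = np.ones((10, 10), dtype=int)
        df = aggregate_production(ymap, mask, county, pixel_area_ha=0.09)
        assert len(df) == 1
        assert df.iloc[0]["production_t"] == pytest.approx(90.0)
        assert df.iloc[0]["mean_yield_t_ha"] == pytest.approx(10.0)

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(2)
        ymap = rng.uniform(5, 15, (12, 12))
        mask = rng.integers(0, 3, (12, 12))
        ymap[mask == 0] = NODATA
        county_one = np.ones((12, 12), dtype=int)
        county_two = np.repeat([1, 2], 6)[None, :] * np.ones((12, 1), dtype=int)
        total_one = aggregate_production(ymap, mask, county_one, 0.09)
        total_two = aggregate_production(ymap, mask, county_two, 0.09)
        for crop in total_one["crop"]:
            a = total_one.query("crop == @crop")["production_t"].sum()
            b = total_two.query("crop == @crop")["production_t"].sum()
            assert a == pytest.approx(b, rel=1e-12)

    def test_refining_counties_conserves_production(self):
        rng = np.random.default_rng(3)
        ymap = rng.uniform(5, 15, (16, 16))
        mask = np.ones((16, 16), dtype=int)
        coarse = np.repeat([1, 2], 8)[:, None] * np.ones((1, 16), dtype=int)
        fine = coarse * 10 + (np.arange(16) // 4)[None, :]
        a = aggregate_production(ymap, mask, coarse, 0.09)["production_t"].sum()
        b = aggregate_production(ymap, mask, fine, 0.09)["production_t"].sum()
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_scene_truth_table(self, small_scene):
        df = aggregate_production(small_scene.true_yield_map(),
                                  small_scene.crop_mask, small_scene.county_map,
                                  small_scene.config.pixel_area_ha,
                                  crop_labels={1: "maize", 2: "sunflower"})
        merged = df.merge(small_scene.county_truth, on=["county", "crop"],
                          suffixes=("_agg", "_true"))
        assert len(merged) == len(small_scene.county_truth)
        np.testing.assert_allclose(merged["production_t_agg"],
                                   merged["production_t_true"], rtol=1e-6)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            aggregate_production(np.zeros((3, 3)), np.zeros((3, 3), dtype=int),
                                 np.zeros((4, 4), dtype=int), 0.09)


class TestRanking:
    @staticmethod
    def ms(rmse, re):
        return MetricSet(rmse=rmse, re=re, r2=0.5, adj_r2=0.4, n=4, p=1)

    def test_lower_mean_rmse_ranks_first(self):
        ranked = rank_models({1: [self.ms(0.80, 5.0)], 2: [self.ms(0.75, 9.0)]})
        assert list(ranked["model_id"]) == [2, 1]
        assert list(ranked["rank"]) == [1, 2]

    def test_re_breaks_rmse_ties(self):
        ranked = rank_models({1: [self.ms(0.75, 7.0)], 2: [self.ms(0.75, 6.1)]})
        assert list(ranked["model_id"]) == [2, 1]

    def test_multi_year_averaging(self):
        ranked = rank_models({
            5: [self.ms(0.70, 6.0), self.ms(0.80, 6.2)],
            7: [self.ms(0.60, 5.0), self.ms(1.20, 9.0)],
        })
        assert ranked.iloc[0]["model_id"] == 5
        assert ranked.iloc[0]["mean_rmse"] == pytest.approx(0.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_models({})
        with pytest.raises(ValueError):
            rank_models({1: []})
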