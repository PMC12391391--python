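"""Expression scaling, ratio-model regression, flagging, cohort shifts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gwlpheno import synth
from gwlpheno.biomarker import (RatioModel, cohort_median_shift, correlate,
                                fit_ratio_model, predict_ed50, rank_and_flag,
                                scale_expression)

# the published sensitivity model: *ED50 = 0.399 x GWL/B55α + 0.406 (µM)
PUBLISHED = RatioModel(gradient=0.399, intercept=0.406, r_squared=0.81,
                       pearson_r=0.9, p=6.45e-5, n=12)


class TestScaleExpression:
    def test_loading_control_then_max_scaling(self):
        raw = pd.DataFrame({"gwl": [2.0, 4.0, 8.0]})
        out = scale_expression(raw, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(out["gwl"], [0.25, 0.5, 1.0])

    def test_every_scaled_analyte_peaks_at_one(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 100, (6, 3)), columns=list("abc"))
        out = scale_expression(raw, rng.uniform(0.5, 2, 6))
        np.testing.assert_allclose(out.max(), 1.0)

    def test_global_factor_invariance(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 10, (5, 2)), columns=["x", "y"])
        ctrl = rng.uniform(0.5, 2, 5)
        pd.testing.assert_frame_equal(scale_expression(raw, ctrl),
                                      scale_expression(raw * 7.3, ctrl))

    def test_zero_loading_control_rejected(self):
        with pytest.raises(ValueError):
            scale_expression(pd.DataFrame({"a": [1.0]}), [0.0])


class TestRatioModel:
    def test_noiseless_fit_is_exact(self):
        panel, _ = synth.gen_expression_panel(10, 0.5, 0.1, 0.0, seed=1)
        m = fit_ratio_model(panel)
        assert m.gradient == pytest.approx(0.5, rel=1e-9)
        assert m.intercept == pytest.approx(0.1, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0.2, 3, 15)
        y = rng.normal(0.4 * x + 0.3, 0.2)
        panel = pd.DataFrame({"gwl": x, "b55a": np.ones(15), "ed50_um": y})
        m = fit_ratio_model(panel)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert m.gradient == pytest.approx(sxy / sxx)
        assert m.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean())
        assert m.r_squared == pytest.approx(m.pearson_r**2)

    def test_recovery_over_200_seeds_is_unbiased(self):
        """Panels simulated from the published model: mean fitted
        coefficients land on the generative values."""
        grads, inters = [], []
        for seed in range(200):
            panel, _ = synth.gen_expression_panel(12, 0.399, 0.406, 0.05,
                                                  seed=seed)
            m = fit_ratio_model(panel)
            grads.append(m.gradient)
            inters.append(m.intercept)
        assert np.mean(grads) == pytest.approx(0.399, abs=3 * np.std(grads) / np.sqrt(200))
        assert np.mean(inters) == pytest.approx(0.406, abs=3 * np.std(inters) / np.sqrt(200))

    def test_zero_variance_predictor_rejected(self):
        panel = pd.DataFrame({"gwl": [1, 1, 1.0], "b55a": [1, 1, 1.0],
                              "ed50_um": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            fit_ratio_model(panel)


class TestPrediction:
    def test_published_model_hand_evaluation(self):
        panel = pd.DataFrame({"gwl": [0.5], "b55a": [1.0]})
        assert predict_ed50(PUBLISHED, panel).iloc[0] == pytest.approx(0.6055)

    def test_ratio_one_gives_gradient_plus_intercept(self):
        panel = pd.DataFrame({"gwl": [0.7], "b55a": [0.7]})
        assert predict_ed50(PUBLISHED, panel).iloc[0] == pytest.approx(0.399 + 0.406)

    def test_zero_gradient_predicts_intercept(self):
        m = RatioModel(0.0, 0.77, 0, 0, 1, 5)
        panel = pd.DataFrame({"gwl": [0.2, 0.9], "b55a": [0.5, 0.4]})
        np.testing.assert_allclose(predict_ed50(m, panel), 0.77)

    def test_zero_b55a_flagged_as_nan(self):
        panel = pd.DataFrame({"gwl": [0.5, 0.5], "b55a": [1.0, 0.0]})
        pred = predict_ed50(PUBLISHED, panel)
        assert np.isnan(pred.iloc[1]) and not np.isnan(pred.iloc[0])

    def test_predict_after_noiseless_fit_is_identity(self):
        panel, _ = synth.gen_expression_panel(10, 0.5, 0.1, 0.0, seed=2)
        m = fit_ratio_model(panel)
        np.testing.assert_allclose(predict_ed50(m, panel), panel["ed50_um"],
                                   rtol=1e-9)


class TestRankAndFlag:
    def test_exact_count(self, rng):
        pred = pd.Series(rng.uniform(0, 2, 100))
        assert rank_and_flag(pred, 0.05).sum() == 5

    def test_flags_are_the_smallest(self, rng):
        pred = pd.Series(rng.uniform(0, 2, 60))
        flags = rank_and_flag(pred, 0.1)
        k = flags.sum()
        assert set(pred[flags]) == set(pred.nsmallest(k))

    # integer grid keeps values separated beyond float resolution under log
    @given(st.lists(st.integers(1, 100_000), min_size=5, max_size=50,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_monotone_transform(self, values):
        pred = pd.Series([v / 1000 for v in values])
        f1 = rank_and_flag(pred, 0.2)
        f2 = rank_and_flag(np.log(pred), 0.2)
        pd.testing.assert_series_equal(f1, f2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_and_flag(pd.Series(dtype=float), 0.05)


class TestCohort:
    def test_null_groups_not_significant(self):
        table, _ = synth.gen_cohort_expression(
            [("A", 40, 40), ("B", 40, 40)], seed=8)
        res = cohort_median_shift(table)
        assert (res["status"] == "tested").all()
        assert (res["p_adj"] > 0.05).all()
        assert np.allclose(res["median_shift"].abs(), 0, atol=15)

    def test_generative_shift_detected(self):
        table, _ = synth.gen_cohort_expression(
            [("A", 60, 60), ("B", 60, 60)], {"A": {"gwl": 0.8}}, seed=9)
        res = cohort_median_shift(table).set_index(["group", "gene"])
        assert res.loc[("A", "gwl"), "median_shift"] > 0
        assert res.loc[("A", "gwl"), "p_adj"] < 0.05

    def test_group_without_normals_is_nd(self):
        table, _ = synth.gen_cohort_expression([("A", 20, 20), ("B", 15, 0)],
                                               seed=10)
        res = cohort_median_shift(table).set_index(["group", "gene"])
        assert (res.loc[("B",), "status"] == "nd").all()
        assert res.loc[("B",), "p"].isna().all()

    def test_shifted_group_dominates_lowest_ed50_flags(self):
        """A group with low GWL and high B55α should own the most-sensitive
        flags under the published prediction formula."""
        table, _ = synth.gen_cohort_expression(
            [("A", 100, 0), ("B", 100, 0), ("C", 100, 0)],
            {"C": {"gwl": -1.5, "b55a": 1.0}}, seed=11)
        wide = table.pivot_table(index=["group", "sample"], columns="gene",
                                 values="fpkm").reset_index()
        pred = predict_ed50(PUBLISHED, wide)
        flags = rank_and_flag(pred, 0.05)
        assert (wide.loc[flags, "group"] == "C").mean() > 0.8


class TestCorrelate:
    def test_perfect_linear_relation(self):
        r, p = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_hand_computed_five_points(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        num = np.sum((x - 3) * (y - y.mean()))
        den = np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - y.mean()) ** 2))
        r, _ = correlate(x, y)
        assert r == pytest.approx(num / den)

    def test_null_r_is_small(self, rng):
        r, p = correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])
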