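"""Phosphoproteomics processing chain and differential statistics."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from gwlpheno import synth
from gwlpheno.phospho import (classify_hits, estimate_prior, hit_counts,
                              intersect_hits, moderated_test, motif_frequencies,
                              normalize_phospho)


def _small_matrix(seed=0, n=200, **kw):
    return synth.gen_phospho_dataset(n, seed=seed, **kw)


class TestNormalise:
    def test_sum_normalisation_totals_one_before_log(self):
        mat, _, _ = _small_matrix(missing_rate=0.0)
        data = mat.drop(columns=["window"])
        frac = data / data.sum()
        np.testing.assert_allclose(frac.sum(), 1.0)

    def test_zero_imputed_to_sample_min_minus_one(self):
        mat = pd.DataFrame({"window": ["A" * 15] * 3,
                            "s1": [4.0, 2.0, 0.0], "s2": [1.0, 1.0, 2.0]},
                           index=pd.Index(list("abc"), name="site"))
        proc = normalize_phospho(mat)
        col = proc["s1"]
        nonzero_min = min(np.log2(4 / 6), np.log2(2 / 6))
        # imputation happens before centring; undo the median shift
        med = np.median([np.log2(4 / 6), np.log2(2 / 6), nonzero_min - 1])
        assert col.loc["c"] == pytest.approx(nonzero_min - 1 - med)

    def test_per_sample_rescaling_invariance(self):
        mat, _, _ = _small_matrix(seed=5)
        scaled = mat.copy()
        scaled["control_1"] = scaled["control_1"] * 10.0
        pd.testing.assert_frame_equal(normalize_phospho(mat),
                                      normalize_phospho(scaled))

    def test_all_zero_sample_rejected(self):
        mat = pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-zero"):
            normalize_phospho(mat)

    def test_median_centred_columns(self):
        mat, _, _ = _small_matrix(seed=6)
        proc = normalize_phospho(mat).drop(columns=["window"])
        np.testing.assert_allclose(proc.median(), 0.0, atol=1e-12)


class TestModeratedTest:
    def test_zero_prior_df_equals_ordinary_t(self, phospho_dataset):
        mat, design, _ = phospho_dataset
        proc = normalize_phospho(mat)
        res = moderated_test(proc, design, prior_df=0)
        data = proc.drop(columns=["window"])
        g1 = [c for c in data if design[c] == "control"]
        g2 = [c for c in data if design[c] == "treated"]
        t, p = st.ttest_ind(data[g2], data[g1], axis=1)
        np.testing.assert_allclose(res["t"], t, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p, rtol=1e-10)

    def test_infinite_prior_df_closed_form(self, phospho_dataset):
        mat, design, _ = phospho_dataset
        proc = normalize_phospho(mat)
        s0_sq = 0.04
        res = moderated_test(proc, design, prior_df=np.inf, prior_s2=s0_sq)
        data = proc.drop(columns=["window"])
        g1 = [c for c in data if design[c] == "control"]
        g2 = [c for c in data if design[c] == "treated"]
        lfc = data[g2].mean(axis=1) - data[g1].mean(axis=1)
        expected = lfc / np.sqrt(s0_sq * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res["t"], expected, rtol=1e-10)

    def test_null_type_one_error_calibrated(self):
        """2,000 null sites, 3v3: fraction with p < 0.05 within 3 MC SD of 0.05."""
        mat, design, _ = synth.gen_phospho_dataset(
            2000, replicates=3, frac_down=0.0, frac_up=0.0, missing_rate=0.0,
            seed=31)
        res = moderated_test(normalize_phospho(mat), design)
        frac = float((res["p"] < 0.05).mean())
        mc_sd = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * mc_sd

    def test_spiked_effects_recovered(self):
        mat, design, truth = synth.gen_phospho_dataset(
            2000, frac_down=0.1, effect_log2=3.0, missing_rate=0.0, seed=17)
        res = classify_hits(moderated_test(normalize_phospho(mat), design))
        status = np.asarray(truth.payload["status"])
        down_hit = res["hit_class"].to_numpy()[status == "down"] == "negative hit"
        assert down_hit.mean() >= 0.8

    def test_prior_estimator_recovers_generative_hyperparameters(self, rng):
        # s2 ~ s0^2 * chi2(df)/df scaled by F prior with d0=8, s0^2=0.09
        d0, s0_sq, df, n = 8.0, 0.09, 4, 20000
        s2 = s0_sq * d0 / rng.chisquare(d0, n) * rng.chisquare(df, n) / df
        d0_hat, s0_hat = estimate_prior(s2, df)
        assert d0_hat == pytest.approx(d0, rel=0.2)
        assert s0_hat == pytest.approx(s0_sq, rel=0.1)

    def test_matches_limma_on_small_fixture(self, tmp_path):
        """Independent oracle: limma's eBayes on the same processed matrix."""
        mat, design, _ = _small_matrix(seed=23, n=120, missing_rate=0.0)
        proc = normalize_phospho(mat).drop(columns=["window"])
        csv = tmp_path / "m.csv"
        proc.to_csv(csv)
        out = tmp_path / "limma.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{csv}", row.names=1))
            design <- cbind(Intercept=1, Treated=rep(c(0,1), each=3))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(lfc=fit$coefficients[,2],
                                 t=fit$t[,2], p=fit$p.value[,2]), "{out}")
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out, index_col=0)
        res = moderated_test(proc, design)
        np.testing.assert_allclose(res["log2fc"], ref["lfc"], rtol=1e-8)
        np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-4)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-3, atol=1e-12)


class TestClassifyHits:
    def _stats(self, p, fdr, fc):
        return pd.DataFrame({"log2fc": [fc], "p": [p], "fdr": [fdr]})

    @pytest.mark.parametrize("p,fdr,fc,expected", [
        (0.01, 0.05, -1.0, "negative hit"),
        (0.01, 0.05, 1.0, "positive hit"),
        (0.5, 0.05, -1.0, "not significant"),   # p gate fails
        (0.01, 0.2, -1.0, "not significant"),   # FDR gate fails
        (0.049, 0.099, -0.001, "negative hit"),
        (0.05, 0.099, -1.0, "not significant"),  # strict inequality on p
    ])
    def test_dual_gate(self, p, fdr, fc, expected):
        out = classify_hits(self._stats(p, fdr, fc))
        assert out["hit_class"].iloc[0] == expected

    def test_counts_monotone_in_stricter_thresholds(self, phospho_dataset):
        mat, design, _ = phospho_dataset
        res = moderated_test(normalize_phospho(mat), design)
        loose = hit_counts(classify_hits(res, p_max=0.05, fdr_max=0.1))
        strict = hit_counts(classify_hits(res, p_max=0.01, fdr_max=0.05))
        assert strict["negative hit"] <= loose["negative hit"]
        assert strict["positive hit"] <= loose["positive hit"]


class TestMotifs:
    def test_full_proline_bias_gives_frequency_one(self):
        wins = ["AAAAAAASPAAAAAA"] * 5 + ["AAAAAAASAAAAAAA"] * 10
        labels = ["negative hit"] * 5 + ["not significant"] * 10
        freqs, enrich = motif_frequencies(wins, labels)
        assert freqs["negative hit"].loc[1, "P"] == 1.0
        assert enrich.set_index("hit_class").loc["negative hit", "freq_plus1_pro"] == 1.0

    def test_enrichment_odds_ratio_matches_2x2_table(self):
        # 120/200 hits with P at +1, 400/2000 background: OR = (120*1600)/(80*400)
        hit_w = ["AAAAAAASPAAAAAA"] * 120 + ["AAAAAAASAAAAAAA"] * 80
        bg_w = ["AAAAAAATPAAAAAA"] * 400 + ["AAAAAAATAAAAAAA"] * 1600
        labels = ["negative hit"] * 200 + ["not significant"] * 2000
        _, enrich = motif_frequencies(hit_w + bg_w, labels)
        row = enrich.set_index("hit_class").loc["negative hit"]
        assert row["odds_ratio"] == pytest.approx((120 * 1600) / (80 * 400))
        assert row["fisher_p"] < 1e-10

    def test_x_padding_excluded_from_denominators(self):
        wins = ["XXXXXXXSPAAAAAA", "AAAAAAASPAAAAAA"]
        labels = ["negative hit", "negative hit"]
        freqs, _ = motif_frequencies(wins, labels + [])
        # position -7: only one non-X observation (A)
        assert freqs["negative hit"].loc[-7, "A"] == 1.0

    def test_generator_bias_detected(self):
        mat, _, truth = synth.gen_phospho_dataset(
            2000, frac_down=0.1, pro_plus1_hit=0.6, pro_plus1_bg=0.2, seed=3)
        status = np.asarray(truth.payload["status"])
        labels = np.where(status == "down", "negative hit", "not significant")
        _, enrich = motif_frequencies(mat["window"].tolist(), labels.tolist())
        row = enrich.set_index("hit_class").loc["negative hit"]
        # true odds ratio (0.6/0.4)/(0.2/0.8) = 6
        assert row["odds_ratio"] == pytest.approx(6.0, rel=0.35)
        assert row["fisher_p"] < 1e-10

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            motif_frequencies([], [])


class TestIntersection:
    def test_identical_sets(self):
        s = {"a": {1, 2, 3}, "b": {1, 2, 3}, "c": {1, 2, 3}}
        res = intersect_hits(s)
        assert res.common == 3
        assert res.shared_fraction == 1.0

    def test_disjoint_sets(self):
        res = intersect_hits({"a": {1}, "b": {2}, "c": {3}})
        assert res.common == 0
        assert res.shared_fraction == 0.0

    def test_partition_matches_set_algebra(self, rng):
        universe = list(range(200))
        sets = {k: set(rng.choice(universe, size=80, replace=False))
                for k in "abc"}
        res = intersect_hits(sets)
        a, b, c = sets["a"], sets["b"], sets["c"]
        assert res.regions[("a",)] == len(a - b - c)
        assert res.regions[("a", "b")] == len((a & b) - c)
        assert res.regions[("a", "b", "c")] == len(a & b & c)
        assert res.union == len(a | b | c)
        # exclusive regions partition the union
        assert sum(res.regions.values()) == res.union

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_hits({"a": {1}})
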