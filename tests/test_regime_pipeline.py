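"""Pi evaluation, PCA driver selection, regimes, ANOVA, summaries, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import marshsim as ms


class TestEvaluatePis:
    def test_table_worked_examples(self, table3_panels):
        pis = ms.evaluate_pis(ms.panel_to_si(table3_panels))
        hamblin = pis[pis["site"] == "Hamblin Pond"].iloc[0]
        # nee 6.9 / par 1602.5 and st 18.7 C, ss 26 ppt, pa 1011.3 mbar.
        assert round(hamblin["lue"], 4) == 0.0043
        assert round(hamblin["lue"], 3) == 0.004
        assert round(hamblin["bgc"], 3) == 0.111

    def test_zero_salinity_limit(self):
        df = pd.DataFrame({"site": ["A"], "nee": [5.0], "par": [1000.0],
                           "st": [18.0], "ss": [0.0], "pa": [1012.0]})
        pis = ms.evaluate_pis(ms.panel_to_si(df))
        assert pis["bgc"].iloc[0] == 0.0

    def test_bgc_is_pi3_over_pi2_elementwise(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        pis = ms.evaluate_pis(ms.panel_to_si(panels))
        np.testing.assert_allclose(pis["bgc"], pis["pi3"] / pis["pi2"],
                                   rtol=1e-12)

    def test_lue_reconstruction_identity(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        si = ms.panel_to_si(panels)
        pis = ms.evaluate_pis(si)
        np.testing.assert_allclose(pis["lue"] * si["par"], si["nee"], rtol=1e-12)

    def test_nonpositive_records_excluded(self, table3_panels, caplog):
        import logging
        broken = table3_panels.copy()
        broken.loc[0, "nee"] = -1.0
        with caplog.at_level(logging.WARNING, logger="marshsim.regime_pipeline"):
            pis = ms.evaluate_pis(ms.panel_to_si(broken))
        assert len(pis) == 3
        assert "excluding" in caplog.text


class TestPCADriverSelection:
    def test_monotone_lue_of_bgc_selects_bgc(self):
        # LUE generated as a monotone (power-law) function of BGC: the BGC
        # loading must be nearly collinear with the response loading.
        rng = np.random.default_rng(11)
        n = 150
        df = pd.DataFrame({
            "site": ["A"] * n,
            "st": rng.uniform(10, 26, n), "ss": rng.uniform(12, 38, n),
            "par": rng.uniform(400, 2000, n), "pa": rng.normal(1013, 4, n),
        })
        si = ms.panel_to_si(df.assign(nee=1.0))
        bgc = si["st"] * 1.48 * si["ss"] / si["pa"]
        lue = 0.002 * (0.13 / bgc) ** 2 * np.exp(rng.normal(0, 0.05, n))
        df["nee"] = lue * df["par"]
        pis = ms.evaluate_pis(ms.panel_to_si(df))
        res = ms.pca_driver_selection(pis)
        assert res.selected_driver == "bgc"
        assert min(res.angles_deg["bgc"], 180 - res.angles_deg["bgc"]) < 15

    def test_log_space_rank_at_most_five(self, synthetic_campaign):
        # All seven numbers are monomials over five base quantities, so the
        # log-transformed matrix has rank <= 5.
        panels, _ = synthetic_campaign
        pis = ms.evaluate_pis(ms.panel_to_si(panels))
        logX = np.log10(pis[["lue"] + ms.regime_pipeline.DRIVER_COLUMNS])
        assert np.linalg.matrix_rank(logX.to_numpy(), tol=1e-8) <= 5

    def test_duplicate_driver_columns_get_identical_loadings(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        pis = ms.evaluate_pis(ms.panel_to_si(panels))
        pis["bgc_copy"] = pis["bgc"]
        res = ms.pca_driver_selection(pis, drivers=["bgc", "bgc_copy", "pi2"])
        np.testing.assert_allclose(res.loadings.loc["bgc"],
                                   res.loadings.loc["bgc_copy"], atol=1e-10)

    def test_zero_variance_column_dropped_with_warning(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        pis = ms.evaluate_pis(ms.panel_to_si(panels))
        pis["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = ms.pca_driver_selection(pis, drivers=["bgc", "flat"])
        assert "flat" not in res.loadings.index

    def test_needs_three_records(self, table3_panels):
        pis = ms.evaluate_pis(ms.panel_to_si(table3_panels.iloc[:2]))
        with pytest.raises(ValueError, match="3 records"):
            ms.pca_driver_selection(pis)


class TestClassify:
    @pytest.mark.parametrize("lue,bgc,regime", [
        (0.004, 0.111, "high"),          # Hamblin-style
        (0.003, 0.143, "transitional"),  # Eel-style
        (0.001, 0.05, "low"),            # below lue_min regardless of bgc
        (0.002, 0.13, "high"),           # boundary ties go to high
        (0.0019999, 0.10, "low"),
        (0.002, 0.1300001, "transitional"),
    ])
    def test_regime_assignment(self, lue, bgc, regime):
        assert ms.classify(lue, bgc) == regime

    def test_partition(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        pis = ms.classify_panel(ms.evaluate_pis(ms.panel_to_si(panels)))
        counts = pis["regime"].value_counts()
        assert counts.sum() == len(pis)
        assert set(counts.index) <= {"high", "transitional", "low"}

    @given(lue=st.floats(1e-5, 0.02), bgc=st.floats(0.02, 0.2),
           dlue=st.floats(0, 0.01), dbgc=st.floats(0, 0.05))
    def test_monotonicity(self, lue, bgc, dlue, dbgc):
        rank = {"low": 0, "transitional": 1, "high": 1}
        before = ms.classify(lue, bgc)
        after_lue = ms.classify(lue + dlue, bgc)
        # Increasing LUE never demotes a record to low.
        assert rank[after_lue] >= rank[before]
        # Increasing BGC never moves transitional -> high.
        after_bgc = ms.classify(lue, bgc + dbgc)
        if before == "transitional":
            assert after_bgc != "high"


class TestAnova:
    def test_hand_computed_two_group_f(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, MSW = 1 -> F(1,4) = 13.5.
        values = [1, 2, 3, 4, 5, 6]
        labels = ["high"] * 3 + ["low"] * 3
        (res,) = ms.anova_pairwise(values, labels)
        assert res.f_stat == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p_value == pytest.approx(stats.f.sf(13.5, 1, 4))
        # Independent oracle.
        f_ref, p_ref = stats.f_oneway(values[:3], values[3:])
        assert res.f_stat == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_identical_groups_give_zero_f(self):
        res = ms.anova_pairwise([1.0, 2.0, 3.0] * 2,
                                ["high"] * 3 + ["low"] * 3)[0]
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_three_regimes_give_three_pairs(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        pis = ms.classify_panel(ms.evaluate_pis(ms.panel_to_si(panels)))
        results = ms.anova_pairwise(pis["lue"], pis["regime"])
        assert len(results) == 3
        assert {r.pair for r in results} == {
            ("high", "transitional"), ("high", "low"), ("transitional", "low")}
        for r in results:
            assert r.p_value < 0.05

    def test_matches_scipy_on_synthetic_data(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        pis = ms.classify_panel(ms.evaluate_pis(ms.panel_to_si(panels)))
        for r in ms.anova_pairwise(pis["lue"], pis["regime"]):
            a = pis.loc[pis["regime"] == r.pair[0], "lue"]
            b = pis.loc[pis["regime"] == r.pair[1], "lue"]
            f_ref, p_ref = stats.f_oneway(a, b)
            assert r.f_stat == pytest.approx(f_ref)
            assert r.p_value == pytest.approx(p_ref)

    def test_empty_regime_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            results = ms.anova_pairwise([1, 2, 3, 4],
                                        ["high", "high", "low", "low"])
        assert len(results) == 1


class TestSiteSummary:
    def test_seasonal_means_reproduce_site_table(self, table3_panels):
        out = ms.site_summary(table3_panels)
        assert list(out.round(3)["lue"]) == [0.004, 0.004, 0.004, 0.003]
        assert list(out.round(3)["bgc"]) == [0.131, 0.111, 0.131, 0.143]
        assert list(out["regime"]) == [
            "transitional", "high", "transitional", "transitional"]

    def test_ratio_of_means_not_mean_of_ratios(self):
        df = pd.DataFrame({"site": ["A", "A"], "nee": [1.0, 8.0],
                           "par": [1000.0, 1000.0], "st": [18.0, 18.0],
                           "ss": [26.0, 26.0], "pa": [1012.0, 1012.0]})
        out = ms.site_summary(df)
        assert out["lue"].iloc[0] == pytest.approx(4.5 / 1000.0)

    def test_single_record_site_equals_record(self, table3_panels):
        one = table3_panels.iloc[[1]]
        out = ms.site_summary(one)
        assert out["nee"].iloc[0] == 6.9
        assert out["regime"].iloc[0] == "high"


class TestATSTThreshold:
    def test_printed_model_at_17(self):
        res = ms.at_st_threshold(coef=(6.31, 1.135), st_eval=17.0)
        assert round(res.at_at_threshold, 1) == 25.6

    def test_collinear_recovery(self):
        df = pd.DataFrame({"st": np.linspace(10, 25, 10)})
        df["at"] = 2.0 * df["st"]
        res = ms.at_st_threshold(df)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(5)
        st_vals = rng.uniform(9, 26, 200)
        at = 6.31 + 1.135 * st_vals + rng.normal(0, 1.5, 200)
        res = ms.at_st_threshold(pd.DataFrame({"st": st_vals, "at": at}))
        lr = stats.linregress(st_vals, at)
        assert abs(res.slope - 1.135) < 3 * lr.stderr

    def test_missing_at_errors_with_schema_hint(self, table3_panels):
        with pytest.raises(ValueError, match="at_c"):
            ms.at_st_threshold(table3_panels)


class TestBinResponse:
    def test_one_degree_bins(self):
        df = pd.DataFrame({"site": ["A", "A"], "st": [17.2, 17.9],
                           "nee": [4.0, 6.0]})
        out = ms.bin_response(df, "st")
        assert len(out) == 1
        assert out["bin_left"].iloc[0] == 17.0
        assert out["bin_right"].iloc[0] == 18.0
        assert out["nee_mean"].iloc[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("driver,width", [("st", 1.0), ("ss", 2.0),
                                              ("par", 100.0)])
    def test_fixed_widths(self, driver, width, synthetic_campaign):
        panels, _ = synthetic_campaign
        out = ms.bin_response(panels, driver)
        np.testing.assert_allclose(out["bin_right"] - out["bin_left"], width)

    def test_step_drop_detected_across_salinity_threshold(self):
        # Step-function response: uptake halves above 30 ppt.
        rng = np.random.default_rng(3)
        ss = rng.uniform(20, 40, 400)
        nee = np.where(ss < 30, 8.0, 2.0) + rng.normal(0, 0.2, 400)
        df = pd.DataFrame({"site": ["A"] * 400, "ss": ss, "nee": nee})
        out = ms.bin_response(df, "ss").set_index("bin_left")
        assert out.loc[28.0, "nee_mean"] - out.loc[30.0, "nee_mean"] > 4.0

    def test_unknown_driver_rejected(self, synthetic_campaign):
        panels, _ = synthetic_campaign
        with pytest.raises(ValueError, match="driver"):
            ms.bin_response(panels, "pa")
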