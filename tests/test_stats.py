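"""Statistics from formulas, checked against published rows and scipy oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import arousalkit.reference_values as ref
from arousalkit.config import PipelineConfig
from arousalkit.stats import (
    GroupSummary,
    chi_square,
    cohens_d,
    cohort_analysis,
    eta,
    eta_from_summaries,
    pooled_t,
    welch_t,
)


def _summary(name):
    (n1, m1, s1), (n2, m2, s2), printed = ref.METRIC_SUMMARIES[name]
    return GroupSummary(n1, m1, s1, n2, m2, s2), printed


class TestPooledT:
    @pytest.mark.parametrize("name", ["wursk", "caars_dsm_hyi", "caars_dsm_g",
                                      "general_sleep", "caars_dsm_ia"])
    def test_reproduces_published_rows(self, name):
        s, printed = _summary(name)
        res = pooled_t(s)
        assert res["t"] == pytest.approx(printed, abs=0.01)
        assert res["df"] == s.n1 + s.n2 - 2

    def test_identical_summaries_give_zero(self):
        res = pooled_t(GroupSummary(10, 5.0, 2.0, 12, 5.0, 2.0))
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_scipy_from_stats(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 40, 2)
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 5, 2)
            mine = pooled_t(GroupSummary(n1, m1, s1, n2, m2, s2))
            t_sp, p_sp = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2)
            assert mine["t"] == pytest.approx(t_sp, rel=1e-12)
            assert mine["p"] == pytest.approx(p_sp, rel=1e-9)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pooled_t(GroupSummary(5, 1.0, 0.0, 5, 2.0, 0.0))


class TestWelchT:
    def test_bdi_row_from_printed_summaries(self):
        s, _ = _summary("bdi")
        res = welch_t(s)
        assert res["t"] == pytest.approx(-2.825, abs=0.01)
        assert res["df"] == pytest.approx(24.3, abs=0.1)

    def test_coincides_with_pooled_for_equal_n_and_sd(self):
        s = GroupSummary(15, 3.0, 2.0, 15, 4.5, 2.0)
        assert welch_t(s)["t"] == pytest.approx(pooled_t(s)["t"], rel=1e-12)

    def test_df_limit_under_extreme_variance_ratio(self):
        s = GroupSummary(5, 0.0, 10.0, 50, 1.0, 1e-4)
        assert welch_t(s)["df"] == pytest.approx(4.0, abs=0.01)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 40, 2)
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 5, 2)
            mine = welch_t(GroupSummary(n1, m1, s1, n2, m2, s2))
            t_sp, p_sp = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                                  equal_var=False)
            assert mine["t"] == pytest.approx(t_sp, rel=1e-12)
            assert mine["p"] == pytest.approx(p_sp, rel=1e-9)


class TestChiSquare:
    @pytest.mark.parametrize("name", ["nicotine_users", "alcohol_users",
                                      "marital_status", "graduation",
                                      "caars_dsm_ia_pct", "gender_women",
                                      "caars_dsm_hyi_pct", "caars_dsm_g_pct"])
    def test_reproduces_published_tables(self, name):
        table, printed = ref.CONTINGENCY_TABLES[name]
        assert chi_square(table)["x2"] == pytest.approx(printed, abs=0.01)

    def test_independent_table_gives_zero(self):
        assert chi_square([[10, 20], [20, 40]])["x2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 5))
            table = rng.integers(1, 21, size=(2, k))
            mine = chi_square(table)
            res = sps.chi2_contingency(table, correction=False)
            assert mine["x2"] == pytest.approx(res.statistic, rel=1e-12)
            assert mine["df"] == res.dof
            assert mine["p"] == pytest.approx(res.pvalue, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 5], [0, 7]])


class TestEta:
    def test_bdi_row(self):
        (g1, g2, _) = ref.METRIC_SUMMARIES["bdi"]
        res = eta_from_summaries([g1, g2])
        assert res["signed_eta"] == pytest.approx(0.437, abs=0.01)
        assert res["eta2"] == pytest.approx(0.191, abs=0.01)

    def test_wursk_row_is_negative(self):
        (g1, g2, _) = ref.METRIC_SUMMARIES["wursk"]
        res = eta_from_summaries([g1, g2])
        assert res["signed_eta"] == pytest.approx(-0.233, abs=0.01)
        assert res["eta2"] == pytest.approx(0.054, abs=0.01)

    def test_raw_values_equal_summary_route(self, rng):
        for _ in range(20):
            x1 = rng.normal(0, 2, int(rng.integers(3, 30)))
            x2 = rng.normal(1, 3, int(rng.integers(3, 30)))
            labels = np.array(["u"] * len(x1) + ["s"] * len(x2))
            raw = eta(np.concatenate([x1, x2]), labels)
            summ = eta_from_summaries([
                (len(x1), x1.mean(), x1.std(ddof=1)),
                (len(x2), x2.mean(), x2.std(ddof=1))])
            assert raw["eta2"] == pytest.approx(summ["eta2"], abs=1e-10)

    def test_constant_values_flagged_undefined(self):
        res = eta([3.0, 3.0, 3.0, 3.0], ["a", "a", "b", "b"])
        assert res["undefined"]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(2, 50),
           st.floats(-10, 10), st.floats(-10, 10),
           st.floats(0.1, 10), st.floats(0.1, 10))
    def test_eta2_t_identity(self, n1, n2, m1, m2, s1, s2):
        """For two groups, Eta^2 = t^2 / (t^2 + df) with the pooled t."""
        summ = GroupSummary(n1, m1, s1, n2, m2, s2)
        res = pooled_t(summ)
        e = eta_from_summaries([(n1, m1, s1), (n2, m2, s2)])
        t2 = res["t"] ** 2
        assert e["eta2"] == pytest.approx(t2 / (t2 + res["df"]), abs=1e-10)

    def test_published_eta_pairs_internally_consistent(self):
        for name, (signed, eta2, _) in ref.ETA_TABLE.items():
            assert signed**2 == pytest.approx(eta2, abs=1.6e-3), name


class TestCohensD:
    def test_unit_pooled_sd_difference(self):
        assert cohens_d(GroupSummary(13, 1.0, 1.0, 17, 0.0, 1.0)) == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        assert cohens_d(GroupSummary(8, 2.0, 1.5, 9, 2.0, 0.5)) == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d(GroupSummary(5, 1.0, 0.0, 5, 2.0, 0.0))


class TestCohortAnalysis:
    def _cohort(self, seed=3):
        from arousalkit.synthetic import simulate_cohort

        return simulate_cohort(rng=np.random.default_rng(seed))

    def test_report_structure(self):
        report = cohort_analysis(self._cohort())
        assert {"variable", "statistic", "df", "p", "eta", "eta2"} <= set(report.columns)
        assert (report["p"].between(0, 1)).all()
        assert set(report.loc[report.kind == "nominal", "test"]) == {"chi_square"}
        powers = report[report.variable.str.startswith(("delta", "theta", "alpha", "beta"))]
        assert len(powers) == 16
        assert powers["cohens_d"].notna().all()

    def test_median_split_applied_when_group_missing(self):
        cohort = self._cohort().drop(columns=["group"])
        report = cohort_analysis(cohort)
        assert len(report) > 0

    def test_empty_cohort_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            cohort_analysis(pd.DataFrame())

    def test_welch_trigger_on_variance_ratio(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(40)],
            "group": ["unstable"] * 20 + ["stable"] * 20,
            "bdi": np.abs(np.concatenate([rng.normal(10, 0.5, 20),
                                          rng.normal(15, 12, 20)])),
        })
        report = cohort_analysis(df)
        assert report.loc[report.variable == "bdi", "test"].item() == "welch_t"
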