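"""KM estimation, log-rank, Cox regression and backward selection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats

import lncmod as lm
from lncmod.survival import CoxConvergenceError

from conftest import make_records, make_study, null_two_group_config


def _sim_cox_records(rng, n, beta=0.7, censor=0.2, extra_noise=0,
                     round_times=False):
    z = rng.normal(size=n)
    rate = 0.05 * np.exp(beta * z)
    t = rng.exponential(1 / rate)
    if censor > 0:
        lam_c = 0.05 * censor / (1 - censor)
        c = rng.exponential(1 / lam_c, n)
    else:
        c = np.full(n, np.inf)
    times = np.minimum(t, c)
    if round_times:  # force ties to exercise the Efron correction
        times = np.maximum(np.round(times, 0), 0.5)
    cov = {"marker": z}
    for j in range(extra_noise):
        cov[f"noise{j}"] = rng.normal(size=n)
    return make_records(times, t <= c, **cov)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = lm.km_estimate(make_records([1, 2, 3], [1, 1, 1]))
        assert list(km["survival"]) == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(km["n_at_risk"]) == [3, 2, 1]

    def test_no_events_flat_curve(self):
        km = lm.km_estimate(make_records([1, 2, 3], [0, 0, 0]))
        assert km.empty  # no event times, S stays 1 everywhere

    def test_censoring_shrinks_risk_set(self):
        km = lm.km_estimate(make_records([1.0, 1.5, 2.0], [1, 0, 1]))
        assert list(km["survival"]) == pytest.approx([2 / 3, 0.0])
        assert list(km["n_at_risk"]) == [3, 1]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=40).round(1) + 0.1
        km = lm.km_estimate(make_records(times, np.ones(40)))
        for _, row in km.iterrows():
            ecdf = (times > row["time"]).mean()
            assert row["survival"] == pytest.approx(ecdf, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        recs = _sim_cox_records(rng, 30, round_times=True)
        km = lm.km_estimate(recs)
        kmf = KaplanMeierFitter().fit([r.time for r in recs],
                                      [r.event for r in recs])
        ref = kmf.survival_function_.loc[km["time"], "KM_estimate"]
        assert np.abs(km["survival"].to_numpy() -
                      ref.to_numpy()).max() < 1e-4


class TestLogRank:
    def test_identical_groups_null(self):
        recs = make_records([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = lm.logrank_test(recs, list(recs))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        a = _sim_cox_records(rng, 15)
        b = _sim_cox_records(rng, 12, beta=1.2)
        assert lm.logrank_test(a, b)[0] == pytest.approx(
            lm.logrank_test(b, a)[0], abs=1e-12)

    def test_matches_lifelines_on_fixture(self):
        # 12-record fixture with ties and censoring
        ta = [1, 2, 2, 4, 5, 5]
        ea = [1, 1, 0, 1, 0, 1]
        tb = [3, 3, 4, 6, 7, 9]
        eb = [1, 0, 1, 1, 1, 0]
        chi2, p = lm.logrank_test(make_records(ta, ea), make_records(tb, eb))
        ref = lifelines_logrank(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
        assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_no_events_warns_p_one(self):
        a = make_records([1, 2], [0, 0])
        b = make_records([3, 4], [0, 0])
        assert lm.logrank_test(a, b) == (0.0, 1.0)

    def test_agrees_with_cox_wald_chi2(self):
        """Log-rank and a two-group Cox test agree asymptotically."""
        rng = np.random.default_rng(3)
        n = 500
        g = rng.integers(0, 2, n).astype(float)
        rate = 0.05 * np.exp(0.5 * g)
        t = rng.exponential(1 / rate)
        recs = make_records(t, np.ones(n), group=g)
        a = [r for r in recs if r.covariates["group"] == 0]
        b = [r for r in recs if r.covariates["group"] == 1]
        chi2, _ = lm.logrank_test(a, b)
        model = lm.cox_fit(recs, ["group"])
        wald = (model.beta[0] / model.se[0]) ** 2
        assert abs(chi2 - wald) / chi2 < 0.1


class TestDichotomize:
    def test_median_split(self):
        study = make_study({"G1": list(range(1, 11))}, {}, {},
                           sample_ids=[f"S{i}" for i in range(10)])
        low, high, cut = lm.dichotomize_expression(study, "G1")
        assert cut == 5.5
        assert len(low) == len(high) == 5

    def test_value_at_median_goes_low(self):
        study = make_study({"G1": [1.0, 2.0, 2.0, 3.0, 9.0]}, {}, {},
                           sample_ids=list("ABCDE"))
        low, high, cut = lm.dichotomize_expression(study, "G1")
        assert cut == 2.0
        assert set(low) == {"A", "B", "C"}

    def test_constant_expression_rejected(self):
        study = make_study({"G1": [2.0, 2.0, 2.0]}, {}, {})
        with pytest.raises(ValueError):
            lm.dichotomize_expression(study, "G1")


class TestCoxFit:
    def test_binary_recoding_negates_beta(self):
        rng = np.random.default_rng(4)
        n = 80
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * g)))
        recs = make_records(t, np.ones(n), g=g)
        flipped = make_records(t, np.ones(n), g=1.0 - g)
        m1 = lm.cox_fit(recs, ["g"])
        m2 = lm.cox_fit(flipped, ["g"])
        assert m1.beta[0] == pytest.approx(-m2.beta[0], abs=1e-8)

    def test_matches_lifelines_on_tied_fixture(self):
        rng = np.random.default_rng(5)
        recs = _sim_cox_records(rng, 20, round_times=True, extra_noise=1)
        model = lm.cox_fit(recs, ["marker", "noise0"])
        df = pd.DataFrame({
            "T": [r.time for r in recs], "E": [r.event for r in recs],
            "marker": [r.covariates["marker"] for r in recs],
            "noise0": [r.covariates["noise0"] for r in recs]})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.abs(model.beta - cph.params_.to_numpy()).max() < 1e-4
        assert np.abs(model.se - cph.standard_errors_.to_numpy()).max() < 1e-4
        assert model.log_partial_likelihood == pytest.approx(
            cph.log_likelihood_, abs=1e-4)

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(6)
        est = [lm.cox_fit(_sim_cox_records(rng, 500), ["marker"]).beta[0]
               for _ in range(20)]
        assert abs(np.mean(est) - 0.7) < 0.05

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(7)
        m = lm.cox_fit(_sim_cox_records(rng, 100), ["marker"])
        assert m.ci95_low[0] < m.hr[0] < m.ci95_high[0]
        assert (m.hr > 0).all()

    def test_separation_raises_naming_variable(self):
        # perfect separation: covariate orders the death times exactly
        t = np.arange(1.0, 21.0)
        recs = make_records(t, np.ones(20), sep=-t)
        with pytest.raises(CoxConvergenceError, match="sep"):
            lm.cox_fit(recs, ["sep"])

    def test_requires_enough_events(self):
        recs = make_records([1, 2, 3], [1, 0, 0], x=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            lm.cox_fit(recs, ["x"])


class TestBackwardSelection:
    def test_informative_variables_all_kept(self):
        rng = np.random.default_rng(8)
        n = 300
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * z1 + 0.8 * z2)))
        recs = make_records(t, np.ones(n), z1=z1, z2=z2)
        model, trace = lm.backward_select(recs, ["z1", "z2"])
        assert set(model.variables) == {"z1", "z2"}
        assert trace == []

    def test_single_noise_variable_empty_model(self):
        rng = np.random.default_rng(9)
        n = 200
        noise = rng.normal(size=n)
        t = rng.exponential(20, size=n)
        recs = make_records(t, np.ones(n), noise=noise)
        model, trace = lm.backward_select(recs, ["noise"])
        assert model.is_empty
        assert [v for v, _ in trace] == ["noise"]

    def test_marker_kept_noise_dropped(self):
        rng = np.random.default_rng(10)
        recs = _sim_cox_records(rng, 400, beta=0.7, extra_noise=3)
        model, trace = lm.backward_select(
            recs, ["marker", "noise0", "noise1", "noise2"])
        assert "marker" in model.variables

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        recs = _sim_cox_records(rng, 150, extra_noise=2)
        out1 = lm.backward_select(recs, ["marker", "noise0", "noise1"])
        out2 = lm.backward_select(recs, ["marker", "noise0", "noise1"])
        assert out1[0].variables == out2[0].variables
        assert out1[1] == out2[1]


@pytest.fixture(scope="module")
def survival_study():
    cfg = null_two_group_config(seed=21, n_genes=20, n_per_group=100)
    cfg.survival_beta = {"LNC00001": 0.7}
    cfg.censor_rate = 0.2
    return lm.simulate_survival(lm.simulate_study(cfg)[0], cfg)


class TestStudyLevelSurvival:
    def test_univariate_forest_order_and_power(self, survival_study):
        table = lm.univariate_forest(survival_study,
                                     ["LNC00002", "LNC00001"], "os")
        assert list(table.index) == ["LNC00002", "LNC00001"]
        assert table.loc["LNC00001", "HR"] > 1.0
        assert table.loc["LNC00001", "logrank_p"] < 0.05
        assert table.loc["LNC00001", "stars"] != "n.s."

    def test_null_covariate_cis_mostly_cover_one(self, survival_study):
        nulls = [f"LNC{i:05d}" for i in range(3, 11)]
        table = lm.univariate_forest(survival_study, nulls, "os")
        covered = ((table["ci95_low"] < 1.0) &
                   (table["ci95_high"] > 1.0)).sum()
        assert covered >= len(nulls) - 1

    def test_complete_case_dropping_logged(self, survival_study, caplog):
        study = survival_study.copy()
        pat = [s for s in study.sample_ids
               if study.samples.at[s, "group"] != "CTR"]
        study.samples.loc[pat[:5], "os_months"] = np.nan
        with caplog.at_level("INFO", logger="lncmod"):
            recs = lm.records_from_study(study, ["LNC00001"], "os")
        assert len(recs) == len(pat) - 5
        assert "dropped 5" in caplog.text

    def test_lower_risk_subanalysis_filters_and_runs(self):
        cfg = null_two_group_config(seed=22, n_genes=20, n_per_group=100)
        cfg.survival_beta = {"LNC00001": 0.9}
        cfg.censor_rate = 0.2
        study = lm.simulate_survival(lm.simulate_study(cfg)[0], cfg)
        rng = np.random.default_rng(0)
        pats = [s for s in study.sample_ids
                if study.samples.at[s, "group"] != "CTR"]
        scores = rng.uniform(0, 9, len(pats))
        study.samples.loc[pats, "ipssr_score"] = scores
        study.samples.loc[pats, "ipssr_category"] = [
            lm.ipssr_category_from_score(v) for v in scores]
        res = lm.lower_risk_subanalysis(study, ["LNC00001", "LNC00002"],
                                        endpoints=("os",))
        model, _ = res["os"]
        n_eligible = int((scores < 4.5).sum())
        recs = lm.records_from_study(
            study, ["LNC00001"], "os",
            sample_ids=[s for s, v in zip(pats, scores) if v < 4.5])
        assert len(recs) == n_eligible
        assert "LNC00001" in model.variables

    def test_lower_risk_requires_eligible_patients(self, survival_study):
        study = survival_study.copy()
        pats = [s for s in study.sample_ids
                if study.samples.at[s, "group"] != "CTR"]
        study.samples.loc[pats, "ipssr_score"] = 6.0
        study.samples.loc[pats, "ipssr_category"] = "high"
        with pytest.raises(ValueError):
            lm.lower_risk_subanalysis(study, ["LNC00001"])


class TestSpearmanMatrix:
    def test_monotone_and_reversed_pairs(self):
        study = make_study({"A": [1, 2, 3, 4, 5], "B": [2, 4, 8, 9, 20],
                            "C": [5, 4, 3, 2, 1]}, {}, {},
                           sample_ids=list("VWXYZ"))
        r, p = lm.spearman_matrix(study, ["A", "B", "C"])
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert r.loc["A", "C"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_hand_ranking(self):
        # ranks with average ties: x=[1,2,2,3]->[1,2.5,2.5,4],
        # y=[1,2,3,3]->[1,2,3.5,3.5]; Pearson of those ranks
        study = make_study({"X": [1, 2, 2, 3], "Y": [1, 2, 3, 3]}, {}, {},
                           sample_ids=list("ABCD"))
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 2, 3.5, 3.5])
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _ = lm.spearman_matrix(study, ["X", "Y"])
        assert r.loc["X", "Y"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_pairs_nan(self):
        study = make_study({"X": [1.0, 2.0, 3.0], "Y": [2.0, 1.0, 5.0]},
                           {}, {})
        r, p = lm.spearman_matrix(study, ["X", "Y"])
        assert np.isnan(r.loc["X", "Y"]) and np.isnan(p.loc["X", "Y"])

    def test_mutation_indicator_covariate(self, small_cohort):
        study = small_cohort[0]
        r, p = lm.spearman_matrix(study, ["TP53_mut", "blast_pct", "H19"])
        assert r.shape == (3, 3)
        assert np.allclose(np.diag(r), 1.0)
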