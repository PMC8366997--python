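import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from psnrisk.outcomes import (
    HazardEstimate,
    NT_PROBNP_BINS,
    biomarker_km,
    chi2_enrichment,
    classify_events,
    cox_hr,
    cumulative_hazard_by_group,
    km_by_group,
    period_breakdown,
)
from tests.oracles import bh_brute, km_brute, nelson_aalen_brute, wilson_interval_brute


def _events_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "event_type", "days_from_therapy_start", "is_death", "is_censor"],
    )


class TestClassifyEvents:
    def test_cohort_scale_de_novo_rate(self):
        # 886 patients with a post-therapy event among 4,632 -> 19% rate
        rows = []
        for i in range(4632):
            pid = f"P{i:05d}"
            if i < 886:
                rows.append((pid, "HF", 100.0, 0, 0))
            rows.append((pid, "censor", 5000.0, 0, 1))
        table = classify_events(_events_frame(rows))
        rate = table.frame["de_novo_ctrcd"].mean()
        assert rate == pytest.approx(886 / 4632)
        assert round(100 * rate) == 19

    def test_event_on_therapy_start_day_is_de_novo(self):
        rows = [("A", "MI", 0.0, 0, 0), ("A", "death", 400.0, 1, 0)]
        table = classify_events(_events_frame(rows))
        assert table.frame.loc["A", "de_novo_ctrcd"] == 1
        assert table.frame.loc["A", "preexisting"] == 0

    def test_pre_therapy_event_is_preexisting(self):
        rows = [("A", "AF", -30.0, 0, 0), ("A", "censor", 900.0, 0, 1)]
        table = classify_events(_events_frame(rows))
        assert table.frame.loc["A", "preexisting"] == 1
        assert table.frame.loc["A", "de_novo_ctrcd"] == 0
        # no de novo event: time-to-event equals follow-up, flag 0
        assert table.frame.loc["A", "denovo_event"] == 0

    def test_flags_match_row_wise_oracle(self, small_cohort):
        table = classify_events(small_cohort.events)
        ev = small_cohort.events
        cardiac = ev[~ev["event_type"].isin(["death", "censor"])]
        for pid in table.frame.index:
            days = cardiac.loc[cardiac["patient_id"] == pid, "days_from_therapy_start"]
            assert table.frame.loc[pid, "preexisting"] == int((days < 0).any())
            assert table.frame.loc[pid, "de_novo_ctrcd"] == int((days >= 0).any())

    def test_event_after_death_rejected(self):
        rows = [("A", "HF", 500.0, 0, 0), ("A", "death", 400.0, 1, 0)]
        with pytest.raises(ValueError, match="after death"):
            classify_events(_events_frame(rows))

    def test_unknown_event_type_rejected(self):
        rows = [("A", "gout", 10.0, 0, 0), ("A", "censor", 900.0, 0, 1)]
        with pytest.raises(ValueError, match="unknown"):
            classify_events(_events_frame(rows))


class TestKaplanMeier:
    def test_no_events_gives_unit_survival(self):
        res = km_by_group(np.array([1.0, 2, 3, 4]), np.zeros(4, int), np.zeros(4, int))
        assert (res.curves[0]["estimate"] == 1.0).all()

    def test_hand_product_limit(self):
        # times {1,2,3} all events: S = 2/3, 1/3, 0
        res = km_by_group(np.array([1.0, 2, 3]), np.ones(3, int), np.zeros(3, int))
        curve = res.curves[0].set_index("time")["estimate"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_product_limit(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(5, 50).round(1)
        e = rng.integers(0, 2, 50)
        res = km_by_group(t, e, np.zeros(50, int))
        curve = res.curves[0].set_index("time")["estimate"]
        for time, surv in km_brute(t, e):
            assert curve.loc[time] == pytest.approx(surv, abs=1e-12)

    def test_single_group_gives_curves_without_tests(self):
        t = np.array([1.0, 2, 3])
        res = km_by_group(t, np.ones(3, int), np.array(["a", "a", "a"]))
        assert list(res.curves) == ["a"]
        assert np.isnan(res.omnibus_p)
        assert res.pairwise.empty

    def test_identical_exponential_groups_rarely_reject(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            t = rng.exponential(10, 100)
            groups = np.repeat([0, 1], 50)
            res = km_by_group(t, np.ones(100, int), groups)
            rejections += res.omnibus_p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rejections / n_sims - 0.05) < 3 * se


class TestNelsonAalen:
    def test_no_events_zero_hazard(self):
        res = cumulative_hazard_by_group(
            np.array([1.0, 2, 3]), np.zeros(3, int), np.zeros(3, int)
        )
        assert (res.curves[0]["estimate"] == 0.0).all()

    def test_matches_brute_force_step_sum(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(4, 40).round(1)
        e = rng.integers(0, 2, 40)
        res = cumulative_hazard_by_group(t, e, np.zeros(40, int))
        curve = res.curves[0].set_index("time")["estimate"]
        for time, haz in nelson_aalen_brute(t, e):
            assert curve.loc[time] == pytest.approx(haz, abs=1e-12)

    def test_exponential_rate_recovered(self):
        # closed form: cumulative hazard of Exp(lam) is lam * t
        lam, n = 0.25, 5000
        rng = np.random.default_rng(5)
        t = rng.exponential(1 / lam, n)
        res = cumulative_hazard_by_group(t, np.ones(n, int), np.zeros(n, int))
        curve = res.curves[0]
        for t_eval in (1.0, 2.0, 4.0):
            est = curve.loc[curve["time"] <= t_eval, "estimate"].iloc[-1]
            se = np.sqrt(lam * t_eval / n)  # MC-scale standard error
            assert abs(est - lam * t_eval) < 3 * se + 0.02

    def test_planted_rate_ordering_across_groups(self, planted_cohort, planted_outcomes):
        frame = planted_outcomes.frame
        truth = planted_cohort.truth_labels.loc[frame.index].to_numpy()
        res = cumulative_hazard_by_group(
            frame["denovo_time_years"].to_numpy(),
            frame["denovo_event"].to_numpy(),
            truth,
        )
        ends = {g: c["estimate"].iloc[-1] for g, c in res.curves.items()}
        # restrict to a common horizon: compare at 10 years
        at10 = {
            g: c.loc[c["time"] <= 10, "estimate"].iloc[-1] for g, c in res.curves.items()
        }
        assert at10[0] < at10[1] < at10[2] < at10[3]
        del ends


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_adjustment_matches_textbook_recursion(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(15)
        adjusted = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjusted, bh_brute(list(p)), atol=1e-12)

    def test_adjusted_at_least_raw_and_rank_monotone(self, planted_outcomes, planted_model):
        frame = planted_outcomes.frame.loc[planted_model.labels.index]
        res = km_by_group(
            frame["os_time_years"].to_numpy(),
            frame["death"].to_numpy(),
            planted_model.labels.to_numpy(),
        )
        pw = res.pairwise.sort_values("p_raw")
        assert (pw["p_bh"].to_numpy() >= pw["p_raw"].to_numpy() - 1e-15).all()
        assert (np.diff(pw["p_bh"].to_numpy()) >= -1e-15).all()


class TestCox:
    def test_binary_covariate_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.1 * 2.0**x))
        c = rng.exponential(8, n)
        df = pd.DataFrame({"t": np.minimum(t, c), "e": (t <= c).astype(int), "x": x})
        est = cox_hr(df, "t", "e", ["x"])[0]
        assert 1.8 <= est.hr <= 2.2
        assert est.ci95[0] <= 2.0 <= est.ci95[1]

    def test_null_covariate_confidence_interval_covers_one(self):
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(50):
            n = 400
            x = rng.integers(0, 2, n)
            t = rng.exponential(5, n)
            df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": x})
            est = cox_hr(df, "t", "e", ["x"])[0]
            covered += est.ci95[0] <= 1.0 <= est.ci95[1]
        assert covered >= 40  # ~95% nominal coverage

    def test_duplicated_covariate_raises_rank_error(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.integers(0, 2, n)
        df = pd.DataFrame(
            {"t": rng.exponential(5, n), "e": np.ones(n, int), "x": x, "x2": x}
        )
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            cox_hr(df, "t", "e", ["x", "x2"])

    def test_hazard_estimate_validates_interval(self):
        with pytest.raises(ValueError):
            HazardEstimate("x", hr=2.0, ci95=(2.5, 3.0), p=0.01)


class TestChi2Enrichment:
    def test_extreme_table(self):
        labels = np.repeat([0, 1], 50)
        outcome = (labels == 0).astype(int)
        res = chi2_enrichment(labels, outcome)
        assert (res["p"] < 1e-10).all()

    def test_homogeneous_split_gives_unit_p(self):
        # equal rates in both halves -> chi2 = 0, p = 1
        labels = np.repeat([0, 1], 2316)
        outcome = np.tile(np.concatenate([np.ones(443, int), np.zeros(1873, int)]), 2)
        res = chi2_enrichment(labels, outcome)
        np.testing.assert_allclose(res["chi2"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-12)

    def test_wilson_interval_matches_hand_formula(self):
        labels = np.repeat([0, 1], 100)
        rng = np.random.default_rng(9)
        outcome = rng.integers(0, 2, 200)
        res = chi2_enrichment(labels, outcome)
        for _, row in res.iterrows():
            lo, hi = wilson_interval_brute(int(row["n_positive"]), int(row["n"]))
            assert row["rate_lo95"] == pytest.approx(lo, abs=1e-9)
            assert row["rate_hi95"] == pytest.approx(hi, abs=1e-9)

    def test_null_p_values_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200)        :
            labels = rng.integers(0, 2, 300)
            outcome = rng.random(300) < 0.3
            res = chi2_enrichment(labels, outcome.astype(int))
            pvals.append(res["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPeriodBreakdown:
    @staticmethod
    def _outcomes(rows):
        frame = pd.DataFrame(rows).set_index("patient_id")
        from psnrisk.outcomes import OutcomeTable

        return OutcomeTable(frame=frame)

    def test_all_events_in_first_period(self):
        rows = [
            {
                "patient_id": f"P{i}",
                "denovo_event": 1,
                "denovo_time_years": 0.5,
                "death": 0,
                "followup_years": 10.0,
            }
            for i in range(20)
        ]
        out = self._outcomes(rows)
        labels = pd.Series(1, index=out.frame.index)
        res = period_breakdown(out, labels)
        dn = res[res["endpoint"] == "de_novo_ctrcd"].set_index("period")
        assert dn.loc["0-1", "percent"] == 100.0
        assert (dn.drop("0-1")["percent"] == 0.0).all()

    def test_periods_partition_events_exactly(self, planted_outcomes, planted_model):
        res = period_breakdown(planted_outcomes, planted_model.labels)
        frame = planted_outcomes.frame.loc[planted_model.labels.index]
        for lev in sorted(planted_model.labels.unique()):
            sub = res[(res["cluster"] == lev) & (res["endpoint"] == "de_novo_ctrcd")]
            cluster_ids = planted_model.labels.index[planted_model.labels == lev]
            n_events = int(frame.loc[cluster_ids, "denovo_event"].sum())
            assert sub["count"].sum() == n_events  # periods tile the horizon

    def test_overlapping_periods_rejected(self, planted_outcomes, planted_model):
        with pytest.raises(ValueError, match="disjoint"):
            period_breakdown(
                planted_outcomes, planted_model.labels, periods=((0, 5), (5, 10))
            )

    def test_planted_high_hazard_group_leads_first_period(self, planted_cohort, planted_outcomes):
        truth = planted_cohort.truth_labels
        res = period_breakdown(planted_outcomes, truth)
        dn = res[(res["endpoint"] == "de_novo_ctrcd") & (res["period"] == "0-1")]
        rates = dn.set_index("cluster")["percent"]
        assert rates[3] > rates[0]  # hazard 0.20/yr vs 0.02/yr


class TestBiomarkerKm:
    def test_single_bin_gives_curves_only(self, planted_outcomes):
        bm = pd.Series(50.0, index=planted_outcomes.frame.index)
        with pytest.warns(UserWarning, match="empty"):
            res, hazards = biomarker_km(planted_outcomes, bm, NT_PROBNP_BINS)
        assert len(res.curves) == 1
        assert hazards == []

    def test_null_biomarker_hr_ci_contains_one(self):
        rng = np.random.default_rng(11)
        n = 2000
        from psnrisk.outcomes import OutcomeTable

        frame = pd.DataFrame(
            {
                "os_time_years": rng.exponential(5, n),
                "death": np.ones(n, int),
            },
            index=[f"P{i}" for i in range(n)],
        )
        out = OutcomeTable(frame=frame)
        bm = pd.Series(rng.uniform(0, 2000, n), index=frame.index)
        _, hazards = biomarker_km(out, bm, NT_PROBNP_BINS)
        for est in hazards:
            assert est.ci95[0] <= 1.0 <= est.ci95[1]

    def test_planted_biomarker_hazard_link_gives_monotone_hrs(
        self, planted_cohort, planted_outcomes
    ):
        # NT-proBNP level rises with the planted de novo hazard, so the HRs
        # across guideline bins must rise monotonically
        from psnrisk.preprocess import build_feature_matrix

        fm = build_feature_matrix(planted_cohort.measurements)
        bm = fm.values["nt_probnp__max"].dropna()
        _, hazards = biomarker_km(
            planted_outcomes,
            bm,
            NT_PROBNP_BINS,
            duration_col="denovo_time_years",
            event_col="denovo_event",
        )
        hrs = [est.hr for est in hazards]
        assert len(hrs) == 2
        assert 1.0 < hrs[0] < hrs[1]
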