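import numpy as np
import pandas as pd
import pytest

from compera_bpa.errors import (
    EmptyCohort,
    PolicyError,
    TimelineError,
    ValidationError,
)
from compera_bpa.longitudinal import (
    EventRecord,
    PatientTimeline,
    build_survival_table,
    contingency_percentages,
    detect_unsatisfactory_response,
    first_clinical_worsening,
    sessions_to_endpoint,
    stratum_elimination_session,
    transition_matrix,
)
from compera_bpa.synthetic_cohort import generate_cohort, recover_parameters


class TestUnsatisfactoryResponse:
    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [
            (800, 1600, True),    # exactly a 100% increase
            (1900, 1850, True),   # above the absolute threshold
            (500, 900, False),    # neither branch
            (100, 199.9, False),
            (900, 1800, True),    # threshold itself counts
        ],
    )
    def test_rule(self, baseline, followup, expected):
        assert detect_unsatisfactory_response(baseline, followup) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            detect_unsatisfactory_response(0, 500)


class TestFirstClinicalWorsening:
    def test_earliest_event_wins(self):
        tl = PatientTimeline(
            "p",
            [EventRecord("p", "ph_hospitalization", 5.0),
             EventRecord("p", "death", 9.0)],
            follow_up_months=16.0,
        )
        assert first_clinical_worsening(tl) == (5.0, True)

    def test_administrative_censoring(self):
        tl = PatientTimeline("p", [], follow_up_months=16.0)
        assert first_clinical_worsening(tl) == (16.0, False)

    def test_negative_event_time_rejected(self):
        tl = PatientTimeline(
            "p", [EventRecord("p", "death", -1.0)], follow_up_months=10.0
        )
        with pytest.raises(TimelineError):
            first_clinical_worsening(tl)

    def test_missing_horizon_rejected(self):
        with pytest.raises(TimelineError):
            first_clinical_worsening(PatientTimeline("p", []))

    def test_idempotence(self):
        """Feeding the composite endpoint its own output changes nothing."""
        tl = PatientTimeline(
            "p",
            [EventRecord("p", "rhf_worsening", 7.0),
             EventRecord("p", "death", 12.0)],
            follow_up_months=20.0,
        )
        t, obs = first_clinical_worsening(tl)
        reduced = PatientTimeline(
            "p", [EventRecord("p", "rhf_worsening", t)] if obs else [], t if not obs else 20.0
        )
        assert first_clinical_worsening(reduced) == (t, obs)

    def test_survival_table(self):
        events = pd.DataFrame(
            [
                {"patient_id": "a", "event_type": "death", "time_months": 4.0},
                {"patient_id": "b", "event_type": "rhf_worsening", "time_months": 30.0},
            ]
        )
        surv = build_survival_table(events, {"a": 20.0, "b": 20.0, "c": 12.0})
        surv = surv.set_index("patient_id")
        assert surv.loc["a", "time_months"] == 4.0 and surv.loc["a", "observed"]
        # event after the censoring horizon does not count
        assert surv.loc["b", "time_months"] == 20.0 and not surv.loc["b", "observed"]
        assert surv.loc["c", "time_months"] == 12.0 and not surv.loc["c", "observed"]


class TestTransitionMatrix:
    def test_hand_counted_toy_flows(self, toy_risk_table):
        tm = transition_matrix(toy_risk_table, "original-4S", (1, "pre"), (1, "post"))
        assert tm.n == 4
        assert tm.improved == 2 and tm.unchanged == 2 and tm.worsened == 0
        assert tm.counts.loc["low", "low"] == 1
        assert tm.counts.loc["intermediate-low", "low"] == 1
        assert tm.counts.loc["intermediate-high", "intermediate-low"] == 1
        assert tm.counts.loc["high", "high"] == 1
        edges = tm.to_edges()
        assert edges["count"].sum() == 4

    def test_identity_flow(self, toy_risk_table):
        same = toy_risk_table[toy_risk_table["timing"] == "pre"].copy()
        post = same.copy()
        post["timing"] = "post"
        tm = transition_matrix(pd.concat([same, post]), "original-4S",
                               (1, "pre"), (1, "post"))
        assert tm.improved == tm.worsened == 0
        assert np.trace(tm.counts.to_numpy()) == tm.n

    def test_conservation(self, small_cohort):
        from compera_bpa.longitudinal import score_cohort

        risk = score_cohort(small_cohort.assessments, small_cohort.config)
        tm = transition_matrix(risk, "hybrid-4S", (1, "pre"), (1, "post"))
        base = risk[(risk["session_index"] == 1) & (risk["timing"] == "pre")]
        for lab in tm.labels:
            assert tm.counts.loc[lab].sum() == (base["hybrid-4S"] == lab).sum()
        assert tm.counts.to_numpy().sum() == tm.n
        assert tm.improved + tm.unchanged + tm.worsened == tm.n

    def test_empty_overlap(self, toy_risk_table):
        with pytest.raises(EmptyCohort):
            transition_matrix(toy_risk_table, "original-4S", (1, "pre"), (9, "post"))

    def test_improved_fraction_tracks_generator_probability(self, small_cohort):
        """Among patients above low risk, one session improves the stratum
        with the generator's per-session probability (binomial error)."""
        rec = recover_parameters(small_cohort)
        p_true = small_cohort.config["generator"]["p_improve"]
        base = small_cohort.patients["true_baseline_stratum"] != "low"
        n_improvable = int(base.sum())
        tol = 3.5 * np.sqrt(p_true * (1 - p_true) / n_improvable)
        assert abs(rec["p_improve"] - p_true) < tol


class TestStratumElimination:
    def _risk(self, rows):
        rank = {"low": 1, "intermediate-low": 2, "intermediate-high": 3, "high": 4}
        return pd.DataFrame(
            [
                {
                    "patient_id": pid,
                    "session_index": s,
                    "timing": "pre",
                    "original-4S": lab,
                    "rank_original-4S": rank[lab],
                }
                for pid, s, lab in rows
            ]
        )

    def test_eliminated_at_third_session(self):
        risk = self._risk(
            [
                ("a", 1, "high"), ("a", 2, "intermediate-high"), ("a", 3, "low"),
                ("b", 1, "high"), ("b", 2, "high"), ("b", 3, "intermediate-low"),
                ("c", 1, "low"), ("c", 2, "low"), ("c", 3, "low"),
            ]
        )
        assert stratum_elimination_session(risk, "original-4S", "high") == 3

    def test_persistent_stratum_never_eliminated(self):
        risk = self._risk([("a", s, "high") for s in (1, 2, 3)])
        assert stratum_elimination_session(risk, "original-4S", "high") is None

    def test_carry_last_variant_differs_from_evaluated_only(self):
        # the high-risk patient drops out after session 1
        risk = self._risk(
            [("a", 1, "high"), ("b", 1, "low"), ("b", 2, "low"), ("b", 3, "low")]
        )
        assert stratum_elimination_session(
            risk, "original-4S", "high", mode="evaluated_only"
        ) == 2
        assert stratum_elimination_session(
            risk, "original-4S", "high", mode="carry_last"
        ) is None

    def test_matches_direct_recount_on_synthetic(self, small_cohort):
        from compera_bpa.longitudinal import score_cohort

        risk = score_cohort(small_cohort.assessments, small_cohort.config)
        got = stratum_elimination_session(risk, "original-4S", "high")
        pre = risk[risk["timing"] == "pre"]
        expect = None
        for s in range(1, int(pre["session_index"].max()) + 1):
            here = pre[pre["session_index"] == s]
            if len(here) and (here["original-4S"] == "high").sum() == 0:
                expect = s
                break
        assert got == expect

    def test_unknown_stratum(self, toy_risk_table):
        with pytest.raises(PolicyError):
            stratum_elimination_session(toy_risk_table, "original-4S", "extreme")


class TestSessionsToEndpoint:
    def _toy(self):
        rank = {"low": 1, "intermediate-low": 2, "intermediate-high": 3, "high": 4}
        rows = []

        def add(pid, s, timing, lab, mpap):
            rows.append(
                {
                    "patient_id": pid,
                    "session_index": s,
                    "timing": timing,
                    "original-4S": lab,
                    "rank_original-4S": rank[lab],
                    "mpap": mpap,
                }
            )

        # a: low after session 1 (post) -> 1 session
        add("a", 1, "pre", "intermediate-low", 45); add("a", 1, "post", "low", 38)
        # b: low first seen at pre-session 3 -> 2 sessions; mPAP<30 there too
        add("b", 1, "pre", "intermediate-high", 50); add("b", 1, "post", "intermediate-low", 40)
        add("b", 2, "pre", "intermediate-low", 36); add("b", 2, "post", "intermediate-low", 33)
        add("b", 3, "pre", "low", 28)
        # c: never reaches low; mPAP stays high
        add("c", 1, "pre", "high", 60); add("c", 1, "post", "intermediate-high", 55)
        add("c", 2, "pre", "intermediate-high", 52)
        # d: low at baseline -> ineligible for the low-risk endpoint
        add("d", 1, "pre", "low", 25)
        return pd.DataFrame(rows)

    def test_low_risk_counts(self):
        per_patient, summary = sessions_to_endpoint(self._toy(), "original-4S", "low_risk")
        pp = per_patient.set_index("patient_id")
        assert list(pp.index) == ["a", "b", "c"]  # d ineligible
        assert pp.loc["a", "sessions"] == 1
        assert pp.loc["b", "sessions"] == 2
        assert not pp.loc["c", "attained"]
        s = summary.set_index("baseline_stratum")
        assert s.loc["high", "n_non_attainers"] == 1

    def test_mpap_endpoint(self):
        per_patient, _ = sessions_to_endpoint(
            self._toy(), "original-4S", "mpap_lt_threshold", mpap_threshold=30.0
        )
        pp = per_patient.set_index("patient_id")
        # d (baseline 25) ineligible; a has no reassessment RHC
        assert "d" not in pp.index and "a" not in pp.index
        assert pp.loc["b", "attained"] and pp.loc["b", "sessions"] == 2
        assert not pp.loc["c", "attained"]

    def test_median_sessions_monotone_on_synthetic(self, small_cohort):
        """With stratum-ordered dynamics, patients starting at higher risk
        need at least as many sessions to reach low risk."""
        from compera_bpa.longitudinal import score_cohort

        risk = score_cohort(small_cohort.assessments, small_cohort.config)
        _, summary = sessions_to_endpoint(risk, "original-4S", "low_risk")
        med = summary.set_index("baseline_stratum")["median_sessions"].dropna()
        order = [l for l in ("intermediate-low", "intermediate-high", "high") if l in med.index]
        vals = [med[l] for l in order]
        assert vals == sorted(vals)

    def test_no_eligible_patients(self):
        df = self._toy()
        df = df[df["patient_id"] == "d"]
        with pytest.raises(EmptyCohort):
            sessions_to_endpoint(df, "original-4S", "low_risk")


class TestContingencyPercentages:
    def test_printed_ratio_examples(self):
        assert contingency_percentages([(43, 52)]) == [82.7]
        assert contingency_percentages([(0, 7)]) == [0.0]
        assert contingency_percentages([(1, 21)]) == [4.8]

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            contingency_percentages([(0, 0)])

    def test_events_exceeding_n(self):
        with pytest.raises(ValidationError):
            contingency_percentages([(5, 4)])
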