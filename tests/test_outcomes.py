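"""Composite responder endpoint: criteria, classification, deltas."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fapitbr.cohort import CohortConfig, generate_cohort
from fapitbr.outcomes import (
    CRITERION_IDS,
    ClinicalRecord,
    CriteriaConfig,
    CriterionResult,
    classify_cohort,
    classify_responder,
    delta_table,
    evaluate_criteria,
    records_from_frame,
)


def record(**kw):
    defaults = dict(patient_id="P1", hscrp_unit="mg/L")
    defaults.update(kw)
    return ClinicalRecord(**defaults)


def by_id(results):
    return {r.criterion_id: r for r in results}


class TestCriteria:
    def test_typical_responder_profile(self):
        # 55% NT-proBNP drop and one NYHA class improvement -> a, b met
        rec = record(
            nt_probnp_baseline=1000.0,
            nt_probnp_followup=450.0,
            nyha_baseline=3,
            nyha_followup=2,
        )
        res = by_id(evaluate_criteria(rec))
        assert res["a"].met and res["b"].met
        assert not any(res[c].met for c in "cde")
        assert classify_responder("P1", list(res.values())).responder

    def test_nt_probnp_strict_30pct_boundary(self):
        just_under = record(nt_probnp_baseline=1000.0, nt_probnp_followup=701.0)
        exactly = record(nt_probnp_baseline=1000.0, nt_probnp_followup=700.0)
        assert not by_id(evaluate_criteria(just_under))["a"].met  # 29.9% drop
        assert by_id(evaluate_criteria(exactly))["a"].met  # exactly 30%

    def test_lvef_eligibility_boundary(self):
        high = record(lvef_baseline=65.0, lvef_followup=75.0)
        assert not by_id(evaluate_criteria(high))["e"].eligible
        at_60 = record(lvef_baseline=60.0, lvef_followup=70.0)
        assert not by_id(evaluate_criteria(at_60))["e"].eligible  # strict < 60
        just_below = record(lvef_baseline=59.9, lvef_followup=64.9)
        r = by_id(evaluate_criteria(just_below))["e"]
        assert r.eligible and r.met  # exactly 5 points

    def test_hscrp_elevation_gate_and_units(self):
        low = record(hscrp_baseline=2.0, hscrp_followup=1.0)  # 2 mg/L: not elevated
        assert not by_id(evaluate_criteria(low))["c"].eligible
        high = record(hscrp_baseline=8.0, hscrp_followup=6.0)  # 25% drop
        r = by_id(evaluate_criteria(high))["c"]
        assert r.eligible and r.met
        # the same numbers in mg/dL are 10x larger in mg/L
        mgdl = record(
            hscrp_baseline=0.8, hscrp_followup=0.75, hscrp_unit="mg/dL"
        )  # 8 -> 7.5 mg/L: elevated, 6.25% drop -> not met
        r = by_id(evaluate_criteria(mgdl))["c"]
        assert r.eligible and not r.met

    def test_dyspnea_exact_category(self):
        assert by_id(evaluate_criteria(record(dyspnea_response="much better")))["d"].met
        assert not by_id(evaluate_criteria(record(dyspnea_response="somewhat better")))["d"].met

    def test_zero_baseline_ntprobnp_warns_and_ineligible(self):
        rec = record(nt_probnp_baseline=0.0, nt_probnp_followup=0.0)
        with pytest.warns(RuntimeWarning, match="NT-proBNP"):
            res = by_id(evaluate_criteria(rec))
        assert not res["a"].eligible

    def test_unit_required_with_hscrp(self):
        with pytest.raises(ValueError, match="hscrp_unit"):
            ClinicalRecord(patient_id="P1", hscrp_baseline=3.0)


class TestClassification:
    def test_counting_rule_boundaries(self):
        def results(n_met):
            return [
                CriterionResult(c, eligible=i < 4, met=i < n_met)
                for i, c in enumerate(CRITERION_IDS)
            ]

        assert classify_responder("P", results(2)).responder
        assert not classify_responder("P", results(1)).responder

    def test_no_eligible_criteria_is_nonresponder(self):
        results = [CriterionResult(c, False, False) for c in CRITERION_IDS]
        out = classify_responder("P", results)
        assert not out.responder and out.n_eligible == 0

    def test_wrong_count_raises(self):
        with pytest.raises(ValueError):
            classify_responder("P", [CriterionResult("a", True, True)])

    def test_exhaustive_against_counting_oracle(self):
        """All 3^5 eligibility/met states agree with brute-force counting."""
        states = list(itertools.product([(False, False), (True, False), (True, True)], repeat=5))
        assert len(states) == 243
        for combo in states:
            results = [
                CriterionResult(c, eligible, met)
                for c, (eligible, met) in zip(CRITERION_IDS, combo)
            ]
            out = classify_responder("P", results)
            oracle = sum(1 for eligible, met in combo if eligible and met) >= 2
            assert out.responder == oracle

    def test_order_invariance(self):
        results = [
            CriterionResult("a", True, True),
            CriterionResult("b", True, False),
            CriterionResult("c", False, False),
            CriterionResult("d", True, True),
            CriterionResult("e", True, False),
        ]
        base = classify_responder("P", results)
        for perm in itertools.permutations(results):
            assert classify_responder("P", list(perm)).responder == base.responder

    def test_met_requires_eligible(self):
        with pytest.raises(ValueError):
            CriterionResult("a", eligible=False, met=True)

    @settings(deadline=None, max_examples=60)
    @given(
        nt=st.floats(100, 5000),
        nt_fu=st.floats(50, 6000),
        nyha=st.integers(1, 4),
        nyha_fu=st.integers(1, 4),
        lvef=st.floats(30, 80),
        lvef_fu=st.floats(30, 85),
        improve_field=st.sampled_from(["nt", "nyha", "lvef"]),
    )
    def test_single_improvement_never_flips_responder_off(
        self, nt, nt_fu, nyha, nyha_fu, lvef, lvef_fu, improve_field
    ):
        rec = record(
            nt_probnp_baseline=nt,
            nt_probnp_followup=nt_fu,
            nyha_baseline=nyha,
            nyha_followup=nyha_fu,
            lvef_baseline=lvef,
            lvef_followup=lvef_fu,
        )
        before = classify_responder("P", evaluate_criteria(rec)).responder
        if improve_field == "nt":
            rec.nt_probnp_followup = nt_fu * 0.5
        elif improve_field == "nyha":
            rec.nyha_followup = max(1, nyha_fu - 1)
        else:
            rec.lvef_followup = min(100.0, lvef_fu + 10.0)
        after = classify_responder("P", evaluate_criteria(rec)).responder
        assert after or not before  # improvement never demotes


class TestCohortLevel:
    def test_missing_followup_excluded_not_classified(self):
        recs = [
            record(nt_probnp_baseline=1000.0),  # no follow-up at all
            record(
                patient_id="P2",
                nt_probnp_baseline=1000.0,
                nt_probnp_followup=500.0,
                nyha_baseline=3,
                nyha_followup=2,
            ),
        ]
        out = classify_cohort(recs)
        assert list(out["patient_id"]) == ["P2"]

    def test_delta_table_signs_and_missing(self):
        recs = [
            record(nt_probnp_baseline=1000.0, nt_probnp_followup=450.0),
            record(patient_id="P2", nt_probnp_baseline=800.0, nt_probnp_followup=800.0),
            record(patient_id="P3"),
        ]
        d = delta_table(recs)
        assert d.loc[0, "delta_nt_probnp_pct"] == pytest.approx(-55.0)
        assert d.loc[1, "delta_nt_probnp_pct"] == 0.0
        assert math.isnan(d.loc[2, "delta_nt_probnp_pct"])

    def test_synthetic_responders_mean_delta_matches_generator(self):
        """Responders are generated with NT-proBNP drops of 45-65%; the
        observed mean change recovers the configured -55% center."""
        table, _ = generate_cohort(CohortConfig(n=120, seed=21))
        d = delta_table(records_from_frame(table)).merge(
            table[["patient_id", "true_responder"]], on="patient_id"
        )
        resp = d[d["true_responder"] == True]["delta_nt_probnp_pct"]  # noqa: E712
        se = (65 - 45) / math.sqrt(12) / math.sqrt(len(resp))
        assert resp.mean() == pytest.approx(-55.0, abs=4 * se + 1.0)
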