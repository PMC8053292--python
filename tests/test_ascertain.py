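import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from migenv import ascertain
from migenv.ascertain import MPAConfig, classify_event, mpa_score, severity_outcomes

from conftest import make_events


def ev(event_type="encounter", code="G43.909", setting="outpatient", med=None):
    return {
        "event_type": event_type,
        "code": code,
        "care_setting": setting,
        "med_class": med,
    }


class TestClassifyEvent:
    def test_icd10_outpatient_encounter(self):
        assert classify_event(ev()) == "migraine_encounter"

    def test_icd9_prefix(self):
        assert classify_event(ev(code="346.90")) == "migraine_encounter"

    def test_case_insensitive(self):
        assert classify_event(ev(code="g43.1")) == "migraine_encounter"

    def test_triptan_fill(self):
        assert classify_event(ev("prescription", code="", med="triptan")) == "abortive_fill"

    def test_ergotamine_fill(self):
        assert classify_event(ev("prescription", code="", med="ergotamine")) == "abortive_fill"

    def test_nonmatching_prefix_is_other(self):
        assert classify_event(ev(code="G44.1")) == "other"

    def test_ed_setting(self):
        assert classify_event(ev(setting="emergency")) == "migraine_ed"

    def test_urgent_care_setting(self):
        assert classify_event(ev(setting="urgent_care")) == "migraine_urgent_care"

    def test_neurology_without_migraine_code(self):
        assert classify_event(ev(code="R51", setting="neurology")) == "neurology_visit"

    def test_problem_list(self):
        assert classify_event(ev("problem_list")) == "problem_list_migraine"

    def test_malformed_code_never_raises(self):
        assert classify_event({"event_type": "encounter", "code": None}) == "other"
        assert classify_event({"event_type": "encounter", "code": 3.14}) == "other"
        assert classify_event({}) == "other"


class TestMpaScore:
    def test_no_events(self):
        res = mpa_score([])
        assert res.score == 0 and not res.is_case and not res.severe

    def test_single_encounter_default_weights(self):
        # default formula by hand: 20 * min(1, 5) = 20 > 10
        res = mpa_score([ev()])
        assert res.score == 20 and res.is_case and not res.severe

    def test_cap_at_101_and_severe(self):
        # 5 encounters (100) + problem list (11) + 1 fill (15) = 126 -> 101
        events = [ev() for _ in range(5)]
        events.append(ev("problem_list"))
        events.append(ev("prescription", code="", med="triptan"))
        res = mpa_score(events)
        assert res.score == 101 and res.severe and res.is_case

    def test_component_caps(self):
        # encounters capped at 5, fills at 3
        events = [ev() for _ in range(9)] + [
            ev("prescription", code="", med="triptan") for _ in range(7)
        ]
        res = mpa_score(events)
        assert res.score == 101  # min(101, 100 + 45)
        assert res.component_counts == (9, 0, 7)

    def test_dataframe_input_matches_list(self):
        frame = make_events(
            [
                ("P1", "encounter", "G43.1", "outpatient", ""),
                ("P1", "prescription", "", "outpatient", "triptan"),
            ]
        )
        res = mpa_score(frame)
        assert res.score == 35

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["encounter", "prescription", "problem_list", "junk"]),
                st.sampled_from(["G43.909", "346.1", "G44.1", "", "x"]),
                st.sampled_from(
                    ["outpatient", "emergency", "urgent_care", "neurology", "inpatient"]
                ),
                st.sampled_from(["triptan", "ergotamine", "statin", None]),
            ),
            max_size=40,
        )
    )
    def test_score_bounded_fuzz(self, tuples):
        events = [ev(t, c, s, m) for t, c, s, m in tuples]
        res = mpa_score(events)
        assert 0 <= res.score <= 101
        assert res.is_case == (res.score > 10)
        assert res.severe == (res.score > 100)
        if res.severe:
            assert res.is_case

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.sampled_from(["enc", "fill"]),
            max_size=15,
        )
    )
    def test_monotone_in_scored_components(self, kinds):
        def build(ks):
            out = []
            for k in ks:
                out.append(ev() if k == "enc" else ev("prescription", code="", med="triptan"))
            return out

        base = mpa_score(build(kinds)).score
        assert mpa_score(build(kinds + ["enc"])).score >= base
        assert mpa_score(build(kinds + ["fill"])).score >= base

    def test_custom_config(self):
        cfg = MPAConfig(w_encounter=5, case_threshold=4)
        res = mpa_score([ev()], cfg)
        assert res.score == 5 and res.is_case


class TestSeverityOutcomes:
    def case_result(self):
        return mpa_score([ev()])

    def test_zero_events(self):
        out = severity_outcomes([], self.case_result(), person_years=2.0)
        assert out.neurology_visits_per_py == 0
        assert out.triptans_per_py == 0
        assert not out.any_migraine_ed

    def test_rate_arithmetic(self):
        events = [ev(code="R51", setting="neurology") for _ in range(3)]
        out = severity_outcomes(events, self.case_result(), person_years=1.5)
        assert out.neurology_visits_per_py == pytest.approx(2.0)

    def test_any_ed_regardless_of_py(self):
        events = [ev(setting="emergency")]
        out = severity_outcomes(events, self.case_result(), person_years=37.0)
        assert out.any_migraine_ed

    def test_non_case_rejected(self):
        not_case = mpa_score([])
        with pytest.raises(ValueError):
            severity_outcomes([], not_case, person_years=1.0)

    def test_nonpositive_py_rejected(self):
        with pytest.raises(ValueError):
            severity_outcomes([], self.case_result(), person_years=0.0)


class TestScoreCohort:
    def test_matches_per_patient_scoring(self):
        events = make_events(
            [
                ("A", "encounter", "G43.909", "outpatient", ""),
                ("A", "encounter", "346.1", "emergency", ""),
                ("B", "prescription", "", "outpatient", "triptan"),
                ("C", "encounter", "G44.1", "outpatient", ""),
            ]
        )
        out = ascertain.score_cohort(events, ["A", "B", "C", "D"]).set_index("patient_id")
        assert out.loc["A", "mpa_score"] == 40  # two scored encounters
        assert out.loc["B", "mpa_score"] == 15
        assert out.loc["C", "mpa_score"] == 0
        assert out.loc["D", "mpa_score"] == 0
        assert bool(out.loc["A", "is_case"]) and bool(out.loc["B", "is_case"])
        assert not bool(out.loc["C", "is_case"]) and not bool(out.loc["D", "is_case"])

    def test_generator_consistency(self, small_cohort):
        patients, events = small_cohort
        scored = ascertain.score_cohort(events, patients["patient_id"])
        merged = scored.merge(
            patients[["patient_id", "latent_case", "latent_severe"]], on="patient_id"
        )
        assert (merged["is_case"].astype(int) == merged["latent_case"]).all()
        assert (merged["severe"].astype(int) == merged["latent_severe"]).all()


def test_severity_table_counts(small_cohort):
    patients, events = small_cohort
    scored = ascertain.score_cohort(events, patients["patient_id"])
    table = ascertain.severity_table(scored, patients).set_index("patient_id")
    cases = patients[patients["latent_case"] == 1].set_index("patient_id")
    assert len(table) == len(cases)
    pd.testing.assert_series_equal(
        table["neurology_count"].astype(int),
        cases["neurology_count"].astype(int),
        check_names=False,
    )
    np.testing.assert_allclose(
        table["triptans_per_py"],
        cases["triptan_count"] / cases["person_years"],
    )
    assert (table["any_migraine_ed"].astype(int) == cases["any_ed_visit"]).all()


def test_mpa_config_from_yaml(tmp_path):
    p = tmp_path / "mpa.yaml"
    p.write_text("w_encounter: 10\ncap_encounter: 2\nencounter_classes: [migraine_encounter]\n")
    cfg = MPAConfig.from_yaml(p)
    assert cfg.w_encounter == 10 and cfg.cap_encounter == 2
    assert cfg.encounter_classes == ("migraine_encounter",)
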