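"""NSD-ISS staging rules, HC eligibility, conversion labeling, transitions."""

import numpy as np
import pandas as pd
import pytest

from iivd.errors import UnstageableError
from iivd.staging import (
    assign_stage,
    assign_stages,
    hc_eligibility,
    label_conversion,
    transition_counts,
)


def _record(**kwargs):
    base = {
        "participant_id": "P1",
        "saa_positive": True,
        "dat_deficit": False,
        "hyposmia": True,
        "rbdsq": 2.0,
        "updrs3": 4.0,
        "functional_impairment": "none",
        "moca": 28.0,
    }
    base.update(kwargs)
    return base


class TestAssignStage:
    def test_saa_positive_dat_deficit_no_impairment_is_2b(self):
        stage, reasons = assign_stage(_record(dat_deficit=True))
        assert stage == "2B"
        assert "dat:deficit" in reasons

    def test_slight_impairment_is_3plus_regardless_of_dat(self):
        stage, reasons = assign_stage(
            _record(dat_deficit=False, functional_impairment="slight")
        )
        assert stage == "3plus"
        assert "impairment:slight" in reasons

    def test_saa_negative_is_hc_candidate(self):
        stage, _ = assign_stage(_record(saa_positive=False, hyposmia=False, moca=28))
        assert stage == "HC-eligible"

    def test_saa_positive_without_signs_is_stage_1(self):
        stage, reasons = assign_stage(
            _record(hyposmia=False, rbdsq=1.0, updrs3=0.0)
        )
        assert stage == "1"
        assert "signs:none" in reasons

    def test_missing_saa_is_unstageable(self):
        with pytest.raises(UnstageableError):
            assign_stage(_record(saa_positive=None))

    def test_missing_dat_for_stage2_candidate_is_unstageable(self):
        with pytest.raises(UnstageableError):
            assign_stage(_record(dat_deficit=None))

    def test_vectorized_agrees_with_scalar(self, default_cohort):
        sample = default_cohort.sample(300, random_state=0)
        fast = assign_stages(sample)
        slow_stages = []
        for rec in sample.to_dict("records"):
            try:
                slow_stages.append(assign_stage(rec)[0])
            except UnstageableError:
                slow_stages.append(None)
        assert list(fast["stage"]) == slow_stages


class TestHCEligibility:
    def _visits(self, moca0, moca1):
        base = _record(saa_positive=False, hyposmia=False, moca=moca0)
        year1 = None if moca1 is None else {"moca": moca1}
        return base, year1

    def test_threshold_pass(self):
        ok, reasons = hc_eligibility(*self._visits(27, 26))
        assert ok and not reasons

    def test_three_point_decline_fails(self):
        ok, reasons = hc_eligibility(*self._visits(30, 27))
        assert not ok and "hc:moca-decline>2" in reasons

    def test_baseline_26_fails_regardless(self):
        ok, reasons = hc_eligibility(*self._visits(26, 30))
        assert not ok and "hc:baseline-moca<27" in reasons

    def test_missing_year1_moca_fails_with_reason(self):
        ok, reasons = hc_eligibility(*self._visits(28, None))
        assert not ok and "hc:year1-moca-missing" in reasons

    def test_hyposmia_or_positive_saa_fail(self):
        base, y1 = self._visits(28, 28)
        ok, reasons = hc_eligibility({**base, "hyposmia": True}, y1)
        assert not ok and "hc:hyposmia" in reasons
        ok, reasons = hc_eligibility({**base, "saa_positive": True}, y1)
        assert not ok and "hc:saa-positive" in reasons


def _six_subject_fixture(registry):
    """Hand-built cohort: 4 followed Stage-2 subjects, 1 out-of-window, 1 HC."""
    rows = []

    def add(pid, vidx, offset, saa, dat, imp, complete=True):
        row = {
            "participant_id": pid,
            "visit_index": vidx,
            "visit_offset_years": offset,
            "age": 65.0, "sex": "M", "education": 16.0,
            "updrs3": 5.0, "hoehn_yahr": 0.0, "scopa_aut": 8.0, "gds15": 1.0,
            "quip": 0.0, "stai_state": 50.0, "upsit": 20.0, "ess": 5.0,
            "rbdsq": 6.0, "moca": 27.0,
            "saa_positive": saa, "dat_deficit": dat, "hyposmia": True,
            "functional_impairment": imp,
        }
        for name in registry.names:
            row[name] = 50.0 if complete else np.nan
        rows.append(row)

    add("s1", 0, 0.0, True, False, "none"); add("s1", 1, 1.0, True, False, "none")
    add("s2", 0, 0.0, True, False, "none"); add("s2", 1, 1.1, True, False, "slight")
    add("s3", 0, 0.0, True, True, "none");  add("s3", 1, 0.9, True, True, "none")
    add("s4", 0, 0.0, True, True, "none");  add("s4", 1, 1.2, True, True, "greater")
    add("s5", 0, 0.0, True, False, "none"); add("s5", 1, 1.6, True, False, "none")
    add("h1", 0, 0.0, False, None, "none"); add("h1", 1, 1.0, False, None, "none")
    df = pd.DataFrame(rows)
    df["saa_positive"] = df["saa_positive"].astype("boolean")
    df["dat_deficit"] = df["dat_deficit"].astype("boolean")
    return df


class TestConversionLabeling:
    def test_hand_counted_outcomes_and_transitions(self, registry):
        cohort = _six_subject_fixture(registry)
        staged = assign_stages(cohort)
        outcomes = label_conversion(staged, cohort, registry)
        out = outcomes.set_index("participant_id")
        assert len(out) == 5  # h1 is not Stage 2 at baseline
        assert bool(out.loc["s2", "converted"]) is True  # 2A -> 3plus
        assert bool(out.loc["s1", "converted"]) is False  # 2A -> 2A
        assert bool(out.loc["s4", "converted"]) is True  # 2B -> 3plus
        assert not out.loc["s5", "followed"]  # 1.6 y outside the window
        assert pd.isna(out.loc["s5", "converted"])

        table = transition_counts(outcomes)
        # hand count: 2A -> {2A:1, 3plus:1}; 2B -> {2B:1, 3plus:1}
        assert table.loc["2A", "2A"] == 1 and table.loc["2A", "3plus"] == 1
        assert table.loc["2B", "2B"] == 1 and table.loc["2B", "3plus"] == 1
        assert table.to_numpy().sum() == out["followed"].sum()

    def test_all_stable_cohort_gives_diagonal_table(self, registry):
        cohort = _six_subject_fixture(registry)
        cohort["functional_impairment"] = "none"
        staged = assign_stages(cohort)
        table = transition_counts(label_conversion(staged, cohort, registry))
        off_diag = table.to_numpy() - np.diag(np.diag(table.to_numpy()))
        assert (off_diag == 0).all()

    def test_incomplete_year1_battery_not_followed(self, registry):
        cohort = _six_subject_fixture(registry)
        cohort.loc[
            (cohort.participant_id == "s1") & (cohort.visit_index == 1),
            registry.names[0],
        ] = np.nan
        staged = assign_stages(cohort)
        out = label_conversion(staged, cohort, registry).set_index("participant_id")
        assert not out.loc["s1", "followed"]


class TestAnalysisSetInvariants:
    def test_no_overlap_between_hc_and_stage2_sets(self, default_bundle):
        assert not set(default_bundle["hc_ids"]) & set(default_bundle["stage2_ids"])

    def test_transition_row_sums_equal_followed(self, default_bundle):
        out = default_bundle["outcomes"]
        table = default_bundle["transitions"]
        assert table.to_numpy().sum() == int(out["followed"].sum())
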