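"""Extraction-engine field rules against examples and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from carepath_qi.extraction_engine import (
    derive_rt_window,
    derive_systemic_window,
    detect_physiotherapy,
    determine_treatment_start,
    extract_abstract,
    extract_dataset,
    select_pretreatment_mdt,
    select_referral_date,
)
from carepath_qi.synthetic_ehr import derive_truth_abstract
from carepath_qi.types import EVENT_COLUMNS, EventType, ExtractionRules, MdtSelection
from conftest import random_events


def make_events(*specs):
    """specs: (event_type, day[, attrs]) relative to 2020-01-01."""
    rows = []
    for spec in specs:
        et, day = spec[0], spec[1]
        attrs = spec[2] if len(spec) > 2 else {}
        rows.append(
            {
                "patient_id": "X",
                "event_type": et.value,
                "event_date": pd.Timestamp("2020-01-01") + pd.Timedelta(days=day),
                "setting": "outpatient",
                "planned_flag": attrs.pop("planned", True),
                "attributes": attrs,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def day(n):
    return pd.Timestamp("2020-01-01") + pd.Timedelta(days=n)


# ---------------------------------------------------------------------------
# field-rule examples


def test_referral_date_is_earliest_scheduling_order():
    ev = make_events((EventType.SCHEDULING_ORDER, 3), (EventType.SCHEDULING_ORDER, 10))
    assert select_referral_date(ev) == day(3)


def test_referral_date_ignores_scanned_letter():
    """A scanned PDF referral letter is invisible to structured extraction."""
    ev = make_events((EventType.SCANNED_REFERRAL_LETTER, 1, {"referral_date": "2020-01-01"}))
    assert select_referral_date(ev) is None


def test_treatment_start_prefers_preceding_surgery():
    ev = make_events((EventType.SURGERY, 20), (EventType.RT_FRACTION, 40))
    assert determine_treatment_start(ev) == (day(20), "surgery")


def test_treatment_start_same_day_tiebreak_and_empty():
    ev = make_events((EventType.RT_FRACTION, 20), (EventType.SURGERY, 20))
    assert determine_treatment_start(ev) == (day(20), "surgery")
    assert determine_treatment_start(make_events()) is None


def test_pretreatment_mdt_rule_divergence_is_7_days():
    """Two weekly MDTs before treatment: the engine's last-before-treatment
    rule and the abstractor's first-after-diagnosis rule differ by 7 days."""
    ev = make_events(
        (EventType.INITIAL_CONSULT, 5),
        (EventType.MDT_MEETING, 10),
        (EventType.MDT_MEETING, 17),
        (EventType.SURGERY, 20),
    )
    assert select_pretreatment_mdt(ev, day(20)) == day(17)
    alt = ExtractionRules(mdt_selection=MdtSelection.FIRST_AFTER_DIAGNOSIS)
    assert select_pretreatment_mdt(ev, day(20), alt) == day(10)


def test_pretreatment_mdt_none_when_only_after_treatment():
    ev = make_events((EventType.MDT_MEETING, 25), (EventType.SURGERY, 20))
    assert select_pretreatment_mdt(ev, day(20)) is None


def test_same_day_mdt_policy():
    ev = make_events((EventType.MDT_MEETING, 20), (EventType.SURGERY, 20))
    assert select_pretreatment_mdt(ev, day(20)) is None
    lax = ExtractionRules(same_day_strict=False)
    assert select_pretreatment_mdt(ev, day(20), lax) == day(20)


def test_rt_window_single_fraction_and_empty():
    assert derive_rt_window(make_events((EventType.RT_FRACTION, 7))) == (day(7), day(7))
    assert derive_rt_window(make_events()) is None


def test_systemic_window_cutoff_excludes_second_round():
    ev = make_events(*[(EventType.SYSTEMIC_ADMIN, d) for d in (0, 21, 42, 200)])
    assert derive_systemic_window(ev, ExtractionRules(systemic_round_cutoff_weeks=6)) == (
        day(0),
        day(42),
    )


def test_systemic_window_without_cutoff_reproduces_naive_logic():
    ev = make_events(*[(EventType.SYSTEMIC_ADMIN, d) for d in (0, 21, 42, 200)])
    assert derive_systemic_window(ev, ExtractionRules(systemic_round_cutoff_weeks=None)) == (
        day(0),
        day(200),
    )


def test_cutoff_below_one_week_rejected():
    with pytest.raises(Exception):
        ExtractionRules(systemic_round_cutoff_weeks=0)


def test_physiotherapy_outpatient_only_is_invisible():
    ev = make_events((EventType.PHYSIO_OUTPATIENT_CONTACT, 30))
    assert detect_physiotherapy(ev) == (False, None)


def test_physiotherapy_inpatient_form_detected():
    ev = make_events((EventType.PHYSIO_INPATIENT_FORM, 30), (EventType.PHYSIO_INPATIENT_FORM, 40))
    assert detect_physiotherapy(ev) == (True, day(30))


# ---------------------------------------------------------------------------
# oracle equivalence on random small instances


def _oracle_referral(ev):
    d = [r.event_date for r in ev.itertuples() if r.event_type == "scheduling_order"]
    return min(d) if d else None


def _oracle_treatment(ev):
    prio = {"surgery": 0, "rt_fraction": 1, "systemic_admin": 2}
    cands = [
        (r.event_date, prio[r.event_type])
        for r in ev.itertuples()
        if r.event_type in prio
    ]
    if not cands:
        return None
    d, p = min(cands)
    return (d, ["surgery", "radiotherapy", "systemic"][p])


def _oracle_mdt(ev, ts):
    if ts is None:
        return None
    d = [r.event_date for r in ev.itertuples() if r.event_type == "mdt_meeting" and r.event_date < ts]
    return max(d) if d else None


def _oracle_systemic(ev, cutoff_weeks):
    """O(n^2) reachability closure: an admission belongs to the first round
    if it can be reached from the first admission through gaps <= cutoff."""
    d = sorted(r.event_date for r in ev.itertuples() if r.event_type == "systemic_admin")
    if not d:
        return None
    reach = {d[0]}
    changed = True
    while changed:
        changed = False
        for x in d:
            if x not in reach and any(
                pd.Timedelta(0) <= x - y <= pd.Timedelta(weeks=cutoff_weeks) for y in reach
            ):
                reach.add(x)
                changed = True
    return (d[0], max(reach))


def test_field_rules_match_brute_force_on_random_instances(rng):
    rules = ExtractionRules(systemic_round_cutoff_weeks=6)
    for _ in range(200):
        ev = random_events(rng)
        assert select_referral_date(ev) == _oracle_referral(ev)
        t = determine_treatment_start(ev)
        assert t == _oracle_treatment(ev)
        ts = t[0] if t else None
        if ts is not None:
            assert select_pretreatment_mdt(ev, ts, rules) == _oracle_mdt(ev, ts)
        assert derive_systemic_window(ev, rules) == _oracle_systemic(ev, 6)
        rt = [r.event_date for r in ev.itertuples() if r.event_type == "rt_fraction"]
        assert derive_rt_window(ev) == ((min(rt), max(rt)) if rt else None)
        forms = [r.event_date for r in ev.itertuples() if r.event_type == "physio_inpatient_form"]
        assert detect_physiotherapy(ev) == ((True, min(forms)) if forms else (False, None))


# ---------------------------------------------------------------------------
# composition


def test_extract_abstract_empty_events_all_null_dates_false_flags(identity_run):
    reg_row = next(identity_run["registry"].itertuples(index=False))
    row = extract_abstract(make_events().iloc[0:0], reg_row)
    from carepath_qi.types import DATE_VARS, FLAG_VARS

    assert all(row[v] is None for v in DATE_VARS)
    assert all(row[v] is False for v in FLAG_VARS)


def test_extract_abstract_full_pathway_fixture():
    """Field-by-field equality with a hand-derived expectation."""

    class Reg:
        patient_id, localization, intent = "X", "larynx", "curative"

    ev = make_events(
        (EventType.SCHEDULING_ORDER, 0),
        (EventType.SCANNED_REFERRAL_LETTER, 0, {"referral_date": "2019-12-30"}),
        (EventType.INITIAL_CONSULT, 6),
        (EventType.MDT_MEETING, 8),
        (EventType.SURGERY, 15, {"complication": True}),
        (EventType.NECK_DISSECTION, 15),
        (EventType.REOPERATION, 20, {"planned": False}),
        (EventType.RT_FRACTION, 50),
        (EventType.RT_FRACTION, 51),
        (EventType.SYSTEMIC_ADMIN, 50),
        (EventType.SYSTEMIC_ADMIN, 71),
        (EventType.DENTAL_CONSULT, 45),
        (EventType.PHYSIO_INPATIENT_FORM, 17),
    )
    row = extract_abstract(ev, Reg)
    assert row["date_referral"] == day(0)  # scheduling order, not the letter
    assert row["date_initial_visit"] == day(6)
    assert row["date_mdt_pretreat"] == day(8)
    assert row["date_surgery"] == day(15)
    assert (row["rt_start"], row["rt_end"]) == (day(50), day(51))
    assert (row["syst_start"], row["syst_end"]) == (day(50), day(71))
    assert (row["date_dental"], row["date_physio"]) == (day(45), day(17))
    assert row["surgical_treatment"] and row["neck_dissection"]
    assert row["complication_flag"] and row["unplanned_reop_flag"]


def test_extraction_idempotent_and_order_invariant(identity_run):
    log, registry = identity_run["events"], identity_run["registry"]
    a1 = extract_dataset(log, registry)
    a2 = extract_dataset(log, registry)
    pd.testing.assert_frame_equal(a1, a2)
    shuffled = log.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a3 = extract_dataset(shuffled, registry)
    pd.testing.assert_frame_equal(a1, a3)


def test_window_sanity(identity_run):
    aed = identity_run["aed"]
    both = aed["rt_start"].notna() & aed["rt_end"].notna()
    assert (aed.loc[both, "rt_start"] <= aed.loc[both, "rt_end"]).all()
    both = aed["syst_start"].notna() & aed["syst_end"].notna()
    assert (aed.loc[both, "syst_start"] <= aed.loc[both, "syst_end"]).all()


def test_identity_pipeline_extraction_equals_truth(identity_run):
    truth = derive_truth_abstract(identity_run["events"], identity_run["registry"])
    pd.testing.assert_frame_equal(identity_run["aed"], truth)


def test_events_without_registry_row_raise(identity_run):
    log = identity_run["events"].copy()
    log.loc[0, "patient_id"] = "GHOST"
    with pytest.raises(KeyError):
        extract_dataset(log, identity_run["registry"])


def test_icd10_exclusion_drops_patient(identity_run):
    registry = identity_run["registry"].copy()
    registry.loc[0, "icd10_code"] = "C61"  # prostate: not a head-and-neck code
    aed = extract_dataset(identity_run["events"], registry)
    assert registry.loc[0, "patient_id"] not in set(aed["patient_id"])
    assert len(aed) == len(registry) - 1
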