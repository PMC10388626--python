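"""Rule-based extraction of per-patient abstracts from a raw event log.

This module is the automated counterpart of manual chart abstraction: it
sees only the structured, coded events (appointments, procedure codes,
administrations, the inpatient physiotherapy form) and derives the flat
AED-style abstract from them.  Deliberate blind spots of real extraction
logic are reproduced faithfully:

* the referral date is proxied by the first scheduling order — the actual
  referral date lives in a scanned PDF the engine cannot read;
* physiotherapy is detected only through the inpatient form, so
  outpatient/external contacts are invisible;
* the systemic-therapy end date is bounded by a configurable round cutoff
  (disable it and the engine reproduces the naive last-administration
  logic that picks up a later round of treatment).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .types import EventType, ExtractionRules, MdtSelection
from .synthetic_ehr import _finalize_abstracts, group_events


def _records(events) -> list:
    """Accept a DataFrame or a pre-grouped list of event records."""
    if isinstance(events, pd.DataFrame):
        return list(events.itertuples(index=False))
    return events


def _dates(events, etype: EventType) -> list[pd.Timestamp]:
    return sorted(r.event_date for r in _records(events) if r.event_type == etype.value)


def select_referral_date(events: pd.DataFrame) -> Optional[pd.Timestamp]:
    """Earliest scheduling order; scanned referral letters are never read."""
    d = _dates(events, EventType.SCHEDULING_ORDER)
    return d[0] if d else None


def determine_treatment_start(
    events: pd.DataFrame,
) -> Optional[tuple[pd.Timestamp, str]]:
    """Earliest treatment event and its modality.

    Ties on the same day resolve surgery > radiotherapy > systemic (a
    same-day surgical procedure takes precedence as phase onset).
    """
    candidates = []
    for etype, modality in [
        (EventType.SURGERY, "surgery"),
        (EventType.RT_FRACTION, "radiotherapy"),
        (EventType.SYSTEMIC_ADMIN, "systemic"),
    ]:
        d = _dates(events, etype)
        if d:
            candidates.append((d[0], modality))
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c[0], ["surgery", "radiotherapy", "systemic"].index(c[1])))


def select_pretreatment_mdt(
    events: pd.DataFrame,
    treatment_start: pd.Timestamp,
    rules: Optional[ExtractionRules] = None,
) -> Optional[pd.Timestamp]:
    """MDT date used for the pre-treatment quality indicators.

    Default rule: the last MDT before treatment start (strictly before,
    unless ``rules.same_day_strict`` is off).  The alternative
    ``first_after_diagnosis`` rule takes the earliest MDT on/after the
    initial consult — the choice a chart abstractor typically makes.
    """
    rules = rules or ExtractionRules()
    mdts = _dates(events, EventType.MDT_MEETING)
    if not mdts:
        return None
    if rules.mdt_selection is MdtSelection.LAST_BEFORE_TREATMENT:
        if treatment_start is None:
            return None
        if rules.same_day_strict:
            qualifying = [d for d in mdts if d < treatment_start]
        else:
            qualifying = [d for d in mdts if d <= treatment_start]
        return qualifying[-1] if qualifying else None
    consults = _dates(events, EventType.INITIAL_CONSULT)
    start = consults[0] if consults else None
    qualifying = [d for d in mdts if start is None or d >= start]
    return qualifying[0] if qualifying else None


def derive_rt_window(
    events: pd.DataFrame,
) -> Optional[tuple[pd.Timestamp, pd.Timestamp]]:
    d = _dates(events, EventType.RT_FRACTION)
    return (d[0], d[-1]) if d else None


def derive_systemic_window(
    events: pd.DataFrame, rules: Optional[ExtractionRules] = None
) -> Optional[tuple[pd.Timestamp, pd.Timestamp]]:
    """Start/end of the first round of systemic therapy.

    The end date is the last administration of the maximal run beginning at
    the first administration in which consecutive administrations are at
    most ``systemic_round_cutoff_weeks`` apart.  With the cutoff disabled
    (``None``) the end is simply the last administration on record, which
    can belong to a later round of treatment.
    """
    rules = rules or ExtractionRules()
    d = _dates(events, EventType.SYSTEMIC_ADMIN)
    if not d:
        return None
    if rules.systemic_round_cutoff_weeks is None:
        return (d[0], d[-1])
    max_gap = pd.Timedelta(weeks=rules.systemic_round_cutoff_weeks)
    end = d[0]
    for nxt in d[1:]:
        if nxt - end > max_gap:
            break
        end = nxt
    return (d[0], end)


def detect_physiotherapy(
    events: pd.DataFrame,
) -> tuple[bool, Optional[pd.Timestamp]]:
    """Physiotherapy detection via the inpatient form only."""
    d = _dates(events, EventType.PHYSIO_INPATIENT_FORM)
    return (True, d[0]) if d else (False, None)


def is_included(icd10_code: str, rules: Optional[ExtractionRules] = None) -> bool:
    rules = rules or ExtractionRules()
    code = str(icd10_code)
    return any(code.startswith(prefix) for prefix in rules.icd10_inclusion)


def extract_abstract(
    events: pd.DataFrame, registry_row, rules: Optional[ExtractionRules] = None
) -> dict:
    """Compose all field rules into one abstract row for one patient."""
    rules = rules or ExtractionRules()
    events = _records(events)
    consults = _dates(events, EventType.INITIAL_CONSULT)
    surgery_dates = _dates(events, EventType.SURGERY)
    treat = determine_treatment_start(events)
    treat_start = treat[0] if treat else None
    rt = derive_rt_window(events)
    syst = derive_systemic_window(events, rules)
    dental = _dates(events, EventType.DENTAL_CONSULT)
    physio_flag, physio_date = detect_physiotherapy(events)
    surgical_types = (EventType.SURGERY.value, EventType.REOPERATION.value)
    complication = any(
        r.attributes.get("complication") for r in events if r.event_type in surgical_types
    )
    unplanned_reop = any(
        not r.planned_flag for r in events if r.event_type == EventType.REOPERATION.value
    )
    return {
        "patient_id": registry_row.patient_id,
        "localization": registry_row.localization,
        "intent": registry_row.intent,
        "date_referral": select_referral_date(events),
        "date_initial_visit": consults[0] if consults else None,
        "date_mdt_pretreat": select_pretreatment_mdt(events, treat_start, rules),
        "date_surgery": surgery_dates[0] if surgery_dates else None,
        "rt_start": rt[0] if rt else None,
        "rt_end": rt[1] if rt else None,
        "syst_start": syst[0] if syst else None,
        "syst_end": syst[1] if syst else None,
        "date_dental": dental[0] if dental else None,
        "date_physio": physio_date,
        "surgical_treatment": len(surgery_dates) > 0,
        "neck_dissection": len(_dates(events, EventType.NECK_DISSECTION)) > 0,
        "rt_flag": rt is not None,
        "systemic_flag": syst is not None,
        "dental_flag": len(dental) > 0,
        "physio_flag": physio_flag,
        "complication_flag": bool(complication),
        "unplanned_reop_flag": bool(unplanned_reop),
    }


def extract_dataset(
    log: pd.DataFrame,
    registry: pd.DataFrame,
    rules: Optional[ExtractionRules] = None,
) -> pd.DataFrame:
    """Extract an AED-style abstract table for every included patient.

    Patients are included by ICD-10 prefix; a patient with events but no
    registry row raises, since extraction relies on the registry's coded
    diagnosis fields.
    """
    rules = rules or ExtractionRules()
    known = set(registry["patient_id"])
    unknown = set(log["patient_id"]) - known
    if unknown:
        raise KeyError(f"events for patients absent from registry: {sorted(unknown)[:5]}")
    grouped = group_events(log)
    rows = []
    for reg_row in registry.itertuples(index=False):
        if not is_included(reg_row.icd10_code, rules):
            continue
        rows.append(extract_abstract(grouped.get(reg_row.patient_id, []), reg_row, rules))
    return _finalize_abstracts(rows)
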