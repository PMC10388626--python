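"""Synthetic head-and-neck-oncology EHR: cohort, event log, manual abstracts.

The generator emulates a single-center annual cohort moving through the
multidisciplinary care pathway (referral → initial consult → diagnostics →
weekly MDT → surgery and/or radiotherapy and/or systemic therapy →
follow-up contacts such as dental and physiotherapy consults).  From one
ground-truth event log it derives

* the event log handed to the extraction engine (optionally corrupted by an
  extraction-layer fault, :func:`apply_extraction_faults`), and
* a simulated manually abstracted dataset (:func:`derive_manual_abstract`)
  in the flat per-patient schema, with configurable missingness.

Discrepancy modes between the two are controlled by
:class:`~carepath_qi.types.DiscrepancyProfile`.  Input-side modes (a
referral letter whose written date precedes the scheduling order, an extra
pre-treatment MDT, outpatient-only physiotherapy, a second round of
systemic therapy) are materialized in the event log itself; the
abstraction- and extraction-side modes (field missingness, the systematic
1-day initial-visit error) are applied when deriving each dataset.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ABSTRACT_COLUMNS,
    DATE_VARS,
    EVENT_COLUMNS,
    REGISTRY_COLUMNS,
    DiscrepancyProfile,
    EventType,
    Histology,
    Intent,
    Localization,
    LOCALIZATION_ICD10,
    PathwayConfig,
    Setting,
    TumorOrder,
)

#: Localization mix of a typical annual cohort (manual counts 82, 66, 4, 14,
#: 60, 16, 17, 3 out of 262).
DEFAULT_LOCALIZATION_WEIGHTS: dict[Localization, float] = {
    Localization.ORAL_CAVITY: 82 / 262,
    Localization.OROPHARYNX: 66 / 262,
    Localization.NASOPHARYNX: 4 / 262,
    Localization.HYPOPHARYNX: 14 / 262,
    Localization.LARYNX: 60 / 262,
    Localization.NASAL_CAVITY: 16 / 262,
    Localization.SALIVARY_GLANDS: 17 / 262,
    Localization.UNKNOWN_PRIMARY: 3 / 262,
}

#: Default manual-abstraction missingness per variable, reflecting that a
#: registry abstractor leaves a handful of fields empty (rates on the order
#: of what a national cancer registry extract shows).
DEFAULT_MED_MISSINGNESS: dict[str, float] = {
    "date_referral": 1 / 262,
    "date_mdt_pretreat": 7 / 262,
    "intent": 1 / 262,
    "dental_flag": 73 / 262,
    "date_dental": 14 / 189,
    "date_physio": 3 / 43,
}

_ONE_DAY = pd.Timedelta(days=1)


def _rng_for(seed: int, index: int) -> np.random.Generator:
    # per-patient stream so output is invariant to patient processing order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _wait_days(rng: np.random.Generator, median: int, dispersion: float = 10.0) -> int:
    """Right-skewed waiting time in days with the given median.

    Negative-binomial day counts (mean set to the target median; the
    median of the truncated draw tracks it to within a day).  A median of
    0 falls back to a geometric with P(0) = 0.75.
    """
    if median <= 0:
        x = int(rng.geometric(0.75)) - 1
    else:
        p = dispersion / (dispersion + median)
        x = int(rng.negative_binomial(dispersion, p))
    return min(x, 6 * max(median, 1) + 10)


def _next_weekday(d: pd.Timestamp) -> pd.Timestamp:
    while d.weekday() >= 5:
        d += _ONE_DAY
    return d


def _next_mdt_day(d: pd.Timestamp, weekday: int) -> pd.Timestamp:
    return d + pd.Timedelta(days=(weekday - d.weekday()) % 7)


def generate_cohort(
    n_patients: int,
    localization_weights: Optional[Sequence[float]] = None,
    seed: int = 0,
    ineligible_fraction: float = 0.0,
) -> pd.DataFrame:
    """Generate a patient registry for one annual cohort.

    Parameters
    ----------
    n_patients
        Cohort size (>= 1).
    localization_weights
        Probability vector over the 8 localization categories (in the order
        of :class:`Localization`); defaults to the typical annual mix.
    seed
        RNG seed.
    ineligible_fraction
        Fraction of patients given a study-exclusion-triggering profile
        (carcinoma in situ, second primary, recurrence/residual disease,
        non-SCC histology, or palliative intent), spread evenly over those
        modes.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    locs = list(Localization)
    if localization_weights is None:
        weights = np.array([DEFAULT_LOCALIZATION_WEIGHTS[l] for l in locs])
    else:
        weights = np.asarray(localization_weights, dtype=float)
        if weights.shape != (len(locs),):
            raise ValueError(f"localization_weights must have length {len(locs)}")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("localization_weights must sum to 1")
    if not 0.0 <= ineligible_fraction <= 1.0:
        raise ValueError("ineligible_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    loc_idx = rng.choice(len(locs), size=n_patients, p=weights / weights.sum())

    exclusion_modes = [
        ("cis", Histology.CIS, TumorOrder.FIRST_PRIMARY, Intent.CURATIVE),
        ("second_primary", Histology.SCC, TumorOrder.SECOND_PRIMARY, Intent.CURATIVE),
        ("recurrence", Histology.SCC, TumorOrder.RECURRENCE, Intent.CURATIVE),
        ("non_scc", Histology.MELANOMA, TumorOrder.FIRST_PRIMARY, Intent.CURATIVE),
        ("palliative", Histology.SCC, TumorOrder.FIRST_PRIMARY, Intent.PALLIATIVE),
    ]
    rows = []
    width = max(4, len(str(n_patients)))
    for i in range(n_patients):
        loc = locs[int(loc_idx[i])]
        histology, order, intent = Histology.SCC, TumorOrder.FIRST_PRIMARY, Intent.CURATIVE
        if ineligible_fraction > 0 and rng.random() < ineligible_fraction:
            _, histology, order, intent = exclusion_modes[int(rng.integers(len(exclusion_modes)))]
        rows.append(
            {
                "patient_id": f"P{i:0{width}d}",
                "icd10_code": LOCALIZATION_ICD10[loc],
                "localization": loc.value,
                "histology": histology.value,
                "tumor_order": order.value,
                "intent": intent.value,
                "initial_consult_year": 0,  # filled by generate_event_log
            }
        )
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def generate_event_log(
    registry: pd.DataFrame,
    pathway: Optional[PathwayConfig] = None,
    seed: int = 0,
    profile: Optional[DiscrepancyProfile] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a ground-truth event log for every registry patient.

    Returns ``(events, registry)`` where the returned registry is a copy
    with ``initial_consult_year`` filled from the generated consult dates.

    The scheduling order is always the first recorded event.  The referral
    letter is scanned on the same day, but the referral date *written in
    the letter* (stored in the event's attribute bag, readable only by a
    human abstractor) may precede it by 1-3 days with probability
    ``profile.p_ref``.
    """
    if registry.empty:
        raise ValueError("registry must be non-empty")
    pathway = pathway or PathwayConfig()
    profile = profile or DiscrepancyProfile.identity()

    offsets = sorted(profile.referral_offset_days)
    offset_w = np.array([profile.referral_offset_days[k] for k in offsets], dtype=float)
    offset_w /= offset_w.sum()

    events: list[dict] = []
    consult_years: list[int] = []

    def emit(pid, etype, date, setting=Setting.OUTPATIENT, planned=True, **attrs):
        events.append(
            {
                "patient_id": pid,
                "event_type": etype.value,
                "event_date": date,
                "setting": setting.value,
                "planned_flag": planned,
                "attributes": attrs,
            }
        )

    for i, row in enumerate(registry.itertuples(index=False)):
        rng = _rng_for(seed, i)
        pid = row.patient_id

        t0 = _next_weekday(
            pd.Timestamp(pathway.year, 1, 1) + pd.Timedelta(days=int(rng.integers(3, 325)))
        )
        emit(pid, EventType.SCHEDULING_ORDER, t0)

        referral_written = t0
        if rng.random() < profile.p_ref:
            off = int(rng.choice(offsets, p=offset_w))
            referral_written = t0 - pd.Timedelta(days=off)
        emit(
            pid,
            EventType.SCANNED_REFERRAL_LETTER,
            t0,
            setting=Setting.EXTERNAL,
            referral_date=referral_written.date().isoformat(),
        )

        consult = _next_weekday(
            t0 + pd.Timedelta(days=_wait_days(rng, pathway.referral_to_consult_median))
        )
        emit(pid, EventType.INITIAL_CONSULT, consult)
        consult_years.append(int(consult.year))

        mdt1 = _next_mdt_day(
            consult + pd.Timedelta(days=_wait_days(rng, pathway.consult_to_mdt_median)),
            pathway.mdt_weekday,
        )
        emit(pid, EventType.MDT_MEETING, mdt1)

        ts = _next_weekday(
            mdt1 + _ONE_DAY + pd.Timedelta(days=_wait_days(rng, pathway.mdt_to_treatment_median))
        )
        # re-discussion in a second weekly MDT, still before treatment start
        if rng.random() < profile.extra_mdt_prob and mdt1 + pd.Timedelta(days=7) < ts:
            emit(pid, EventType.MDT_MEETING, mdt1 + pd.Timedelta(days=7))

        surgery = rng.random() < pathway.p_surgery
        neck_dissected = False
        rt_start: Optional[pd.Timestamp] = None
        syst_start: Optional[pd.Timestamp] = None

        if surgery:
            emit(
                pid,
                EventType.SURGERY,
                ts,
                setting=Setting.INPATIENT,
                complication=bool(rng.random() < pathway.p_complication),
            )
            if rng.random() < pathway.p_neck_dissection:
                neck_dissected = True
                emit(pid, EventType.NECK_DISSECTION, ts, setting=Setting.INPATIENT)
            if rng.random() < pathway.p_unplanned_reop:
                emit(
                    pid,
                    EventType.REOPERATION,
                    _next_weekday(ts + pd.Timedelta(days=int(rng.integers(2, 11)))),
                    setting=Setting.INPATIENT,
                    planned=False,
                )
            if rng.random() < pathway.p_adjuvant_rt_after_surgery:
                rt_start = _next_weekday(
                    ts
                    + pd.Timedelta(
                        days=7 + _wait_days(rng, pathway.surgery_to_adjuvant_median - 7)
                    )
                )
                if rng.random() < pathway.p_adjuvant_systemic:
                    syst_start = rt_start
        else:
            if rng.random() < pathway.p_rt_no_surgery:
                rt_start = ts
                if rng.random() < pathway.p_concurrent_systemic:
                    syst_start = ts
            else:
                syst_start = ts  # primary systemic treatment

        if rt_start is not None:
            n_frac = int(rng.integers(pathway.rt_fractions_min, pathway.rt_fractions_max + 1))
            d = rt_start
            for _ in range(n_frac):
                emit(pid, EventType.RT_FRACTION, d)
                d = _next_weekday(d + _ONE_DAY)
            if rng.random() < pathway.p_dental_before_rt:
                dd = rt_start - pd.Timedelta(days=int(rng.integers(3, 22)))
                if dd < consult:
                    dd = consult  # dental screening squeezed into the diagnostic phase
                dd = _next_weekday(dd)
                if dd < rt_start:
                    emit(pid, EventType.DENTAL_CONSULT, dd)

        last_admin: Optional[pd.Timestamp] = None
        if syst_start is not None:
            d = syst_start
            for _ in range(pathway.systemic_cycles):
                emit(pid, EventType.SYSTEMIC_ADMIN, d, setting=Setting.INPATIENT, round=1)
                last_admin = d
                d = _next_weekday(d + pd.Timedelta(days=pathway.systemic_cycle_days))
            if rng.random() < profile.second_systemic_round_prob:
                gap = int(
                    rng.integers(pathway.second_round_gap_min, pathway.second_round_gap_max + 1)
                )
                d = _next_weekday(last_admin + pd.Timedelta(days=gap))
                for _ in range(int(rng.integers(2, pathway.systemic_cycles + 1))):
                    emit(pid, EventType.SYSTEMIC_ADMIN, d, setting=Setting.INPATIENT, round=2)
                    d = _next_weekday(d + pd.Timedelta(days=pathway.systemic_cycle_days))

        p_physio = (
            pathway.p_physio_after_neck_dissection if neck_dissected else pathway.p_physio_other
        )
        if rng.random() < p_physio:
            pd_date = _next_weekday(ts + pd.Timedelta(days=int(rng.integers(1, 6))))
            if rng.random() < profile.physio_outpatient_prob:
                emit(pid, EventType.PHYSIO_OUTPATIENT_CONTACT, pd_date, setting=Setting.OUTPATIENT)
                if rng.random() < 0.5:
                    emit(
                        pid,
                        EventType.PHYSIO_EXTERNAL_REFERRAL,
                        pd_date,
                        setting=Setting.EXTERNAL,
                    )
            else:
                emit(pid, EventType.PHYSIO_INPATIENT_FORM, pd_date, setting=Setting.INPATIENT)

    log = pd.DataFrame(events, columns=EVENT_COLUMNS)
    out_registry = registry.copy()
    out_registry["initial_consult_year"] = consult_years
    return log, out_registry


def apply_extraction_faults(
    log: pd.DataFrame, profile: DiscrepancyProfile, seed: int = 0
) -> pd.DataFrame:
    """Return the raw extract seen by the engine, with injected faults.

    Currently one fault mode: the systematic 1-day error on initial-visit
    dates (each ``initial_consult`` event shifted +1 day with probability
    ``profile.initial_visit_shift``).
    """
    out = log.copy()
    if profile.initial_visit_shift > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10**6,)))
        mask = (out["event_type"] == EventType.INITIAL_CONSULT.value) & (
            rng.random(len(out)) < profile.initial_visit_shift
        )
        out.loc[mask, "event_date"] = out.loc[mask, "event_date"] + _ONE_DAY
    return out


def _first(dates: list[pd.Timestamp]) -> Optional[pd.Timestamp]:
    return min(dates) if dates else None


def group_events(log: pd.DataFrame) -> dict[str, list]:
    """One pass over the log → per-patient lists of event records."""
    grouped: dict[str, list] = {}
    for rec in log.itertuples(index=False):
        grouped.setdefault(rec.patient_id, []).append(rec)
    return grouped


def _abstract_row_from_events(
    pid: str,
    ev: list,
    reg_row,
    mdt_rule: str,
) -> dict:
    """Perfect-knowledge abstract of one patient's events.

    ``ev`` is a list of event records (as from :func:`group_events`);
    ``mdt_rule`` is ``"first_after_consult"`` (what a registry abstractor
    records) or ``"last_before_treatment"`` (the indicator-correct MDT).
    """

    def dates_of(etype: EventType) -> list[pd.Timestamp]:
        return [r.event_date for r in ev if r.event_type == etype.value]

    letters = [r for r in ev if r.event_type == EventType.SCANNED_REFERRAL_LETTER.value]
    if letters:
        first_letter = min(letters, key=lambda r: r.event_date)
        date_referral = pd.Timestamp(first_letter.attributes["referral_date"])
    else:
        date_referral = _first(dates_of(EventType.SCHEDULING_ORDER))

    initial = _first(dates_of(EventType.INITIAL_CONSULT))
    surgery_dates = dates_of(EventType.SURGERY)
    date_surgery = _first(surgery_dates)
    rt = dates_of(EventType.RT_FRACTION)
    rt_start, rt_end = (min(rt), max(rt)) if rt else (None, None)

    first_round = [
        r.event_date
        for r in ev
        if r.event_type == EventType.SYSTEMIC_ADMIN.value and r.attributes.get("round", 1) == 1
    ]
    syst_start = min(first_round) if first_round else None
    syst_end = max(first_round) if first_round else None

    mdts = sorted(dates_of(EventType.MDT_MEETING))
    treatment_candidates = [d for d in (date_surgery, rt_start, syst_start) if d is not None]
    treat_start = min(treatment_candidates) if treatment_candidates else None
    mdt_date = None
    if mdts:
        if mdt_rule == "first_after_consult":
            after = [d for d in mdts if initial is None or d >= initial]
            mdt_date = after[0] if after else None
        else:
            if treat_start is not None:
                before = [d for d in mdts if d < treat_start]
                mdt_date = before[-1] if before else None

    dental = dates_of(EventType.DENTAL_CONSULT)
    physio = (
        dates_of(EventType.PHYSIO_INPATIENT_FORM)
        + dates_of(EventType.PHYSIO_OUTPATIENT_CONTACT)
        + dates_of(EventType.PHYSIO_EXTERNAL_REFERRAL)
    )
    surgical_types = (EventType.SURGERY.value, EventType.REOPERATION.value)
    complication = any(
        r.attributes.get("complication") for r in ev if r.event_type in surgical_types
    )
    unplanned_reop = any(
        not r.planned_flag for r in ev if r.event_type == EventType.REOPERATION.value
    )

    return {
        "patient_id": pid,
        "localization": reg_row.localization,
        "intent": reg_row.intent,
        "date_referral": date_referral,
        "date_initial_visit": initial,
        "date_mdt_pretreat": mdt_date,
        "date_surgery": date_surgery,
        "rt_start": rt_start,
        "rt_end": rt_end,
        "syst_start": syst_start,
        "syst_end": syst_end,
        "date_dental": _first(dental),
        "date_physio": _first(physio),
        "surgical_treatment": len(surgery_dates) > 0,
        "neck_dissection": len(dates_of(EventType.NECK_DISSECTION)) > 0,
        "rt_flag": len(rt) > 0,
        "systemic_flag": len(dates_of(EventType.SYSTEMIC_ADMIN)) > 0,
        "dental_flag": len(dental) > 0,
        "physio_flag": len(physio) > 0,
        "complication_flag": bool(complication),
        "unplanned_reop_flag": bool(unplanned_reop),
    }


def _finalize_abstracts(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=ABSTRACT_COLUMNS)
    for col in DATE_VARS:
        df[col] = pd.to_datetime(df[col])
    for col in [c for c in ABSTRACT_COLUMNS if c not in DATE_VARS and c not in (
        "patient_id", "localization", "intent")]:
        df[col] = df[col].astype("boolean")
    return df


def derive_truth_abstract(log: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth abstract: perfect knowledge of every event, the
    indicator-correct (last-before-treatment) MDT, all physiotherapy
    settings visible, and systemic end restricted to the primary episode."""
    rows = []
    grouped = group_events(log)
    for reg_row in registry.itertuples(index=False):
        ev = grouped.get(reg_row.patient_id, [])
        rows.append(
            _abstract_row_from_events(
                reg_row.patient_id, ev, reg_row, mdt_rule="last_before_treatment"
            )
        )
    return _finalize_abstracts(rows)


# MED recording conventions: some variables are only chart-abstracted for the
# relevant subgroup, mirroring how a cancer-registry extract is coded.
_SURGICAL_ONLY_FLAGS = ["neck_dissection", "complication_flag", "unplanned_reop_flag"]
_POSITIVE_ONLY_FLAGS = ["physio_flag"]


def derive_manual_abstract(
    log: pd.DataFrame,
    registry: pd.DataFrame,
    profile: Optional[DiscrepancyProfile] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the manually abstracted dataset (MED).

    The abstractor reads the whole chart: the referral date written in the
    scanned letter, every physiotherapy contact regardless of setting, the
    primary systemic episode's end date, and the first MDT after the
    initial consult (a later re-discussion MDT is the one a chart reviewer
    tends to miss).  Per-variable missingness is then applied.

    Surgical-detail flags (neck dissection, complications, unplanned
    reoperation) are recorded only for surgical patients; the physiotherapy
    flag is recorded only when a contact was found.
    """
    profile = profile or DiscrepancyProfile.identity()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2 * 10**6,)))

    rows = []
    grouped = group_events(log)
    for reg_row in registry.itertuples(index=False):
        ev = grouped.get(reg_row.patient_id, [])
        row = _abstract_row_from_events(
            reg_row.patient_id, ev, reg_row, mdt_rule="first_after_consult"
        )
        for flag in _SURGICAL_ONLY_FLAGS:
            if not row["surgical_treatment"]:
                row[flag] = None
        for flag in _POSITIVE_ONLY_FLAGS:
            if not row[flag]:
                row[flag] = None
        for var, rate in profile.missingness.items():
            if rate > 0 and row.get(var) is not None and rng.random() < rate:
                row[var] = None
        rows.append(row)
    return _finalize_abstracts(rows)
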