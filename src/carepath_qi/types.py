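"""Shared domain types: enumerations, table schemas and configuration models.

The pipeline moves three tabular artifacts around:

* an **event log** — one row per timestamped care event (long format),
* a **patient registry** — one row per patient with diagnosis coding,
* **patient abstracts** — one flat row per patient in the schema shared by
  the manually abstracted dataset (MED) and the automatically extracted
  dataset (AED).

All tables are plain :class:`pandas.DataFrame` objects; the constants and
pydantic models here pin their columns and the configuration surface.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class EventType(str, enum.Enum):
    """Kinds of care events the synthetic EHR emits and the engine reads."""

    SCHEDULING_ORDER = "scheduling_order"
    SCANNED_REFERRAL_LETTER = "scanned_referral_letter"
    INITIAL_CONSULT = "initial_consult"
    MDT_MEETING = "mdt_meeting"
    SURGERY = "surgery"
    NECK_DISSECTION = "neck_dissection"
    REOPERATION = "reoperation"
    RT_FRACTION = "rt_fraction"
    SYSTEMIC_ADMIN = "systemic_admin"
    DENTAL_CONSULT = "dental_consult"
    PHYSIO_INPATIENT_FORM = "physio_inpatient_form"
    PHYSIO_OUTPATIENT_CONTACT = "physio_outpatient_contact"
    PHYSIO_EXTERNAL_REFERRAL = "physio_external_referral"


class Setting(str, enum.Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    EXTERNAL = "external"


class Localization(str, enum.Enum):
    """Tumor localization categories derived from ICD-10 coding."""

    ORAL_CAVITY = "oral_cavity_and_lip"
    OROPHARYNX = "oropharynx"
    NASOPHARYNX = "nasopharynx"
    HYPOPHARYNX = "hypopharynx"
    LARYNX = "larynx"
    NASAL_CAVITY = "nasal_cavity_and_paranasal_sinuses"
    SALIVARY_GLANDS = "salivary_glands"
    UNKNOWN_PRIMARY = "unknown_primary"


#: Fixed ICD-10 prefix -> localization mapping used for inclusion and for
#: assigning a representative code to synthetic patients.  Head and neck
#: sites C00-C14, C30-C32 plus C77.0 (cervical nodes, unknown primary).
ICD10_LOCALIZATION_MAP: dict[str, Localization] = {
    "C00": Localization.ORAL_CAVITY,
    "C02": Localization.ORAL_CAVITY,
    "C03": Localization.ORAL_CAVITY,
    "C04": Localization.ORAL_CAVITY,
    "C05": Localization.ORAL_CAVITY,
    "C06": Localization.ORAL_CAVITY,
    "C01": Localization.OROPHARYNX,
    "C09": Localization.OROPHARYNX,
    "C10": Localization.OROPHARYNX,
    "C11": Localization.NASOPHARYNX,
    "C12": Localization.HYPOPHARYNX,
    "C13": Localization.HYPOPHARYNX,
    "C14": Localization.HYPOPHARYNX,
    "C30": Localization.NASAL_CAVITY,
    "C31": Localization.NASAL_CAVITY,
    "C32": Localization.LARYNX,
    "C07": Localization.SALIVARY_GLANDS,
    "C08": Localization.SALIVARY_GLANDS,
    "C77.0": Localization.UNKNOWN_PRIMARY,
}

#: One representative ICD-10 code per localization (synthetic registry).
LOCALIZATION_ICD10: dict[Localization, str] = {
    Localization.ORAL_CAVITY: "C02",
    Localization.OROPHARYNX: "C09",
    Localization.NASOPHARYNX: "C11",
    Localization.HYPOPHARYNX: "C13",
    Localization.LARYNX: "C32",
    Localization.NASAL_CAVITY: "C31",
    Localization.SALIVARY_GLANDS: "C07",
    Localization.UNKNOWN_PRIMARY: "C77.0",
}


class Histology(str, enum.Enum):
    SCC = "scc"
    CIS = "cis"
    MELANOMA = "melanoma"
    THYROID = "thyroid"
    SKIN = "skin"
    SARCOMA = "sarcoma"
    NEUROENDOCRINE = "neuroendocrine"
    HEMATOLOGIC = "hematologic"
    OTHER = "other"


class TumorOrder(str, enum.Enum):
    FIRST_PRIMARY = "first_primary"
    SECOND_PRIMARY = "second_primary"
    RECURRENCE = "recurrence"
    RESIDUAL = "residual"


class Intent(str, enum.Enum):
    CURATIVE = "curative"
    PALLIATIVE = "palliative"


EVENT_COLUMNS = [
    "patient_id",
    "event_type",
    "event_date",
    "setting",
    "planned_flag",
    "attributes",
]

REGISTRY_COLUMNS = [
    "patient_id",
    "icd10_code",
    "localization",
    "histology",
    "tumor_order",
    "intent",
    "initial_consult_year",
]

#: Flat per-patient schema shared by MED and AED.
DATE_VARS = [
    "date_referral",
    "date_initial_visit",
    "date_mdt_pretreat",
    "date_surgery",
    "rt_start",
    "rt_end",
    "syst_start",
    "syst_end",
    "date_dental",
    "date_physio",
]
FLAG_VARS = [
    "surgical_treatment",
    "neck_dissection",
    "rt_flag",
    "systemic_flag",
    "dental_flag",
    "physio_flag",
    "complication_flag",
    "unplanned_reop_flag",
]
CATEGORICAL_VARS = ["localization", "intent"]
ABSTRACT_COLUMNS = ["patient_id"] + CATEGORICAL_VARS + DATE_VARS + FLAG_VARS


class DiscrepancyProfile(BaseModel):
    """Configuration of the injected manual-vs-automatic error modes.

    The defaults form the *identity* profile: no injected discrepancies and
    no missingness, under which the manually abstracted dataset, the
    automatic extraction and the ground truth coincide exactly.

    Parameters
    ----------
    p_ref
        Probability that the referral letter carries a date earlier than the
        scheduling order, by an offset drawn from ``referral_offset_days``.
        The letter is scanned as a PDF, so the extraction engine can never
        see that earlier date.
    referral_offset_days
        Probability weights over offsets {1, 2, 3} days.
    initial_visit_shift
        Probability of a systematic +1 day error on the initial-visit date
        in the raw extract handed to the engine (an extraction-layer fault).
    extra_mdt_prob
        Probability that a patient is re-discussed in an additional MDT
        seven days after the abstractor-chosen one, still before treatment.
    physio_outpatient_prob
        Probability that a physiotherapy contact happens only in the
        outpatient/external setting, where no inpatient form is filed and
        the contact is invisible to extraction.
    second_systemic_round_prob
        Probability of a later, second round of systemic therapy whose
        administrations can contaminate the extracted end date.
    missingness
        Per-variable probability that the manual abstractor leaves the
        field empty.
    """

    p_ref: float = Field(0.0, ge=0.0, le=1.0)
    referral_offset_days: dict[int, float] = Field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15}
    )
    initial_visit_shift: float = Field(0.0, ge=0.0, le=1.0)
    extra_mdt_prob: float = Field(0.0, ge=0.0, le=1.0)
    physio_outpatient_prob: float = Field(0.0, ge=0.0, le=1.0)
    second_systemic_round_prob: float = Field(0.0, ge=0.0, le=1.0)
    missingness: dict[str, float] = Field(default_factory=dict)

    @field_validator("referral_offset_days")
    @classmethod
    def _check_offsets(cls, v: dict[int, float]) -> dict[int, float]:
        if set(v) - {1, 2, 3}:
            raise ValueError("referral offsets must be in {1, 2, 3}")
        if any(p < 0 for p in v.values()) or sum(v.values()) <= 0:
            raise ValueError("offset weights must be non-negative, not all zero")
        return v

    @field_validator("missingness")
    @classmethod
    def _check_missingness(cls, v: dict[str, float]) -> dict[str, float]:
        for name, rate in v.items():
            if name not in ABSTRACT_COLUMNS:
                raise ValueError(f"unknown abstract variable {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        return v

    @classmethod
    def identity(cls) -> "DiscrepancyProfile":
        return cls()


class MdtSelection(str, enum.Enum):
    LAST_BEFORE_TREATMENT = "last_before_treatment"
    FIRST_AFTER_DIAGNOSIS = "first_after_diagnosis"


class ExtractionRules(BaseModel):
    """Tunable rules of the extraction engine.

    ``systemic_round_cutoff_weeks`` separates rounds of systemic therapy: a
    gap longer than the cutoff between consecutive administrations starts a
    new round and later administrations no longer move the end date.  The
    default of 6 weeks mirrors the conventional adjuvant-treatment window.
    ``same_day_strict`` controls whether "prior to treatment" comparisons
    are strict (default) or allow same-day events.
    """

    icd10_inclusion: tuple[str, ...] = tuple(ICD10_LOCALIZATION_MAP)
    systemic_round_cutoff_weeks: Optional[int] = 6
    mdt_selection: MdtSelection = MdtSelection.LAST_BEFORE_TREATMENT
    same_day_strict: bool = True

    @field_validator("systemic_round_cutoff_weeks")
    @classmethod
    def _check_cutoff(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 1:
            raise ValueError("systemic round cutoff must be >= 1 week")
        return v


class PathwayConfig(BaseModel):
    """Waiting-time and treatment-mix parameters of the synthetic pathway.

    Waiting times are truncated-geometric day counts parameterized by their
    median; MDTs run on a weekly schedule on ``mdt_weekday`` (0 = Monday).
    """

    year: int = 2020
    mdt_weekday: int = Field(2, ge=0, le=6)  # Wednesday
    referral_to_consult_median: int = Field(5, ge=0)
    consult_to_mdt_median: int = Field(0, ge=0)
    mdt_to_treatment_median: int = Field(14, ge=0)
    surgery_to_adjuvant_median: int = Field(35, ge=1)
    p_surgery: float = Field(0.50, ge=0, le=1)
    p_adjuvant_rt_after_surgery: float = Field(0.55, ge=0, le=1)
    p_adjuvant_systemic: float = Field(0.20, ge=0, le=1)
    p_rt_no_surgery: float = Field(0.92, ge=0, le=1)
    p_concurrent_systemic: float = Field(0.25, ge=0, le=1)
    p_neck_dissection: float = Field(0.50, ge=0, le=1)
    p_physio_after_neck_dissection: float = Field(0.60, ge=0, le=1)
    p_physio_other: float = Field(0.03, ge=0, le=1)
    p_dental_before_rt: float = Field(0.90, ge=0, le=1)
    p_complication: float = Field(0.20, ge=0, le=1)
    p_unplanned_reop: float = Field(0.07, ge=0, le=1)
    rt_fractions_min: int = Field(28, ge=1)
    rt_fractions_max: int = Field(35, ge=1)
    systemic_cycles: int = Field(3, ge=1)
    systemic_cycle_days: int = Field(21, ge=1)
    second_round_gap_min: int = Field(120, ge=1)
    second_round_gap_max: int = Field(250, ge=1)

    @model_validator(mode="after")
    def _check_ranges(self) -> "PathwayConfig":
        if self.rt_fractions_max < self.rt_fractions_min:
            raise ValueError("rt_fractions_max < rt_fractions_min")
        if self.second_round_gap_max < self.second_round_gap_min:
            raise ValueError("second_round_gap_max < second_round_gap_min")
        return self


class RunConfig(BaseModel):
    """Full pipeline configuration; a run is reproducible from this object."""

    seed: int = 0
    n_patients: int = Field(262, ge=1)
    year: int = 2020
    ineligible_fraction: float = Field(0.0, ge=0.0, le=1.0)
    localization_weights: Optional[list[float]] = None
    pathway: PathwayConfig = Field(default_factory=PathwayConfig)
    profile: DiscrepancyProfile = Field(default_factory=DiscrepancyProfile)
    rules: ExtractionRules = Field(default_factory=ExtractionRules)
    strict_intersection: bool = False

    @model_validator(mode="after")
    def _sync_year(self) -> "RunConfig":
        # the pathway generates consults in the study year
        self.pathway = self.pathway.model_copy(update={"year": self.year})
        return self
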