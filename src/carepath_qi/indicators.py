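"""Head-and-neck quality indicators: definitions, computation, comparison.

Each indicator is a numerator/denominator pair of declarative conditions
over the flat patient abstract (the national audit convention): seven
proportion indicators and three median waiting times.

* ``mdt_before_treatment``      — MDT discussed prior to curative treatment
* ``treatment_within_30d``      — treatment start ≤ 30 days after initial visit
* ``adjuvant_within_6w``        — adjuvant therapy ≤ 42 days after surgery
* ``initial_visit_within_7d``   — initial visit ≤ 7 days after referral
* ``dental_before_rt``          — dental-team consult before radiotherapy start
* ``physio_after_neck_dissection`` — physiotherapist contact after neck dissection
* ``unplanned_reoperation``     — unplanned reoperation after surgery
* ``median_consult_to_mdt``, ``median_referral_to_mdt``,
  ``median_referral_to_consult`` — median waiting times in days

Denominators count rows where every field a predicate needs is non-missing
and the denominator condition holds; "within N days" windows are inclusive
and "prior to" comparisons strict by default, both configurable per
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .rounding import percentage, round_half_away


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    description: str
    kind: str  # "proportion" | "median_days"
    window_days: Optional[int] = None
    boundary: str = "inclusive"  # window boundary
    strict_before: bool = True  # "prior to" comparisons

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IndicatorDefinition":
        return cls(**d)


@dataclass
class IndicatorResult:
    id: str
    numerator: int = 0
    denominator: int = 0
    pct: Optional[float] = None
    median: Optional[float] = None


@dataclass
class ComparisonRow:
    id: str
    manual: IndicatorResult
    automatic: IndicatorResult
    difference: Optional[float] = None  # automatic − manual, on rounded values


def builtin_definitions() -> list[IndicatorDefinition]:
    return [
        IndicatorDefinition(
            "mdt_before_treatment",
            "Patients discussed in an MDT prior to curative treatment",
            "proportion",
        ),
        IndicatorDefinition(
            "treatment_within_30d",
            "Treatment started within 30 days after the initial appointment",
            "proportion",
            window_days=30,
        ),
        IndicatorDefinition(
            "adjuvant_within_6w",
            "Adjuvant therapy started within 6 weeks after surgical treatment",
            "proportion",
            window_days=42,
        ),
        IndicatorDefinition(
            "initial_visit_within_7d",
            "Initial appointment within 7 days after referral",
            "proportion",
            window_days=7,
        ),
        IndicatorDefinition(
            "dental_before_rt",
            "Curative patients seen by the dental team prior to radiotherapy",
            "proportion",
        ),
        IndicatorDefinition(
            "physio_after_neck_dissection",
            "Patients seen by a physiotherapist after a neck dissection",
            "proportion",
        ),
        IndicatorDefinition(
            "unplanned_reoperation",
            "Unplanned reoperation after surgical treatment",
            "proportion",
        ),
        IndicatorDefinition(
            "median_consult_to_mdt",
            "Median days from initial consultation to pre-treatment MDT",
            "median_days",
        ),
        IndicatorDefinition(
            "median_referral_to_mdt",
            "Median days from referral to pre-treatment MDT",
            "median_days",
        ),
        IndicatorDefinition(
            "median_referral_to_consult",
            "Median days from referral to initial consultation",
            "median_days",
        ),
    ]


def treatment_start(df: pd.DataFrame) -> pd.Series:
    """Row-wise earliest treatment date (surgery, RT start, systemic start)."""
    return df[["date_surgery", "rt_start", "syst_start"]].min(axis=1, skipna=True)


def _days(later: pd.Series, earlier: pd.Series) -> pd.Series:
    return (later - earlier).dt.days


def _within(days: pd.Series, window: int, boundary: str) -> pd.Series:
    return days <= window if boundary == "inclusive" else days < window


def _true(col: pd.Series) -> pd.Series:
    return col.notna() & col.fillna(False).astype(bool)


def _before(a: pd.Series, b: pd.Series, strict: bool) -> pd.Series:
    return (a < b) if strict else (a <= b)


def _adjuvant_start(df: pd.DataFrame) -> pd.Series:
    """Earliest adjuvant (post-surgery) RT or systemic start."""
    surg = df["date_surgery"]
    cands = pd.concat(
        [df["rt_start"].where(df["rt_start"] > surg), df["syst_start"].where(df["syst_start"] > surg)],
        axis=1,
    )
    return cands.min(axis=1, skipna=True)


def _proportion_masks(
    df: pd.DataFrame, definition: IndicatorDefinition
) -> tuple[pd.Series, pd.Series]:
    ts = treatment_start(df)
    strict = definition.strict_before
    w, b = definition.window_days, definition.boundary
    iid = definition.id
    if iid == "mdt_before_treatment":
        den = (df["intent"] == "curative") & ts.notna()
        num = den & df["date_mdt_pretreat"].notna() & _before(df["date_mdt_pretreat"], ts, strict)
    elif iid == "treatment_within_30d":
        den = df["date_initial_visit"].notna() & ts.notna()
        num = den & _within(_days(ts, df["date_initial_visit"]), w, b)
    elif iid == "adjuvant_within_6w":
        adj = _adjuvant_start(df)
        den = _true(df["surgical_treatment"]) & df["date_surgery"].notna() & adj.notna()
        num = den & _within(_days(adj, df["date_surgery"]), w, b)
    elif iid == "initial_visit_within_7d":
        den = df["date_referral"].notna() & df["date_initial_visit"].notna()
        num = den & _within(_days(df["date_initial_visit"], df["date_referral"]), w, b)
    elif iid == "dental_before_rt":
        den = (df["intent"] == "curative") & df["rt_start"].notna() & df["dental_flag"].notna()
        num = (
            den
            & _true(df["dental_flag"])
            & df["date_dental"].notna()
            & _before(df["date_dental"], df["rt_start"], strict)
        )
    elif iid == "physio_after_neck_dissection":
        den = _true(df["neck_dissection"]) & df["date_surgery"].notna()
        num = (
            den
            & _true(df["physio_flag"])
            & df["date_physio"].notna()
            & (df["date_physio"] >= df["date_surgery"])
        )
    elif iid == "unplanned_reoperation":
        den = _true(df["surgical_treatment"]) & df["unplanned_reop_flag"].notna()
        num = den & _true(df["unplanned_reop_flag"])
    else:
        raise KeyError(f"unknown indicator id {definition.id!r}")
    return den.fillna(False).astype(bool), num.fillna(False).astype(bool)


_MEDIAN_PAIRS = {
    "median_consult_to_mdt": ("date_mdt_pretreat", "date_initial_visit"),
    "median_referral_to_mdt": ("date_mdt_pretreat", "date_referral"),
    "median_referral_to_consult": ("date_initial_visit", "date_referral"),
}


def compute_indicator(
    abstracts: pd.DataFrame, definition: IndicatorDefinition
) -> IndicatorResult:
    """Evaluate one indicator on a (cohort-filtered) abstract table."""
    if definition.kind == "median_days":
        later_col, earlier_col = _MEDIAN_PAIRS.get(definition.id, (None, None))
        if later_col is None:
            raise KeyError(f"unknown indicator id {definition.id!r}")
        both = abstracts[later_col].notna() & abstracts[earlier_col].notna()
        days = _days(abstracts.loc[both, later_col], abstracts.loc[both, earlier_col])
        med = round_half_away(float(np.median(days)), 1) if len(days) else None
        return IndicatorResult(definition.id, denominator=int(both.sum()), median=med)
    den, num = _proportion_masks(abstracts, definition)
    n_den, n_num = int(den.sum()), int(num.sum())
    pct = percentage(n_num, n_den, 1) if n_den else None
    return IndicatorResult(definition.id, numerator=n_num, denominator=n_den, pct=pct)


def compute_all(
    abstracts: pd.DataFrame, definitions: Optional[list[IndicatorDefinition]] = None
) -> list[IndicatorResult]:
    return [compute_indicator(abstracts, d) for d in definitions or builtin_definitions()]


def compare_results(manual: IndicatorResult, automatic: IndicatorResult) -> ComparisonRow:
    """Automatic minus manual, on the rounded reported values."""
    if manual.id != automatic.id:
        raise ValueError(f"indicator id mismatch: {manual.id!r} vs {automatic.id!r}")
    if manual.pct is not None and automatic.pct is not None:
        diff = round_half_away(automatic.pct - manual.pct, 1)
    elif manual.median is not None and automatic.median is not None:
        diff = round_half_away(automatic.median - manual.median, 1)
    else:
        diff = None
    return ComparisonRow(manual.id, manual, automatic, diff)


def comparison_table(
    manual: list[IndicatorResult], automatic: list[IndicatorResult]
) -> pd.DataFrame:
    """Manual-versus-automatic indicator table (audit report layout)."""
    auto_by_id = {r.id: r for r in automatic}
    rows = []
    for m in manual:
        c = compare_results(m, auto_by_id[m.id])
        rows.append(
            {
                "indicator": c.id,
                "manual_numerator": m.numerator,
                "manual_denominator": m.denominator,
                "manual_value": m.pct if m.pct is not None else m.median,
                "auto_numerator": c.automatic.numerator,
                "auto_denominator": c.automatic.denominator,
                "auto_value": c.automatic.pct
                if c.automatic.pct is not None
                else c.automatic.median,
                "difference": c.difference,
            }
        )
    return pd.DataFrame(rows)
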