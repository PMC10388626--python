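"""Builders that reconstruct datasets from published summary counts.

Concordance tables and indicator tables report only marginal counts
(records present per source, pairs compared, pairs agreeing, numerators
and denominators).  These helpers synthesize minimal MED/AED tables with
exactly those counts so that the full computation path — linkage,
agreement, indicator evaluation, comparison — can be exercised against the
printed values.  They are calibration utilities, not simulators.
"""

from __future__ import annotations

import pandas as pd

from .indicators import IndicatorDefinition
from .types import DATE_VARS, FLAG_VARS

_BASE = pd.Timestamp("2020-06-01")


def _agree_pair(variable):
    if variable in DATE_VARS:
        return _BASE, _BASE
    if variable in FLAG_VARS:
        return True, True
    return "curative", "curative"


def _disagree_pair(variable):
    if variable in DATE_VARS:
        return _BASE, _BASE + pd.Timedelta(days=1)
    if variable in FLAG_VARS:
        return True, False
    return "curative", "palliative"


def linked_pairs_from_counts(
    variable: str,
    n_manual: int,
    n_auto: int,
    n_agree: int,
    n_compared: int,
    total: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MED/AED tables with the given per-variable presence/agreement counts.

    ``n_compared`` pairs have the variable present in both sources
    (``n_agree`` of them equal); presence in exactly one source is padded to
    reach ``n_manual``/``n_auto``; remaining patients up to ``total`` have
    the variable missing in both.
    """
    m_only = n_manual - n_compared
    a_only = n_auto - n_compared
    if not 0 <= n_agree <= n_compared or m_only < 0 or a_only < 0:
        raise ValueError("inconsistent counts")
    if n_compared + m_only + a_only > total:
        raise ValueError(f"counts exceed total {total}")
    med_vals: list = []
    aed_vals: list = []
    for _ in range(n_agree):
        m, a = _agree_pair(variable)
        med_vals.append(m)
        aed_vals.append(a)
    for _ in range(n_compared - n_agree):
        m, a = _disagree_pair(variable)
        med_vals.append(m)
        aed_vals.append(a)
    filler = _agree_pair(variable)[0]
    med_vals += [filler] * m_only + [None] * (a_only + total - n_compared - m_only - a_only)
    aed_vals += [None] * m_only + [filler] * a_only + [None] * (total - n_compared - m_only - a_only)
    ids = [f"P{i:04d}" for i in range(total)]
    med = pd.DataFrame({"patient_id": ids, variable: med_vals})
    aed = pd.DataFrame({"patient_id": ids, variable: aed_vals})
    if variable in DATE_VARS:
        med[variable] = pd.to_datetime(med[variable])
        aed[variable] = pd.to_datetime(aed[variable])
    return med, aed


def abstracts_from_indicator_counts(
    definition: IndicatorDefinition, numerator: int, denominator: int, total: int
) -> pd.DataFrame:
    """An abstract table on which ``definition`` evaluates to exactly
    numerator/denominator, padded with out-of-denominator rows to ``total``."""
    if not 0 <= numerator <= denominator <= total:
        raise ValueError("inconsistent counts")
    iid = definition.id
    in_rows, out_rows = _indicator_row_templates(iid)
    rows = (
        [dict(in_rows[0]) for _ in range(numerator)]
        + [dict(in_rows[1]) for _ in range(denominator - numerator)]
        + [dict(out_rows) for _ in range(total - denominator)]
    )
    for i, r in enumerate(rows):
        r["patient_id"] = f"P{i:04d}"
        r.setdefault("intent", "curative")
    df = pd.DataFrame(rows)
    for col in DATE_VARS:
        if col not in df:
            df[col] = pd.NaT
        df[col] = pd.to_datetime(df[col])
    for col in FLAG_VARS:
        if col not in df:
            df[col] = pd.NA
        df[col] = df[col].astype("boolean")
    return df


def abstracts_with_waiting_days(
    definition: IndicatorDefinition, days: int, total: int
) -> pd.DataFrame:
    """An abstract table whose waiting-time indicator has median ``days``."""
    row = {
        "date_referral": _BASE,
        "date_initial_visit": _BASE,
        "date_mdt_pretreat": _BASE,
    }
    target = {
        "median_consult_to_mdt": ("date_mdt_pretreat", "date_initial_visit"),
        "median_referral_to_mdt": ("date_mdt_pretreat", "date_referral"),
        "median_referral_to_consult": ("date_initial_visit", "date_referral"),
    }[definition.id]
    later, earlier = target
    rows = []
    for i in range(total):
        r = dict(row)
        r[later] = r[earlier] + pd.Timedelta(days=days)
        if later == "date_initial_visit":
            r["date_mdt_pretreat"] = r[later] + pd.Timedelta(days=2)
        r["patient_id"] = f"P{i:04d}"
        rows.append(r)
    df = pd.DataFrame(rows)
    for col in DATE_VARS:
        if col not in df:
            df[col] = pd.NaT
        df[col] = pd.to_datetime(df[col])
    for col in FLAG_VARS:
        df[col] = pd.Series([pd.NA] * total, dtype="boolean")
    df["intent"] = "curative"
    return df


def _indicator_row_templates(iid: str) -> tuple[list[dict], dict]:
    """(numerator row, denominator-only row), out-of-denominator row."""
    d0 = _BASE
    if iid == "mdt_before_treatment":
        return (
            [
                {"date_mdt_pretreat": d0, "date_surgery": d0 + pd.Timedelta(days=7)},
                {"date_mdt_pretreat": d0 + pd.Timedelta(days=7), "date_surgery": d0},
            ],
            {},
        )
    if iid == "treatment_within_30d":
        return (
            [
                {"date_initial_visit": d0, "date_surgery": d0 + pd.Timedelta(days=10)},
                {"date_initial_visit": d0, "date_surgery": d0 + pd.Timedelta(days=60)},
            ],
            {"date_surgery": d0},
        )
    if iid == "adjuvant_within_6w":
        return (
            [
                {
                    "surgical_treatment": True,
                    "date_surgery": d0,
                    "rt_start": d0 + pd.Timedelta(days=30),
                },
                {
                    "surgical_treatment": True,
                    "date_surgery": d0,
                    "rt_start": d0 + pd.Timedelta(days=60),
                },
            ],
            {"surgical_treatment": True, "date_surgery": d0},
        )
    if iid == "initial_visit_within_7d":
        return (
            [
                {"date_referral": d0, "date_initial_visit": d0 + pd.Timedelta(days=5)},
                {"date_referral": d0, "date_initial_visit": d0 + pd.Timedelta(days=20)},
            ],
            {"date_referral": d0},
        )
    if iid == "dental_before_rt":
        return (
            [
                {
                    "rt_start": d0,
                    "dental_flag": True,
                    "date_dental": d0 - pd.Timedelta(days=7),
                },
                {"rt_start": d0, "dental_flag": False},
            ],
            {"dental_flag": False},
        )
    if iid == "physio_after_neck_dissection":
        return (
            [
                {
                    "neck_dissection": True,
                    "date_surgery": d0,
                    "physio_flag": True,
                    "date_physio": d0 + pd.Timedelta(days=3),
                },
                {"neck_dissection": True, "date_surgery": d0},
            ],
            {"neck_dissection": False},
        )
    if iid == "unplanned_reoperation":
        return (
            [
                {"surgical_treatment": True, "unplanned_reop_flag": True},
                {"surgical_treatment": True, "unplanned_reop_flag": False},
            ],
            {"surgical_treatment": False},
        )
    raise KeyError(f"no reconstruction template for {iid!r}")
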