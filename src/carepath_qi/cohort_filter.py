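"""Study inclusion/exclusion criteria applied to an abstract dataset.

A patient enters the analysis cohort when they (a) had their initial
consultation in the study year, (b) have a tumor in one of the eight
eligible head-and-neck localizations, and (c) were treated with curative
intent — and trigger none of the exclusions: (a) carcinoma in situ,
(b) second primary tumor, (c) residual or recurrent disease, (d) non-SCC
histology (mucosal melanoma, thyroid, skin, sarcoma, neuroendocrine,
hematologic or other).

Each patient receives a disposition label: ``included`` or the first
failing criterion in the fixed order inclusion a-c then exclusion a-d.
"""

from __future__ import annotations

import pandas as pd

from .types import Histology, Intent, Localization, TumorOrder

_ELIGIBLE_LOCALIZATIONS = {l.value for l in Localization}
_EXCLUDED_HISTOLOGIES = {
    Histology.MELANOMA.value,
    Histology.THYROID.value,
    Histology.SKIN.value,
    Histology.SARCOMA.value,
    Histology.NEUROENDOCRINE.value,
    Histology.HEMATOLOGIC.value,
    Histology.OTHER.value,
}

DISPOSITION_INCLUDED = "included"


def _disposition(abs_row, reg_row, year: int) -> str:
    histology = reg_row.histology
    tumor_order = reg_row.tumor_order
    if histology not in {h.value for h in Histology}:
        raise ValueError(f"unknown histology {histology!r}")
    if tumor_order not in {t.value for t in TumorOrder}:
        raise ValueError(f"unknown tumor_order {tumor_order!r}")

    # inclusion (a): initial consultation in the study year; the dataset's
    # own visit date decides, the registry year is the missing-date fallback
    visit = abs_row.date_initial_visit
    visit_year = visit.year if pd.notna(visit) else reg_row.initial_consult_year
    if int(visit_year) != int(year):
        return "inclusion-a"
    if abs_row.localization not in _ELIGIBLE_LOCALIZATIONS:
        return "inclusion-b"
    intent = abs_row.intent if pd.notna(abs_row.intent) else reg_row.intent
    if intent != Intent.CURATIVE.value:
        return "inclusion-c"
    if histology == Histology.CIS.value:
        return "exclusion-a"
    if tumor_order == TumorOrder.SECOND_PRIMARY.value:
        return "exclusion-b"
    if tumor_order in (TumorOrder.RECURRENCE.value, TumorOrder.RESIDUAL.value):
        return "exclusion-c"
    if histology in _EXCLUDED_HISTOLOGIES:
        return "exclusion-d"
    return DISPOSITION_INCLUDED


def apply_criteria(
    abstracts: pd.DataFrame, registry: pd.DataFrame, year: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter an abstract table to the analysis cohort.

    Returns ``(filtered, disposition)`` where ``disposition`` is a Series
    of labels indexed like ``abstracts``.  Filtering is a pure function of
    the rows: applying it twice equals applying it once.
    """
    reg = registry.set_index("patient_id")
    missing = set(abstracts["patient_id"]) - set(reg.index)
    if missing:
        raise KeyError(f"abstract patients missing from registry: {sorted(missing)[:5]}")
    labels = []
    for abs_row in abstracts.itertuples(index=False):
        reg_row = reg.loc[abs_row.patient_id]
        labels.append(_disposition(abs_row, reg_row, year))
    disposition = pd.Series(labels, index=abstracts.index, name="disposition")
    filtered = abstracts.loc[disposition == DISPOSITION_INCLUDED].reset_index(drop=True)
    return filtered, disposition
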