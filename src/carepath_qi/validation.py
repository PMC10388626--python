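"""Concordance analysis between a manual (MED) and an automatic (AED) dataset.

Records are linked on the exact patient identifier; every record gets a
three-group linkage indicator (linked / MED-only / AED-only).  For linked
pairs the module computes, per variable: presence counts in each source,
the number of pairs with the variable present in both, the number agreeing
exactly (dates: same calendar day; categories: same code; booleans: same
value), the percent agreement over compared pairs, and — for categorical
variables — Cohen's kappa with a large-sample test of kappa = 0.

For date variables the signed day difference (manual minus automatic) of
each *disagreeing* pair is collected; a negative value means the manual
date is earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .rounding import percentage
from .types import ABSTRACT_COLUMNS, CATEGORICAL_VARS, DATE_VARS, FLAG_VARS

MED_SUFFIX, AED_SUFFIX = "_med", "_aed"


@dataclass
class LinkedDataset:
    """MED/AED pairs joined on patient_id, plus the linkage indicator."""

    linked: pd.DataFrame  # columns <var>_med / <var>_aed, indexed by patient_id
    med_only: list[str]
    aed_only: list[str]
    n_med_total: int
    n_aed_total: int

    @property
    def n_linked(self) -> int:
        return len(self.linked)

    def linkage_table(self) -> pd.DataFrame:
        rows = [{"patient_id": pid, "linkage_indicator": "linked"} for pid in self.linked.index]
        rows += [{"patient_id": pid, "linkage_indicator": "med_only"} for pid in self.med_only]
        rows += [{"patient_id": pid, "linkage_indicator": "aed_only"} for pid in self.aed_only]
        return pd.DataFrame(rows, columns=["patient_id", "linkage_indicator"])


@dataclass
class AgreementResult:
    variable: str
    n_manual_present: int
    n_auto_present: int
    n_compared: int
    n_agree: int
    pct_agreement: Optional[float]
    kappa: Optional[float] = None
    p_value: Optional[float] = None


@dataclass
class DateDiffDistribution:
    variable: str
    differences: list[int] = field(default_factory=list)  # manual - auto, days; no zeros


def link_datasets(med: pd.DataFrame, aed: pd.DataFrame) -> LinkedDataset:
    """Exact-identifier record linkage with a three-group indicator."""
    for name, df in (("MED", med), ("AED", aed)):
        dupes = df["patient_id"][df["patient_id"].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate patient_id in {name}: {sorted(set(dupes))[:5]}")
    m = med.set_index("patient_id")
    a = aed.set_index("patient_id")
    shared = m.index.intersection(a.index)
    linked = m.loc[shared].add_suffix(MED_SUFFIX).join(a.loc[shared].add_suffix(AED_SUFFIX))
    return LinkedDataset(
        linked=linked,
        med_only=sorted(m.index.difference(a.index)),
        aed_only=sorted(a.index.difference(m.index)),
        n_med_total=len(m),
        n_aed_total=len(a),
    )


def coverage(linked: LinkedDataset) -> float:
    """Linked records as a percentage of MED records, 2 decimals."""
    if linked.n_med_total == 0:
        raise ValueError("coverage undefined: empty MED")
    return percentage(linked.n_linked, linked.n_med_total, ndigits=2)


def _values_equal(x, y, variable: str) -> bool:
    if variable in DATE_VARS:
        return pd.Timestamp(x).normalize() == pd.Timestamp(y).normalize()
    if variable in FLAG_VARS:
        return bool(x) == bool(y)
    return x == y


def compute_agreement(
    linked: LinkedDataset,
    variable: str,
    comparator=None,
    with_kappa: Optional[bool] = None,
) -> AgreementResult:
    """Per-variable presence, comparison and agreement counts.

    Agreement is exact equality among pairs with the variable present in
    both sources; ``comparator`` overrides the equality test.  Kappa is
    computed for categorical variables by default ("if applicable") — dates
    get the day-difference distribution instead.
    """
    if variable not in ABSTRACT_COLUMNS or variable == "patient_id":
        raise KeyError(f"unknown variable {variable!r}")
    mcol = linked.linked[variable + MED_SUFFIX]
    acol = linked.linked[variable + AED_SUFFIX]
    m_present, a_present = mcol.notna(), acol.notna()
    both = m_present & a_present
    cmp_fn = comparator or (lambda x, y: _values_equal(x, y, variable))
    agree = [cmp_fn(x, y) for x, y in zip(mcol[both], acol[both])]
    n_compared, n_agree = len(agree), int(sum(agree))
    pct = percentage(n_agree, n_compared, 1) if n_compared else None

    kappa = p_value = None
    if with_kappa is None:
        with_kappa = variable in CATEGORICAL_VARS or variable in FLAG_VARS
    if with_kappa and n_compared:
        mv = mcol[both].astype(str)
        av = acol[both].astype(str)
        table = pd.crosstab(mv, av)
        cats = table.index.union(table.columns)
        table = table.reindex(index=cats, columns=cats, fill_value=0)
        if len(cats) > 1:
            try:
                kappa, p_value = cohen_kappa(table.to_numpy())
            except ValueError:  # degenerate marginals
                kappa = p_value = None
    return AgreementResult(
        variable=variable,
        n_manual_present=int(m_present.sum()),
        n_auto_present=int(a_present.sum()),
        n_compared=n_compared,
        n_agree=n_agree,
        pct_agreement=pct,
        kappa=kappa,
        p_value=p_value,
    )


def date_diff_distribution(linked: LinkedDataset, variable: str) -> DateDiffDistribution:
    """Signed day differences (manual − automatic) of disagreeing pairs."""
    if variable not in DATE_VARS:
        raise ValueError(f"{variable!r} is not a date variable")
    mcol = pd.to_datetime(linked.linked[variable + MED_SUFFIX])
    acol = pd.to_datetime(linked.linked[variable + AED_SUFFIX])
    both = mcol.notna() & acol.notna()
    diffs = (mcol[both] - acol[both]).dt.days
    return DateDiffDistribution(
        variable=variable, differences=[int(d) for d in diffs if d != 0]
    )


def cohen_kappa(cross_tab: np.ndarray) -> tuple[float, float]:
    """Cohen's kappa and a two-tailed large-sample test of kappa = 0.

    kappa = (p_o − p_e) / (1 − p_e) with p_o the diagonal proportion and
    p_e = Σ_i r_i·c_i / N² from the marginals.  The null standard error is
    the standard asymptotic expression
    SE₀ = sqrt(p_e + p_e² − Σ_i r_i·c_i·(r_i + c_i)/N³) / ((1 − p_e)·√N)
    and p = 2·(1 − Φ(|kappa| / SE₀)).
    """
    t = np.asarray(cross_tab, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("cross_tab must be square")
    n = t.sum()
    if n <= 0:
        raise ValueError("cross_tab must contain counts")
    p_o = np.trace(t) / n
    row = t.sum(axis=1) / n
    col = t.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)
    # variance term can dip below zero by floating error for extreme marginals
    var_term = max(p_e + p_e**2 - float((row * col) @ (row + col)), 0.0)
    se0 = np.sqrt(var_term) / ((1 - p_e) * np.sqrt(n))
    if se0 == 0:
        p_value = 0.0 if kappa != 0 else 1.0
    else:
        p_value = float(2 * (1 - norm.cdf(abs(kappa) / se0)))
    return float(kappa), p_value


def agreement_table(
    linked: LinkedDataset, variables: Optional[list[str]] = None
) -> pd.DataFrame:
    """Agreement summary in the layout of a published concordance table."""
    variables = variables or (DATE_VARS + CATEGORICAL_VARS + FLAG_VARS)
    rows = []
    for var in variables:
        r = compute_agreement(linked, var)
        rows.append(
            {
                "variable": r.variable,
                "manual_present": r.n_manual_present,
                "auto_present": r.n_auto_present,
                "agree": r.n_agree,
                "compared": r.n_compared,
                "pct_agreement": r.pct_agreement,
                "kappa": r.kappa,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def localization_crosstab(linked: LinkedDataset) -> pd.DataFrame:
    """Full manual × automatic cross-tabulation of tumor localization."""
    m = linked.linked["localization" + MED_SUFFIX].astype(str)
    a = linked.linked["localization" + AED_SUFFIX].astype(str)
    return pd.crosstab(m, a, dropna=False)
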