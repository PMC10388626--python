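"""Reading and writing the pipeline's plain-text artifacts.

Event logs are JSON-lines (one care event per line, ISO-8601 dates);
registries and patient abstracts are UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import ABSTRACT_COLUMNS, DATE_VARS, EVENT_COLUMNS, FLAG_VARS


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for row in events.itertuples(index=False):
            rec = {
                "patient_id": row.patient_id,
                "event_type": row.event_type,
                "event_date": pd.Timestamp(row.event_date).date().isoformat(),
                "setting": row.setting,
                "planned_flag": bool(row.planned_flag),
                "attributes": row.attributes or {},
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_events(path: str | Path) -> pd.DataFrame:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    df = pd.DataFrame(records, columns=EVENT_COLUMNS)
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["attributes"] = df["attributes"].apply(lambda a: a or {})
    return df


def write_registry(registry: pd.DataFrame, path: str | Path) -> None:
    registry.to_csv(path, index=False)


def read_registry(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def write_abstracts(abstracts: pd.DataFrame, path: str | Path) -> None:
    out = abstracts.copy()
    for col in DATE_VARS:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_abstracts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ABSTRACT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    for col in DATE_VARS:
        df[col] = pd.to_datetime(df[col])
    for col in FLAG_VARS:
        df[col] = df[col].map(
            lambda v: pd.NA if pd.isna(v) else bool(v) if isinstance(v, bool) else str(v) == "True"
        )
        df[col] = df[col].astype("boolean")
    return df[ABSTRACT_COLUMNS]
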