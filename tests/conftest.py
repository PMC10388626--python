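import numpy as np
import pandas as pd
import pytest

from carepath_qi.cli_report import simulate, stage_seeds
from carepath_qi.extraction_engine import extract_dataset
from carepath_qi.types import RunConfig, EventType, EVENT_COLUMNS


@pytest.fixture(scope="session")
def identity_run():
    """One identity-profile pipeline run shared across test modules."""
    cfg = RunConfig(seed=11, n_patients=150)
    sim = simulate(cfg)
    sim["aed"] = extract_dataset(sim["events"], sim["registry"], cfg.rules)
    sim["config"] = cfg
    return sim


def random_events(rng: np.random.Generator, n_max: int = 20) -> pd.DataFrame:
    """Random small per-patient event set for oracle-equivalence tests."""
    types = list(EventType)
    n = int(rng.integers(0, n_max + 1))
    rows = []
    for _ in range(n):
        et = types[int(rng.integers(len(types)))]
        date = pd.Timestamp("2020-01-01") + pd.Timedelta(days=int(rng.integers(0, 400)))
        attrs = {}
        if et is EventType.SCANNED_REFERRAL_LETTER:
            attrs["referral_date"] = (
                (date - pd.Timedelta(days=int(rng.integers(0, 4)))).date().isoformat()
            )
        if et in (EventType.SURGERY, EventType.REOPERATION):
            attrs["complication"] = bool(rng.integers(2))
        rows.append(
            {
                "patient_id": "X",
                "event_type": et.value,
                "event_date": date,
                "setting": "outpatient",
                "planned_flag": bool(rng.integers(2)),
                "attributes": attrs,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_926)


__all__ = ["random_events", "stage_seeds"]
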