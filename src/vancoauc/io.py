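"""NONMEM-style dataset reading and writing.

The on-disk cohort format is a flat CSV with the conventional
pharmacometric columns:

    ID, TIME, AMT, DUR (or RATE), DV, EVID, MDV, PKIND, IVL,
    CLCR, CCI, WT, AGE, SEX, HCT, HGB, RBC, DOSE24, INTERVAL

EVID 1 rows are doses (AMT + DUR or RATE set, DV empty), EVID 0 rows
observations (DV set unless MDV 1). PKIND/IVL persist the peak/trough
annotation and dosing-interval index of each sample so the train/test
split round-trips. Covariates repeat on every row of a subject.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import SubjectData
from .pk import ConcentrationPoint, DoseEvent, Regimen
from .popmodel import Covariates

__all__ = ["read_dataset", "write_dataset"]

_COV_COLS = {
    "CLCR": "clcr", "CCI": "cci", "WT": "wt", "AGE": "age", "SEX": "sex",
    "HCT": "hct", "HGB": "hgb", "RBC": "rbc", "DOSE24": "dose24",
}


def write_dataset(subjects: Sequence[SubjectData], path: str | Path) -> None:
    """Serialize a cohort to the NONMEM-style CSV."""
    rows = []
    for s in subjects:
        cov = {col: getattr(s.covariates, attr) for col, attr in _COV_COLS.items()}
        common = {"ID": s.id, "INTERVAL": s.regimen.interval, **cov}
        for ev in s.regimen.events:
            rows.append({**common, "TIME": ev.start, "AMT": ev.amount,
                         "DUR": ev.duration, "DV": np.nan, "EVID": 1, "MDV": 1,
                         "PKIND": "", "IVL": -1})
        for o in s.observations:
            rows.append({**common, "TIME": o.time, "AMT": np.nan, "DUR": np.nan,
                         "DV": o.value, "EVID": 0, "MDV": 0,
                         "PKIND": o.kind, "IVL": o.interval_index})
    df = pd.DataFrame(rows)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable")
    cols = ["ID", "TIME", "AMT", "DUR", "DV", "EVID", "MDV", "PKIND", "IVL",
            *_COV_COLS, "INTERVAL"]
    # %.17g guarantees float64 round-trips exactly through the text format
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> list[SubjectData]:
    """Parse the NONMEM-style CSV back into subjects.

    EVID/MDV inconsistencies raise with the offending 1-based data row
    number. Observation rows with MDV=1 are retained in the file but
    excluded from the returned observation sequences (and hence from
    every likelihood).
    """
    df = pd.read_csv(path, dtype={"ID": str, "PKIND": str},
                     float_precision="round_trip")
    required = {"ID", "TIME", "AMT", "DV", "EVID", "MDV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    has_dur = "DUR" in df.columns
    has_rate = "RATE" in df.columns
    if not (has_dur or has_rate):
        raise ValueError("dataset needs a DUR or RATE column for infusions")
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        events, obs = [], []
        for idx, row in grp.iterrows():
            line = idx + 2  # 1-based with header
            evid = int(row["EVID"])
            if evid == 1:
                if not pd.isna(row["DV"]):
                    raise ValueError(f"row {line}: dose row (EVID=1) must not set DV")
                amt = float(row["AMT"])
                if has_dur and not pd.isna(row.get("DUR", np.nan)):
                    dur = float(row["DUR"])
                else:
                    rate = float(row["RATE"])
                    if rate <= 0:
                        raise ValueError(f"row {line}: RATE must be > 0")
                    dur = amt / rate
                events.append(DoseEvent(amount=amt, start=float(row["TIME"]),
                                        duration=dur))
            elif evid == 0:
                if int(row["MDV"]) == 1:
                    continue  # missing DV: kept on disk, dropped from likelihood
                if pd.isna(row["DV"]):
                    raise ValueError(
                        f"row {line}: observation (EVID=0, MDV=0) must set DV"
                    )
                kind = row.get("PKIND", "") or "other"
                if isinstance(kind, float) and math.isnan(kind):
                    kind = "other"
                obs.append(ConcentrationPoint(
                    time=float(row["TIME"]), value=float(row["DV"]),
                    kind=str(kind), interval_index=int(row.get("IVL", -1)),
                ))
            else:
                raise ValueError(f"row {line}: unsupported EVID {evid}")
        events.sort(key=lambda e: e.start)
        obs.sort(key=lambda o: o.time)
        first = grp.iloc[0]
        cov = Covariates(**{attr: (int(first[col]) if attr == "sex" else float(first[col]))
                            for col, attr in _COV_COLS.items()})
        interval = float(first["INTERVAL"]) if "INTERVAL" in grp.columns else 12.0
        subjects.append(SubjectData(
            id=str(sid),
            regimen=Regimen(events=tuple(events), interval=interval),
            observations=tuple(obs),
            covariates=cov,
        ))
    return subjects
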