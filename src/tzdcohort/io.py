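"""Reading and writing the delimited record tables.

On disk every table is a comma-separated UTF-8 file with a header row
and ISO-8601 dates.  In memory every date is an integer day since the
global epoch (see :mod:`tzdcohort.timeutils`); this module converts
between the two representations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .timeutils import dates_to_days, days_to_dates

#: date-valued columns per table (internal representation: int64 days)
DATE_COLUMNS = {
    "patients": ["data_start", "data_end", "death_day"],
    "prescriptions": ["day"],
    "events": ["day"],
    "covariates": ["day"],
    "death_causes": [],
    "ground_truth": [],
    "cohorts": ["index_day", "censor_day"],
    "person_time": ["start", "end"],
}

TABLE_FILES = {
    "patients": "patients.csv",
    "prescriptions": "prescriptions.csv",
    "events": "events.csv",
    "death_causes": "death_causes.csv",
    "covariates": "covariates.csv",
    "ground_truth": "ground_truth.csv",
    "cohorts": "cohorts.csv",
    "person_time": "person_time.csv",
}


def _days_to_iso(col: pd.Series) -> pd.Series:
    out = pd.Series("", index=col.index, dtype="object")
    ok = col.notna()
    if ok.any():
        days = col[ok].astype("int64").to_numpy()
        out[ok] = np.datetime_as_string(days_to_dates(days), unit="D")
    return out


def _iso_to_days(col: pd.Series) -> pd.Series:
    out = pd.Series(np.nan, index=col.index, dtype="float64")
    ok = col.notna() & (col.astype(str).str.len() > 0)
    if ok.any():
        out[ok] = dates_to_days(col[ok].astype(str).to_numpy())
    if out.notna().all():
        return out.astype("int64")
    return out


def write_table(df: pd.DataFrame, name: str, out_dir) -> Path:
    """Write one table, converting day columns to ISO dates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in DATE_COLUMNS.get(name, []):
        if col in out.columns:
            out[col] = _days_to_iso(out[col])
    path = out_dir / TABLE_FILES.get(name, f"{name}.csv")
    out.to_csv(path, index=False)
    return path


def write_tables(tables: dict, out_dir) -> dict:
    return {name: write_table(df, name, out_dir) for name, df in tables.items()}


def read_table(name: str, in_dir) -> pd.DataFrame:
    path = Path(in_dir) / TABLE_FILES.get(name, f"{name}.csv")
    df = pd.read_csv(path)
    for col in DATE_COLUMNS.get(name, []):
        if col in df.columns:
            df[col] = _iso_to_days(df[col])
    if "icd10_code" in df.columns:
        df["icd10_code"] = df["icd10_code"].fillna("")
    if "multi_constituent" in df.columns:
        df["multi_constituent"] = df["multi_constituent"].fillna("")
    if "death_source" in df.columns:
        df["death_source"] = df["death_source"].fillna("")
    return df


def read_tables(in_dir, names=("patients", "prescriptions", "events",
                               "death_causes", "covariates")) -> dict:
    return {name: read_table(name, in_dir) for name in names}
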