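"""CSV reading/writing with ISO-8601 dates and stable column order.

Round-trip contract: a table written by :func:`write_csv` and read back
by the matching reader is value-identical (dates parsed, booleans
restored, missing values preserved).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DATE_COLUMNS = {
    "birth_date", "hiv_diagnosis_date", "lab_date", "event_date",
    "consent_date", "withdrawal_date",
}
BOOL_COLUMNS = {"jurisdiction_resident", "review_flag", "accepted"}


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if col in DATE_COLUMNS and pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", dtype={"ssn": "string"})
    for col in df.columns:
        if col in DATE_COLUMNS:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        elif col in BOOL_COLUMNS and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    if "ssn" in df.columns:
        df["ssn"] = df["ssn"].fillna("").astype(str)
    return df
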