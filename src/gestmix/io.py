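"""TSV/JSON serialization with deterministic formatting.

All tables are tab-separated with empty fields for missing values and a
fixed float format, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

EXPOSURE_COLUMNS = [
    "subject_id",
    "case",
    "hg",
    "as",
    "cd",
    "pb",
    "mn",
    "se",
    "co",
    "cs",
    "cu",
    "zn",
    "mg",
    "round",
    "mat_age",
    "seafood",
    "folate",
    "parity",
    "education",
    "smoking",
    "sex",
    "birth_period",
    "gest_age",
    "bmi",
    "sga",
]

FLOAT_FORMAT = "%.8g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format=FLOAT_FORMAT)
    return path


def read_exposures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "case" in df.columns:
        df["case"] = df["case"].astype(int)
    return df


def write_exposures(df: pd.DataFrame, path: str | Path) -> Path:
    cols = [c for c in EXPOSURE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c != "case_propensity"]
    return write_table(df[cols], path)


def read_qc(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qc(qc: pd.DataFrame, path: str | Path) -> Path:
    return write_table(qc[["round", "metal", "qc_value"]], path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True) + "\n")
    return path


def config_hash(config: dict) -> str:
    canon = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:12]
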