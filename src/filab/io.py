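"""Cohort table reading/writing and report bundles."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .panels import ReferencePanel, Sex

__all__ = ["read_cohort", "write_table", "REQUIRED_COLUMNS"]

logger = logging.getLogger("filab")

REQUIRED_COLUMNS = ("patient_id", "age", "sex", "time_days", "event")


def read_cohort(path, panel: ReferencePanel | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Requires ``patient_id, age, sex, time_days, event`` plus analyte
    columns; empty cells are missing labs.  Raises on duplicate patient ids,
    negative follow-up times, events outside {0, 1} and unknown sex labels.
    Columns that are neither required nor panel analytes are logged and kept
    (coding ignores them).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient_id: {sorted(dup.unique())}")
    if (df["time_days"] < 0).any():
        bad = df.loc[df["time_days"] < 0, "patient_id"].tolist()
        raise ValueError(f"negative time_days for patients {bad}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event column must contain only 0 and 1")
    valid_sex = {s.value for s in Sex}
    if not df["sex"].astype(str).isin(valid_sex).all():
        bad = sorted(set(df["sex"].astype(str)) - valid_sex)
        raise ValueError(f"unknown sex labels: {bad}")
    if panel is not None:
        extra = [
            c for c in df.columns
            if c not in REQUIRED_COLUMNS and c not in panel.analyte_order
        ]
        if extra:
            logger.info("ignoring %d non-panel columns: %s", len(extra), extra)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_metadata(path, **fields) -> Path:
    import filab

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"filab_version": filab.__version__, **fields}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
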