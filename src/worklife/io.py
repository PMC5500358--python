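"""CSV interfaces for registry-style extracts.

``episodes.csv``: person_id, state_code (1-8), start_age, end_age
(decimal years, '.' separator, header required).
``covariates.csv``: person_id, iq_raw, mental_raw, phys_health, arm, hand,
walking, back, skin, bmi, birth_year; empty string means missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

EPISODE_CSV_COLUMNS = ["person_id", "state_code", "start_age", "end_age"]
COVARIATE_CSV_COLUMNS = ["person_id", "iq_raw", "mental_raw", "phys_health",
                         "arm", "hand", "walking", "back", "skin", "bmi",
                         "birth_year"]


def read_episodes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EPISODE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"episodes.csv missing columns {sorted(missing)}")
    return df.rename(columns={"state_code": "state"}).astype(
        {"state": int, "start_age": float, "end_age": float})


def write_episodes(episodes: pd.DataFrame, path: str | Path) -> None:
    out = episodes.rename(columns={"state": "state_code"})
    out[EPISODE_CSV_COLUMNS].to_csv(path, index=False,
                                    float_format="%.6f")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(COVARIATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"covariates.csv missing columns {sorted(missing)}")
    df = df.replace("", np.nan)
    for col in ["phys_health", "arm", "hand", "walking", "back", "skin",
                "bmi", "birth_year", "mental_raw"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # iq_raw mixes integers and letter grades; keep strings, numeric where
    # possible
    def _iq(v):
        if isinstance(v, float) and np.isnan(v):
            return np.nan
        try:
            return int(float(v))
        except (TypeError, ValueError):
            return str(v).strip()
    df["iq_raw"] = [_iq(v) for v in df["iq_raw"]]
    return df


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    out = covariates[COVARIATE_CSV_COLUMNS].copy()
    out["bmi"] = out["bmi"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    for col in COVARIATE_CSV_COLUMNS:
        if col in ("bmi",):
            continue
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else v)
    out.to_csv(path, index=False)
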