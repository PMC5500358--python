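"""Classification of conscription assessment scores.

General ability is scored on the STANINE scale (mean 5, SD 2), linearly
convertible to IQ points (mean 100, SD 15).  Men without a test carry a
letter grade: A (assumed above average), B (assumed average), C (assumed
below average).  Mental health is scored 1-7 or 9; 9 means no problems were
found and 8 is never used.  Missing values may be passed as None, NaN or an
empty string.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np
import pandas as pd

IQ_LOW = "low"
IQ_AVERAGE = "average"
IQ_HIGH = "high"
MENTAL_PROBLEMS = "problems"
MENTAL_NONE = "none"
MISSING = "missing"

#: The six analysis groups (IQ category x mental health), reference first.
GROUPS = [
    ("average", "none"),
    ("low", "none"),
    ("high", "none"),
    ("average", "problems"),
    ("low", "problems"),
    ("high", "problems"),
]
REFERENCE_GROUP = ("average", "none")


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, str):
        return value.strip() == "" or value.strip().lower() == "missing"
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def classify_iq(iq_raw: Any) -> str:
    """Map a STANINE score or letter grade onto {low, average, high, missing}.

    Scores 1-2 and grade C are low (IQ <= 85); 3-7 and grade B are average
    (85-115); 8-9 and grade A are high (> 115).
    """
    if _is_missing(iq_raw):
        return MISSING
    if isinstance(iq_raw, str):
        letter = iq_raw.strip().upper()
        if letter == "C":
            return IQ_LOW
        if letter == "B":
            return IQ_AVERAGE
        if letter == "A":
            return IQ_HIGH
        try:
            iq_raw = int(letter)
        except ValueError:
            raise ValueError(f"malformed IQ score: {iq_raw!r}") from None
    score = float(iq_raw)
    if not score.is_integer() or not 1 <= score <= 9:
        raise ValueError(f"malformed IQ score: {iq_raw!r}")
    score = int(score)
    if score <= 2:
        return IQ_LOW
    if score <= 7:
        return IQ_AVERAGE
    return IQ_HIGH


def stanine_to_iq(s: int | float) -> float:
    """Convert a STANINE score to IQ points via the linear map fixed by the
    two scales' means and standard deviations: IQ = 100 + (s - 5) * 15/2."""
    score = float(s)
    if not score.is_integer() or not 1 <= score <= 9:
        raise ValueError(f"STANINE score must be an integer in 1..9, got {s!r}")
    return 100.0 + (score - 5.0) * 7.5


def classify_mental(mental_raw: Any) -> str:
    """Map a mental-health score onto {problems, none, missing}.

    9 means the examining physician found no problems; 1-7 grade the severity
    of a discovered problem.  8 was never applied and is rejected.
    """
    if _is_missing(mental_raw):
        return MISSING
    score = float(mental_raw)
    if score == 8:
        raise ValueError("mental-health score 8 was never applied")
    if not score.is_integer() or not 1 <= score <= 9:
        raise ValueError(f"malformed mental-health score: {mental_raw!r}")
    return MENTAL_NONE if int(score) == 9 else MENTAL_PROBLEMS


def classify_cohort(covariates: pd.DataFrame) -> pd.DataFrame:
    """Add iq_cat / mental_cat / group columns to a covariate table.

    ``group`` is "<iq_cat>/<mental_cat>" when both are observed, else NaN.
    Expects columns ``iq_raw`` and ``mental_raw``.
    """
    out = covariates.copy()
    out["iq_cat"] = [classify_iq(v) for v in out["iq_raw"]]
    out["mental_cat"] = [classify_mental(v) for v in out["mental_raw"]]
    complete = (out["iq_cat"] != MISSING) & (out["mental_cat"] != MISSING)
    out["group"] = np.where(complete, out["iq_cat"] + "/" + out["mental_cat"],
                            np.nan)
    return out


def group_label(iq_cat: str, mental_cat: str) -> str:
    return f"{iq_cat}/{mental_cat}"


def dichotomize_physical(scores: pd.DataFrame,
                         columns: list[str] | None = None) -> pd.DataFrame:
    """Dichotomize physical assessment scores as below-9 vs 9 (no impairment).

    Returns 0/1 indicators (1 = any impairment, score < 9); missing stays NaN.
    """
    if columns is None:
        columns = ["phys_health", "arm", "hand", "walking", "back", "skin"]
    out = pd.DataFrame(index=scores.index)
    for col in columns:
        vals = pd.to_numeric(scores[col], errors="coerce")
        out[col + "_impaired"] = np.where(vals.isna(), np.nan,
                                          (vals < 9).astype(float))
    return out
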