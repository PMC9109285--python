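"""Trial table ingestion, validation, complete-case filtering and encoding.

The analysis models consume a fixed design matrix layout:

    intercept, Group (1 = brief intervention), Sex (1 = female),
    Education(complete), Education(superior), Age [years]
    [+ baseline AUDIT score for the Gaussian score models]

with health centers mapped to consecutive indices in first-appearance
order, and the binary outcome defined as risky drinking at follow-up
(AUDIT-total >= 8). Only participants with observed follow-up enter the
design (complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesignError,
    EmptyDesignError,
    SchemaError,
    ValidationError,
)
from .simulate import ARM_LEVELS, CSV_COLUMNS, EDUCATION_LEVELS, SEX_LEVELS

RISKY_THRESHOLD = 8  # AUDIT-total >= 8 defines risky drinking

OUTCOMES = ("risk", "audit_total", "audit_c")

DESIGN_COLUMNS = [
    "intercept", "group", "sex", "edu_complete", "edu_superior", "age",
]


@dataclass(frozen=True)
class TrialTable:
    """Validated per-participant trial records (raw scale, pre-encoding)."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class EncodedDesign:
    """Completer-only design matrix plus outcome vectors.

    ``center_index`` uses consecutive integers 1..k in first-appearance
    order. ``X`` has 6 columns for the risk model and 7 (baseline score
    appended) for the score models.
    """

    outcome: str
    X: np.ndarray
    colnames: list[str]
    center_index: np.ndarray  # 1-based
    y_binary: np.ndarray
    y_total: np.ndarray
    y_auditc: np.ndarray
    n: int
    k: int
    center_labels: list

    @property
    def y(self) -> np.ndarray:
        return {
            "risk": self.y_binary,
            "audit_total": self.y_total,
            "audit_c": self.y_auditc,
        }[self.outcome]


def _read_mapping(mapping) -> dict:
    """Category-spelling overrides, either a dict or a key=value text file."""
    if mapping is None:
        return {}
    if isinstance(mapping, dict):
        return dict(mapping)
    out = {}
    for line in Path(mapping).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"mapping line is not key=value: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _check_range(df, col, lo, hi):
    vals = df[col].dropna()
    bad = vals[(vals < lo) | (vals > hi)]
    if len(bad):
        row = df.loc[bad.index[0], "id"]
        raise ValidationError(
            f"{col} out of range [{lo}, {hi}] for participant id={row} "
            f"(value {bad.iloc[0]})"
        )


def validate_table(df: pd.DataFrame) -> TrialTable:
    """Validate ranges, category levels and completion consistency."""
    for col, levels in (("arm", ARM_LEVELS), ("sex", SEX_LEVELS),
                        ("education", EDUCATION_LEVELS)):
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} value(s) {sorted(bad)}; "
                                  f"expected one of {levels}")
    if not df["completed"].isin([0, 1]).all():
        raise ValidationError("completed must be 0 or 1")
    _check_range(df, "age", 0, 130)
    _check_range(df, "audit_total_baseline", 0, 40)
    _check_range(df, "audit_c_baseline", 0, 12)
    _check_range(df, "audit_total_fu", 0, 40)
    _check_range(df, "audit_c_fu", 0, 12)
    for c_col, t_col in (("audit_c_baseline", "audit_total_baseline"),
                         ("audit_c_fu", "audit_total_fu")):
        both = df[[c_col, t_col, "id"]].dropna()
        bad = both[both[c_col] > both[t_col]]
        if len(bad):
            raise ValidationError(
                f"{c_col} exceeds {t_col} for participant id={bad['id'].iloc[0]}"
            )
    done = df[df["completed"] == 1]
    missing_fu = done[done["audit_total_fu"].isna() | done["audit_c_fu"].isna()]
    if len(missing_fu):
        raise ValidationError(
            "completed=1 but follow-up score missing for participant "
            f"id={missing_fu['id'].iloc[0]}"
        )
    return TrialTable(df=df.reset_index(drop=True))


def read_trial_csv(path: str | Path, mapping=None) -> TrialTable:
    """Read and validate a trial CSV in the canonical schema.

    ``mapping`` optionally remaps category spellings (dict or key=value
    file), e.g. ``Intervention=bi``, to ingest externally deposited data.
    """
    df = pd.read_csv(path, dtype={"arm": str, "sex": str, "education": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[CSV_COLUMNS].copy()
    remap = _read_mapping(mapping)
    if remap:
        for col in ("arm", "sex", "education"):
            df[col] = df[col].replace(remap)
    for col in ("audit_total_fu", "audit_c_fu"):
        df[col] = pd.array(df[col], dtype="Int64")
    for col in ("audit_total_baseline", "audit_c_baseline", "completed"):
        if df[col].isna().any():
            raise ValidationError(f"missing value in required column {col}")
    return validate_table(df)


def encode(table: TrialTable, outcome: str = "risk") -> EncodedDesign:
    """Build the completer-only design matrix for one outcome.

    Raises ``EmptyDesignError`` when no completers remain and
    ``DegenerateDesignError`` when only one arm survives filtering.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    df = table.df[table.df["completed"] == 1].reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise EmptyDesignError("no participants completed follow-up")
    if df["arm"].nunique() < 2:
        raise DegenerateDesignError(
            "only one arm present among completers; group effect unidentifiable"
        )

    cols = [
        np.ones(n),
        (df["arm"] == "bi").to_numpy(float),
        (df["sex"] == "female").to_numpy(float),
        (df["education"] == "complete").to_numpy(float),
        (df["education"] == "superior").to_numpy(float),
        df["age"].to_numpy(float),
    ]
    colnames = list(DESIGN_COLUMNS)
    if outcome == "audit_total":
        cols.append(df["audit_total_baseline"].to_numpy(float))
        colnames.append("baseline")
    elif outcome == "audit_c":
        cols.append(df["audit_c_baseline"].to_numpy(float))
        colnames.append("baseline")
    X = np.column_stack(cols)

    center_labels = list(dict.fromkeys(df["center"].tolist()))  # first appearance
    lookup = {c: i + 1 for i, c in enumerate(center_labels)}
    center_index = df["center"].map(lookup).to_numpy(int)

    return EncodedDesign(
        outcome=outcome,
        X=X,
        colnames=colnames,
        center_index=center_index,
        y_binary=(df["audit_total_fu"].to_numpy(float) >= RISKY_THRESHOLD).astype(float),
        y_total=df["audit_total_fu"].to_numpy(float),
        y_auditc=df["audit_c_fu"].to_numpy(float),
        n=n,
        k=len(center_labels),
        center_labels=center_labels,
    )
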