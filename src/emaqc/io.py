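"""Reading, writing and validation of the participant/assessment tables.

Both tables are plain comma-separated text with a header row and ISO-8601
timestamps; item responses of missed assessments are empty fields.
Validation is strict about the columns the analyses rely on and silently
preserves any extra columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import DEFAULT_DESIGN, StudyDesign


class ValidationError(ValueError):
    pass


REQUIRED_PARTICIPANT_COLS = ("person_id", "invited", "participated", "n_completed")
REQUIRED_ASSESSMENT_COLS = ("person_id", "day", "window", "completed")


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False)


def write_assessments(assessments: pd.DataFrame, path: str | Path) -> None:
    df = assessments.copy()
    for col in ("prompt_time", "reminder_time", "expiry_time", "start_time", "end_time"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PARTICIPANT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"participant table missing columns: {missing}")
    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValidationError(f"duplicate person_id {dup!r} in participant table")
    bad = df[(df["participated"] == 1) & (df["invited"] == 0)]
    if len(bad):
        raise ValidationError(
            f"participated without invitation: person {bad['person_id'].iloc[0]!r}"
        )
    if "compliance" not in df.columns:
        df["compliance"] = df["n_completed"] / DEFAULT_DESIGN.max_prompts
    return df


def read_assessments(
    path: str | Path, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_ASSESSMENT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"assessment table missing columns: {missing}")
    dup = df.duplicated(subset=["person_id", "day", "window"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate prompt key (person {row['person_id']!r}, day {row['day']}, "
            f"window {row['window']})"
        )
    if not df["day"].between(1, design.n_ema_days).all():
        row = df[~df["day"].between(1, design.n_ema_days)].iloc[0]
        raise ValidationError(
            f"day {row['day']} outside 1..{design.n_ema_days} "
            f"(person {row['person_id']!r})"
        )
    if not df["window"].between(1, design.prompts_per_day).all():
        row = df[~df["window"].between(1, design.prompts_per_day)].iloc[0]
        raise ValidationError(f"window {row['window']} outside range")
    item_cols = [f"item_{i:02d}" for i in range(1, design.n_items_common + 1)]
    for col in item_cols:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.notna()
        bad = present & ~vals.between(design.likert_min, design.likert_max)
        if bad.any():
            idx = df.index[bad][0]
            raise ValidationError(
                f"item value {vals[idx]} outside "
                f"[{design.likert_min}, {design.likert_max}] at row {idx} ({col})"
            )
        df[col] = vals.astype("Int64")
    for col in ("prompt_time", "reminder_time", "expiry_time", "start_time", "end_time"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df
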