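"""Per-assessment affect scores and careless-responding parameters.

Three assessment-level quantities drive the careless-response screening:
time per item (completion duration divided by the item count of that
assessment), the standard deviation of the 12 common Likert responses, and
the share of responses sitting at the assessment's modal response.  PA and
NA scores are plain means of their item subsets — the two affect scales are
separate unipolar constructs, so nothing is reverse-coded.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .design import DEFAULT_DESIGN, StudyDesign


class DataError(ValueError):
    """Raised for out-of-range or inconsistent assessment records."""


def score_affect(
    items: dict[int, int] | list[int], design: StudyDesign = DEFAULT_DESIGN
) -> tuple[float, float]:
    """PA and NA score of one assessment: means of the 5 PA / 4 NA items.

    ``items`` maps item id (1-based) to the response, or is a list of the 12
    common responses in item order.
    """
    if not isinstance(items, dict):
        items = {i + 1: v for i, v in enumerate(items)}
    for i, v in items.items():
        if not design.likert_min <= v <= design.likert_max:
            raise DataError(f"item {i} response {v} outside "
                            f"[{design.likert_min}, {design.likert_max}]")
    pa = float(np.mean([items[i] for i in design.pa_item_ids]))
    na = float(np.mean([items[i] for i in design.na_item_ids]))
    return pa, na


def time_per_item(start, end, n_items: int) -> float:
    """Seconds per item of one assessment; ``n_items`` is that assessment's
    own item count (morning/evening assessments carry more items)."""
    if n_items < 1:
        raise DataError("n_items must be >= 1")
    seconds = (pd.Timestamp(end) - pd.Timestamp(start)).total_seconds()
    if seconds <= 0:
        raise DataError(f"non-positive completion duration: {seconds} s")
    return seconds / n_items


def response_dispersion(items: list[int] | np.ndarray) -> tuple[float, float]:
    """(sample SD, share-at-mode) of the 12 common responses.

    The SD uses the n-1 denominator; with modal ties any mode gives the same
    share because tied modes have equal counts.
    """
    arr = np.asarray(items, dtype=float)
    sd = float(arr.std(ddof=1))
    top = Counter(arr.tolist()).most_common(1)[0][1]
    return sd, top / len(arr)


def enrich_assessments(
    assessments: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Add pa_score, na_score, time_per_item, sd_items, pct_mode columns.

    Missed assessments keep NaN in every derived column.  Vectorized over
    the whole table; the scalar helpers above define the semantics.
    """
    out = assessments.copy()
    item_cols = [f"item_{i:02d}" for i in range(1, design.n_items_common + 1)]
    completed = out["completed"] == 1
    items = out.loc[completed, item_cols].to_numpy(dtype=float)
    if items.size:
        bad = (items < design.likert_min) | (items > design.likert_max)
        if np.isnan(items).any() or bad.any():
            rows = out.index[completed][np.isnan(items).any(axis=1) | bad.any(axis=1)]
            raise DataError(
                f"completed assessments with missing/out-of-range items at rows "
                f"{list(rows[:5])}"
            )

    pa_cols = [f"item_{i:02d}" for i in design.pa_item_ids]
    na_cols = [f"item_{i:02d}" for i in design.na_item_ids]
    for col in ("pa_score", "na_score", "time_per_item", "sd_items", "pct_mode"):
        out[col] = np.nan
    out.loc[completed, "pa_score"] = out.loc[completed, pa_cols].mean(axis=1).astype(float)
    out.loc[completed, "na_score"] = out.loc[completed, na_cols].mean(axis=1).astype(float)

    if "n_items" not in out.columns:
        out["n_items"] = [design.n_items_of_window(w) for w in out["window"]]
    dur = (
        pd.to_datetime(out.loc[completed, "end_time"])
        - pd.to_datetime(out.loc[completed, "start_time"])
    ).dt.total_seconds()
    if (dur <= 0).any():
        raise DataError("non-positive completion duration in assessment table")
    out.loc[completed, "time_per_item"] = dur / out.loc[completed, "n_items"]

    if items.size:
        out.loc[completed, "sd_items"] = items.std(axis=1, ddof=1)
        # share at mode: max count of any response value within the row
        counts = np.stack(
            [
                (items == v).sum(axis=1)
                for v in range(design.likert_min, design.likert_max + 1)
            ],
            axis=1,
        )
        out.loc[completed, "pct_mode"] = counts.max(axis=1) / items.shape[1]
    return out
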