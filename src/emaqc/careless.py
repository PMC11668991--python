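"""Careless-response and careless-responder detection.

Assessment level: a completed assessment is flagged careless when it was
answered implausibly fast (time per item at or below 1 second) or with no
response variance at all (straight-lining: SD of the 12 common items equals
0, equivalently 100% of responses at the mode).  The thresholds are
justified empirically via psychometric antonyms — the item pair with the
strongest negative correlation: restricted to suspicious subsets the
antonym correlation flattens towards zero (random responding) or is forced
to +1 (straight-lining), while attentive subsets keep it negative.

Person level: a participant is a potential careless responder when they
have fewer valid (completed and unflagged) assessments than the minimum
needed for a stable estimate of their affect mean and variability, or when
their individual raw Cronbach alpha is below 0.11 ("practically no
reliability") for either affect scale.  The minimum is set by a resampling
stability analysis: growing random subsets of each eligible person's
gold-standard assessments are compared to the gold standard via a two-way
absolute-agreement ICC, and the minimum is the smallest subset size from
which all four curves (mean and SD of PA and NA) stay at or above 0.90.
Flagged responders are marked for sensitivity analyses, never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_DESIGN, StudyDesign
from .reliability import stability_icc


class CarelessError(ValueError):
    pass


@dataclass(frozen=True)
class CarelessRuleConfig:
    """Operational thresholds of the careless rules."""

    tpi_threshold_seconds: float = 1.0
    alpha_floor: float = 0.11
    icc_stability_target: float = 0.90
    gold_standard_n: int = 40
    subset_min: int = 2
    subset_max: int = 40
    n_replicates: int = 5
    #: 'first' = first gold_standard_n completed assessments chronologically;
    #: 'random' = seeded random selection among all completed
    gold_standard_selection: str = "first"

    def __post_init__(self) -> None:
        if self.tpi_threshold_seconds <= 0:
            raise CarelessError("tpi threshold must be positive")
        if not 0 < self.icc_stability_target < 1:
            raise CarelessError("icc_stability_target must lie in (0, 1)")
        if not 2 <= self.subset_min <= self.subset_max <= self.gold_standard_n:
            raise CarelessError("need 2 <= subset_min <= subset_max <= gold_standard_n")


@dataclass
class StabilityCurve:
    """Agreement-vs-subset-size curves and the resulting minimum."""

    curves: pd.DataFrame  # columns: subset_size, mean_pa, sd_pa, mean_na, sd_na
    minimum_valid_assessments: int | None
    n_persons: int
    target: float

    @property
    def reached(self) -> bool:
        return self.minimum_valid_assessments is not None


# ---------------------------------------------------------------------------
# psychometric antonyms


def select_antonyms(
    assessments: pd.DataFrame,
    candidate_items: list[str] | None = None,
    design: StudyDesign = DEFAULT_DESIGN,
) -> tuple[tuple[str, str], float, list[str]]:
    """Item pair with the strongest negative Pearson correlation over all
    completed assessments; ties break to the lowest item-index pair.

    Returns ``(pair, correlation, diagnostics)``; a warning diagnostic is
    added when even the most negative correlation is >= 0 (no antonyms).
    """
    if candidate_items is None:
        candidate_items = [f"item_{i:02d}" for i in range(1, design.n_items_common + 1)]
    done = assessments[assessments["completed"] == 1]
    if len(done) < 3 or len(candidate_items) < 2:
        raise CarelessError("need >= 2 items and >= 3 completed assessments")
    diags: list[str] = []
    data = done[candidate_items].astype(float)
    constant = [c for c in candidate_items if data[c].nunique() <= 1]
    if constant:
        diags.append(f"constant items excluded from antonym search: {constant}")
    usable = [c for c in candidate_items if c not in constant]
    if len(usable) < 2:
        raise CarelessError("fewer than 2 non-constant candidate items")
    corr = data[usable].corr(method="pearson")
    best_pair, best_r = None, np.inf
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            r = corr.loc[a, b]
            if r < best_r - 1e-15:
                best_pair, best_r = (a, b), float(r)
    if best_r >= 0:
        diags.append(
            f"most negative item correlation is {best_r:.3f} >= 0: "
            "no psychometric antonyms in these data"
        )
    return best_pair, best_r, diags


def antonym_threshold_curve(
    assessments: pd.DataFrame,
    parameter: str,
    thresholds: list[float],
    antonym_pair: tuple[str, str],
) -> pd.DataFrame:
    """Antonym correlation restricted to the suspicious side of each
    threshold.

    'Suspicious' means <= threshold for time_per_item and sd_items and
    >= threshold for pct_mode.  Subsets with fewer than 3 assessments or a
    constant antonym item yield a missing correlation, never an error.
    """
    if parameter not in {"time_per_item", "sd_items", "pct_mode"}:
        raise CarelessError(f"unknown careless parameter {parameter!r}")
    a, b = antonym_pair
    done = assessments[assessments["completed"] == 1]
    rows = []
    for thr in thresholds:
        if parameter == "pct_mode":
            sub = done[done[parameter] >= thr]
        else:
            sub = done[done[parameter] <= thr]
        note = ""
        if len(sub) < 3:
            r = np.nan
            note = "fewer than 3 assessments below threshold"
        else:
            x, y = sub[a].astype(float), sub[b].astype(float)
            if x.nunique() <= 1 or y.nunique() <= 1:
                r = np.nan
                note = "constant antonym item in subset"
            elif np.array_equal(x.to_numpy(), y.to_numpy()):
                # straight-lined subsets make the antonym columns identical;
                # report the forced correlation of exactly 1
                r = 1.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "parameter": parameter,
                "threshold": thr,
                "r": r,
                "n": len(sub),
                "share": len(sub) / len(done) if len(done) else np.nan,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assessment-level flags


def flag_careless_responses(
    assessments: pd.DataFrame, config: CarelessRuleConfig = CarelessRuleConfig()
) -> pd.DataFrame:
    """Flag completed assessments: 'fast' (TPI <= threshold), 'straightline'
    (zero item SD), 'both', or 'none'.  Missed assessments are never
    flagged."""
    for col in ("time_per_item", "sd_items"):
        if col not in assessments.columns:
            raise CarelessError(f"column {col!r} missing; enrich the table first")
    out = assessments.copy()
    done = out["completed"] == 1
    fast = done & (out["time_per_item"] <= config.tpi_threshold_seconds)
    straight = done & (out["sd_items"] == 0)
    flag = np.select(
        [fast & straight, fast, straight],
        ["both", "fast", "straightline"],
        default="none",
    )
    out["careless_flag"] = flag
    out["careless"] = (out["careless_flag"] != "none").astype(int)
    return out


def careless_response_summary(flagged: pd.DataFrame) -> dict:
    """Counts and shares of flagged responses and their overlap."""
    done = flagged[flagged["completed"] == 1]
    n_done = len(done)
    counts = done["careless_flag"].value_counts().to_dict()
    n_fast = counts.get("fast", 0) + counts.get("both", 0)
    n_straight = counts.get("straightline", 0) + counts.get("both", 0)
    n_flagged = int(done["careless"].sum())
    return {
        "n_completed": n_done,
        "n_flagged": n_flagged,
        "share_flagged": n_flagged / n_done if n_done else np.nan,
        "n_fast": int(n_fast),
        "n_straightline": int(n_straight),
        "n_both": int(counts.get("both", 0)),
    }


# ---------------------------------------------------------------------------
# minimum-assessment stability analysis


def minimum_valid_assessments(
    assessments: pd.DataFrame,
    config: CarelessRuleConfig = CarelessRuleConfig(),
    seed: int = 0,
) -> StabilityCurve:
    """Resampling stability analysis setting the minimum valid assessments.

    Eligible persons are those with at least ``gold_standard_n`` completed
    assessments; their gold standard is the first ``gold_standard_n``
    completed assessments in chronological order (or a seeded random
    selection).  For each subset size s, each of ``n_replicates`` seeded
    replicates draws s assessments per person without replacement from the
    gold-standard pool and compares the persons' subset mean and SD of PA
    and NA to the gold-standard values via the two-way absolute-agreement
    ICC; replicate curves are averaged before thresholding.  The minimum is
    the smallest s from which all four averaged curves stay >= the target.
    """
    need = {"pa_score", "na_score"}
    if not need <= set(assessments.columns):
        raise CarelessError("assessments must be enriched with pa_score/na_score")
    done = assessments[assessments["completed"] == 1].sort_values(
        ["person_id", "prompt_time"], kind="stable"
    )
    counts = done.groupby("person_id").size()
    eligible = counts[counts >= config.gold_standard_n].index
    if len(eligible) < 3:
        raise CarelessError(
            f"need >= 3 persons with >= {config.gold_standard_n} completed assessments"
        )
    rng = np.random.default_rng(seed)
    gold: dict[str, np.ndarray] = {}
    for pid in eligible:
        scores = done.loc[done["person_id"] == pid, ["pa_score", "na_score"]].to_numpy()
        if config.gold_standard_selection == "random":
            idx = rng.choice(len(scores), size=config.gold_standard_n, replace=False)
            gold[pid] = scores[np.sort(idx)]
        else:
            gold[pid] = scores[: config.gold_standard_n]

    gold_stats = {
        pid: (
            arr[:, 0].mean(),
            arr[:, 0].std(ddof=1),
            arr[:, 1].mean(),
            arr[:, 1].std(ddof=1),
        )
        for pid, arr in gold.items()
    }
    stat_names = ("mean_pa", "sd_pa", "mean_na", "sd_na")
    sizes = list(range(config.subset_min, config.subset_max + 1))
    curves = np.zeros((len(sizes), 4))
    for si, s in enumerate(sizes):
        acc = np.zeros(4)
        for _ in range(config.n_replicates):
            subset_stats = np.empty((len(gold), 4))
            gold_arr = np.empty((len(gold), 4))
            for row, (pid, arr) in enumerate(gold.items()):
                pick = arr[rng.choice(config.gold_standard_n, size=s, replace=False)]
                subset_stats[row] = (
                    pick[:, 0].mean(),
                    pick[:, 0].std(ddof=1),
                    pick[:, 1].mean(),
                    pick[:, 1].std(ddof=1),
                )
                gold_arr[row] = gold_stats[pid]
            for j in range(4):
                acc[j] += stability_icc(
                    np.column_stack([subset_stats[:, j], gold_arr[:, j]])
                )
        curves[si] = acc / config.n_replicates

    table = pd.DataFrame(curves, columns=list(stat_names))
    table.insert(0, "subset_size", sizes)
    ok = (curves >= config.icc_stability_target).all(axis=1)
    minimum = None
    # smallest size from which every larger evaluated size also passes
    for si in range(len(sizes)):
        if ok[si:].all():
            minimum = sizes[si]
            break
    return StabilityCurve(table, minimum, len(gold), config.icc_stability_target)


# ---------------------------------------------------------------------------
# person-level flags


def flag_careless_responders(
    participants: pd.DataFrame,
    flagged_assessments: pd.DataFrame,
    alpha_table: pd.DataFrame,
    minimum: int,
    config: CarelessRuleConfig = CarelessRuleConfig(),
) -> pd.DataFrame:
    """Person-level flags: too few valid (non-careless) assessments, or raw
    alpha below the floor on either affect scale.

    A missing alpha (undefined: <2 occasions or zero total variance) does
    not by itself trigger the low-alpha reason but is reported in its own
    column; negative alphas count as below the floor.
    """
    done = flagged_assessments[flagged_assessments["completed"] == 1]
    per = done.groupby("person_id").agg(
        n_completed=("careless", "size"), n_careless=("careless", "sum")
    )
    per["n_valid"] = per["n_completed"] - per["n_careless"]
    out = participants[participants["participated"] == 1][["person_id"]].merge(
        per.reset_index(), on="person_id", how="left"
    )
    for c in ("n_completed", "n_careless", "n_valid"):
        out[c] = out[c].fillna(0).astype(int)
    out = out.merge(
        alpha_table[["person_id", "alpha_pa", "alpha_na"]], on="person_id", how="left"
    )
    low_valid = out["n_valid"] < minimum
    low_alpha = (out["alpha_pa"] < config.alpha_floor) | (
        out["alpha_na"] < config.alpha_floor
    )
    low_alpha = low_alpha.fillna(False)
    out["alpha_undefined"] = (
        out["alpha_pa"].isna() | out["alpha_na"].isna()
    ).astype(int)
    out["flag_low_valid"] = low_valid.astype(int)
    out["flag_low_alpha"] = low_alpha.astype(int)
    out["responder_flag"] = np.select(
        [low_valid & low_alpha, low_valid, low_alpha],
        ["both", "low_valid", "low_alpha"],
        default="none",
    )
    return out


def careless_responder_summary(responders: pd.DataFrame) -> dict:
    n = len(responders)
    flagged = (responders["responder_flag"] != "none").sum()
    return {
        "n_participants": n,
        "n_flagged": int(flagged),
        "share_flagged": flagged / n if n else np.nan,
        "n_low_valid": int(responders["flag_low_valid"].sum()),
        "n_low_alpha": int(responders["flag_low_alpha"].sum()),
        "n_both": int((responders["responder_flag"] == "both").sum()),
        "n_alpha_undefined": int(responders["alpha_undefined"].sum()),
    }
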