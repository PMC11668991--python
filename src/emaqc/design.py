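"""Study design constants for the EMA sampling scheme.

The design mirrors a signal-contingent protocol used in mobile mental-health
studies of university students: four prompts per day delivered at a random
moment inside fixed 2-hour windows (morning, midday, afternoon, evening) over
14 consecutive EMA days, giving a design maximum of 56 momentary assessments
per participant.  Each prompt presents 12 common 7-point Likert items covering
momentary stress, energy, concentration and affect; 5 of the items form the
positive-affect (PA) scale and 4 the negative-affect (NA) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Labels of the 12 common Likert items, in schedule order.  Items 4-8 form
#: the PA scale, items 9-12 the NA scale; 1-3 are stress / energy /
#: concentration and belong to neither affect scale.
ITEM_LABELS: dict[int, str] = {
    1: "stress",
    2: "tired_low_energy",
    3: "trouble_concentrating",
    4: "happy",
    5: "interest",
    6: "relaxed",
    7: "optimistic",
    8: "pleasure",
    9: "nervous",
    10: "upset",
    11: "depressed",
    12: "worried",
}


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent."""


@dataclass(frozen=True)
class StudyDesign:
    """Fixed sampling design of the EMA protocol.

    Parameters
    ----------
    n_ema_days
        Number of days with momentary prompts (the day-1/15 questionnaire
        days are outside the momentary design).
    prompts_per_day
        Prompts issued per day, one per window.
    window_starts
        Clock hours at which each prompt window opens.
    window_length_minutes
        Width of each window; an assessment not completed inside the window
        counts as missed.
    reminder_minutes
        Delay of the single reminder notification after the prompt.
    n_items_common
        Number of Likert items shared by every assessment.
    pa_item_ids, na_item_ids
        Disjoint subsets of the common items forming the PA and NA scales.
    extra_items_regular, extra_items_morning_evening
        Non-Likert items (context questions; sleep/alcohol add-ons in the
        morning and evening) that contribute to the per-assessment item
        count used for time-per-item, but are never scored.
    """

    n_ema_days: int = 14
    prompts_per_day: int = 4
    window_starts: tuple[int, ...] = (8, 12, 16, 20)
    window_length_minutes: int = 120
    reminder_minutes: int = 30
    n_items_common: int = 12
    likert_min: int = 1
    likert_max: int = 7
    pa_item_ids: tuple[int, ...] = (4, 5, 6, 7, 8)
    na_item_ids: tuple[int, ...] = (9, 10, 11, 12)
    extra_items_regular: int = 3
    extra_items_morning_evening: int = 8

    def __post_init__(self) -> None:
        if self.n_ema_days < 1 or self.prompts_per_day < 1:
            raise DesignError("need at least one day and one prompt per day")
        if len(self.window_starts) != self.prompts_per_day:
            raise DesignError(
                f"{self.prompts_per_day} prompts/day but "
                f"{len(self.window_starts)} window starts"
            )
        if self.likert_min >= self.likert_max:
            raise DesignError("likert_min must be below likert_max")
        pa, na = set(self.pa_item_ids), set(self.na_item_ids)
        if pa & na:
            raise DesignError("PA and NA item sets overlap")
        common = set(range(1, self.n_items_common + 1))
        if not (pa <= common and na <= common):
            raise DesignError("affect items must be among the common items")

    @property
    def max_prompts(self) -> int:
        """Design maximum of momentary assessments per participant (56)."""
        return self.n_ema_days * self.prompts_per_day

    def n_items_of_window(self, window: int) -> int:
        """Total item count of an assessment in the given window (1-based).

        Morning (first) and evening (last) assessments carry the add-on
        questions and are therefore longer than midday/afternoon ones.
        """
        if window in (1, self.prompts_per_day):
            return self.n_items_common + self.extra_items_morning_evening
        return self.n_items_common + self.extra_items_regular


#: Default design shared by the generator, metrics and pipeline.
DEFAULT_DESIGN = StudyDesign()
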