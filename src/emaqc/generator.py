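"""Seeded synthetic EMA cohort generator.

Emulates a 14-day, 4-prompts/day momentary-assessment study of university
students recruited into four mental-health quota subsamples.  The generator
produces three long-format tables:

* a participant table (invitation, participation, subsample, covariates),
* an assessment table (one row per scheduled prompt, with timestamps and the
  12 common Likert item responses when completed),
* a truth table holding the injected ground truth (careless labels, latent
  affect components) used only for validating the detection stages.

The affect model is a generalizability-theory style decomposition: each item
response is

    y[p, t, i] = mu + P[p] + T[p, t] + I[i] + PI[p, i] + e[p, t, i]

with person intercepts ``P``, momentary (time-within-person) deviations
``T``, item intercepts ``I``, person-by-item interactions ``PI`` and item
residuals ``e``, all Gaussian on the latent scale and mapped to the 1-7
Likert grid by rounding and clamping.  The scale-level variance targets
(``sigma2_between``, ``sigma2_within``) refer to the PA/NA *score* (mean of
k items), so the latent components are derived as

    var(P)  = sigma2_between - sigma2_person_item / k
    var(T)  = sigma2_within  - sigma2_error / k

which makes the simulated score variances land on the configured targets.

Missingness is completion-only: a prompt is either answered within its
2-hour window or missed entirely, with a person-specific completion
probability (Beta-distributed across persons) and a linear day trend.
Careless behaviour is injected as "fast" assessments (time-per-item below
one second, items answered uniformly at random) and "straight-lined"
assessments (all 12 items identical), concentrated in a small cluster of
participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .design import DEFAULT_DESIGN, StudyDesign

SUBSAMPLES = ("suicidal_ideation", "alcohol", "anxiety_depression", "control")

#: Covariate categories (reference level first) and their default sampling
#: probabilities, patterned on the composition of a large Spanish
#: university-student EMA cohort.
DEFAULT_COVARIATES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "sex": (("male", "female"), (0.208, 0.792)),
    "nationality": (("spanish", "other"), (0.923, 0.077)),
    "age_group": (("18-21", "22-25", "26-29", ">=30"), (0.738, 0.225, 0.027, 0.010)),
    "field_of_study": (
        (
            "arts_humanities",
            "sciences",
            "health_sciences",
            "social_legal",
            "engineering_architecture",
        ),
        (0.113, 0.120, 0.280, 0.358, 0.129),
    ),
}

EMA_START_DATE = datetime(2022, 4, 4)


class ConfigurationError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class ItemComponents:
    """Item-level variance components of one affect scale (latent units)."""

    sigma2_item: float
    sigma2_person_item: float
    sigma2_error: float

    def validate(self) -> None:
        if min(self.sigma2_item, self.sigma2_person_item, self.sigma2_error) < 0:
            raise ConfigurationError("item variance components must be >= 0")


@dataclass(frozen=True)
class ExposureSpec:
    """A binary baseline exposure with configurable effects.

    ``or_participation`` acts multiplicatively on the participation odds;
    ``rr_compliance`` multiplies the person-level completion probability.
    """

    name: str
    prevalence: float
    or_participation: float = 1.0
    rr_compliance: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Scale-level variance defaults reproduce the variance decomposition of
    momentary affect in a student EMA cohort (between/within ~0.9/0.8,
    ICC ~0.5); compliance defaults give a mean of 76.9% with wide
    person-to-person spread and a gentle linear decline over days.
    """

    n_participants: int = 782
    subsample_probs: tuple[float, float, float, float] = (0.214, 0.299, 0.263, 0.224)
    participation_prob: float = 0.621

    # scale-level (score) variance targets
    sigma2_between_pa: float = 0.94
    sigma2_within_pa: float = 0.81
    sigma2_between_na: float = 0.88
    sigma2_within_na: float = 0.80
    pa_mean: float = 4.2
    na_mean: float = 2.8
    #: correlation of PA and NA latents at the person / moment level;
    #: negative so that antonym item pairs (e.g. nervous vs relaxed)
    #: correlate negatively across assessments
    rho_between: float = -0.6
    rho_within: float = -0.4
    pa_items: ItemComponents = ItemComponents(0.05, 0.15, 2.0)
    na_items: ItemComponents = ItemComponents(0.05, 0.12, 1.3)
    #: residual variance of the three non-affect items (loading on NA)
    sigma2_error_other: float = 2.0
    #: lag-1 autocorrelation of momentary deviations; 0 = exchangeable
    ar1_rho: float = 0.0

    mean_compliance: float = 0.769
    person_compliance_sd: float = 0.27
    compliance_day_slope: float = -0.01

    careless_fraction_fast: float = 0.0013
    careless_fraction_straightline: float = 0.0078
    careless_cluster_size: int = 8
    careless_cluster_share: float = 0.5

    latency_median_minutes: float = 15.0
    tpi_median_seconds: float = 3.9
    #: log-scale SD of honest time-per-item; at 0.35 the honest tail below
    #: the 1-second careless threshold is negligible (~5e-5)
    tpi_log_sd: float = 0.35
    fast_tpi_range: tuple[float, float] = (0.3, 0.95)

    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    exposures: tuple[ExposureSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        probs = np.asarray(self.subsample_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subsample_probs must be >= 0 and sum to 1")
        for v in (
            self.sigma2_between_pa,
            self.sigma2_within_pa,
            self.sigma2_between_na,
            self.sigma2_within_na,
        ):
            if v < 0:
                raise ConfigurationError("variances must be >= 0")
        for p in (
            self.participation_prob,
            self.mean_compliance,
            self.careless_fraction_fast,
            self.careless_fraction_straightline,
            self.careless_cluster_share,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("proportions must lie in [0, 1]")
        if self.compliance_day_slope > 0:
            raise ConfigurationError("compliance_day_slope must be <= 0")
        self.pa_items.validate()
        self.na_items.validate()
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigurationError("ar1_rho must lie in (-1, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("pa_items", "na_items"):
            if key in d and isinstance(d[key], (list, tuple, dict)):
                d[key] = (
                    ItemComponents(**d[key])
                    if isinstance(d[key], dict)
                    else ItemComponents(*d[key])
                )
        if "exposures" in d:
            d["exposures"] = tuple(
                e if isinstance(e, ExposureSpec) else ExposureSpec(**e)
                for e in d["exposures"]
            )
        for key in ("subsample_probs", "fast_tpi_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# cohort


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta(a, b); shrinks sd if infeasible for the mean."""
    max_var = mean * (1 - mean)
    var = min(sd**2, 0.99 * max_var) if max_var > 0 else 0.0
    if var <= 0:
        return np.inf, np.inf  # degenerate: caller handles
    conc = max_var / var - 1.0
    return mean * conc, (1 - mean) * conc


def generate_cohort(
    config: GeneratorConfig, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Draw the invited cohort: subsamples, covariates and participation.

    Every row is an invited student; ``participated`` marks those who will
    go on to complete at least one momentary assessment (the realized flag
    is reconciled with the assessment table by :func:`generate_responses`).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    n = config.n_participants
    cohort = pd.DataFrame(
        {
            "person_id": [f"p{i:05d}" for i in range(1, n + 1)],
            "invited": 1,
            "subsample": rng.choice(SUBSAMPLES, size=n, p=config.subsample_probs),
        }
    )
    for name, (levels, probs) in config.covariates.items():
        probs = np.asarray(probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"covariate {name}: invalid probabilities")
        cohort[name] = rng.choice(levels, size=n, p=probs)

    logit0 = _logit(config.participation_prob)
    eta = np.full(n, logit0)
    for exp_spec in config.exposures:
        x = rng.binomial(1, exp_spec.prevalence, size=n)
        cohort[exp_spec.name] = x
        # centre the effect so the marginal participation stays on target
        eta += np.log(exp_spec.or_participation) * (x - exp_spec.prevalence)
    cohort["participated"] = rng.binomial(1, _expit(eta)).astype(int)
    return cohort


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# prompt schedule


def generate_prompt_schedule(
    cohort: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
    seed: int = 0,
) -> pd.DataFrame:
    """One prompt per person x day x window, uniform inside its 2-h window."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[1])
    persons = cohort["person_id"].to_numpy()
    n_p, n_d, n_w = len(persons), design.n_ema_days, design.prompts_per_day
    idx = pd.MultiIndex.from_product(
        [persons, range(1, n_d + 1), range(1, n_w + 1)],
        names=["person_id", "day", "window"],
    )
    sched = idx.to_frame(index=False)
    offsets = rng.uniform(0, design.window_length_minutes, size=len(sched))
    window_hours = np.asarray(design.window_starts)[sched["window"].to_numpy() - 1]
    prompt = (
        pd.Timestamp(EMA_START_DATE)
        + pd.to_timedelta(sched["day"].to_numpy() - 1, unit="D")
        + pd.to_timedelta(window_hours, unit="h")
        + pd.to_timedelta(offsets, unit="m")
    )
    sched["prompt_time"] = prompt
    sched["reminder_time"] = prompt + pd.Timedelta(minutes=design.reminder_minutes)
    sched["expiry_time"] = prompt + pd.Timedelta(minutes=design.window_length_minutes)
    sched["n_items"] = [design.n_items_of_window(w) for w in sched["window"]]
    return sched


# ---------------------------------------------------------------------------
# responses


def _latent_components(config: GeneratorConfig) -> dict[str, float]:
    """Latent component variances derived from the score-level targets."""
    k_pa, k_na = 5, 4
    out = {
        "var_p_pa": max(config.sigma2_between_pa - config.pa_items.sigma2_person_item / k_pa, 0.0),
        "var_t_pa": max(config.sigma2_within_pa - config.pa_items.sigma2_error / k_pa, 0.0),
        "var_p_na": max(config.sigma2_between_na - config.na_items.sigma2_person_item / k_na, 0.0),
        "var_t_na": max(config.sigma2_within_na - config.na_items.sigma2_error / k_na, 0.0),
    }
    return out


def _bivariate(rng, n, var_a, var_b, rho):
    """n draws of a zero-mean bivariate normal with given variances/corr."""
    z = rng.standard_normal((n, 2))
    b = rho * z[:, 0] + np.sqrt(max(1 - rho**2, 0.0)) * z[:, 1]
    return z[:, 0] * np.sqrt(var_a), b * np.sqrt(var_b)


def generate_responses(
    prompts: pd.DataFrame,
    config: GeneratorConfig,
    design: StudyDesign = DEFAULT_DESIGN,
    cohort: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the prompt schedule with completions, items and timestamps.

    ``cohort`` (the table from :func:`generate_cohort`) is only needed when
    exposures with compliance effects are configured.  Returns
    ``(assessments, truth)``; the truth table carries the injected careless
    labels and the per-person latent affect intercepts and is meant for
    validation only, never as an input to the analysis stages.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    df = prompts.sort_values(["person_id", "day", "window"], kind="stable").reset_index(
        drop=True
    )
    persons = df["person_id"].unique()
    n_pers = len(persons)
    pidx = pd.Series(np.arange(n_pers), index=persons)
    row_p = pidx[df["person_id"]].to_numpy()

    # --- completion process -------------------------------------------------
    a, b = _beta_params(config.mean_compliance, config.person_compliance_sd)
    if np.isinf(a):
        p_person = np.full(n_pers, config.mean_compliance)
    else:
        p_person = rng.beta(a, b, size=n_pers)
    if config.exposures and cohort is not None:
        cov = cohort.set_index("person_id")
        for exp_spec in config.exposures:
            if exp_spec.name in cov.columns and exp_spec.rr_compliance != 1.0:
                x = cov.loc[persons, exp_spec.name].to_numpy()
                p_person = p_person * exp_spec.rr_compliance**x
        p_person = np.clip(p_person, 0.0, 1.0)
    day = df["day"].to_numpy()
    day_centre = (design.n_ema_days + 1) / 2.0
    p_prompt = np.clip(
        p_person[row_p] + config.compliance_day_slope * (day - day_centre), 0.0, 1.0
    )
    completed = rng.binomial(1, p_prompt).astype(int)

    # --- latent affect ------------------------------------------------------
    lat = _latent_components(config)
    p_pa, p_na = _bivariate(
        rng, n_pers, lat["var_p_pa"], lat["var_p_na"], config.rho_between
    )
    n_rows = len(df)
    t_pa, t_na = _bivariate(
        rng, n_rows, lat["var_t_pa"], lat["var_t_na"], config.rho_within
    )
    if config.ar1_rho != 0.0:
        t_pa = _apply_ar1(t_pa, row_p, config.ar1_rho)
        t_na = _apply_ar1(t_na, row_p, config.ar1_rho)

    pa_occ = config.pa_mean + p_pa[row_p] + t_pa
    na_occ = config.na_mean + p_na[row_p] + t_na

    item_cols = [f"item_{i:02d}" for i in range(1, design.n_items_common + 1)]
    latent = np.empty((n_rows, design.n_items_common))
    item_fx = {
        i: rng.normal(
            0.0,
            np.sqrt(
                config.pa_items.sigma2_item
                if i in design.pa_item_ids
                else config.na_items.sigma2_item
                if i in design.na_item_ids
                else config.na_items.sigma2_item
            ),
        )
        for i in range(1, design.n_items_common + 1)
    }
    for j, i in enumerate(range(1, design.n_items_common + 1)):
        if i in design.pa_item_ids:
            comp, base = config.pa_items, pa_occ
        else:
            comp, base = config.na_items, na_occ
        s2_err = (
            config.sigma2_error_other
            if i not in design.pa_item_ids and i not in design.na_item_ids
            else comp.sigma2_error
        )
        pi = rng.normal(0.0, np.sqrt(comp.sigma2_person_item), size=n_pers)
        latent[:, j] = (
            base + item_fx[i] + pi[row_p] + rng.normal(0.0, np.sqrt(s2_err), size=n_rows)
        )
    items = np.clip(np.rint(latent), design.likert_min, design.likert_max).astype(int)

    # --- careless injection -------------------------------------------------
    comp_idx = np.flatnonzero(completed == 1)
    injected = np.full(n_rows, "none", dtype=object)
    cluster_ids = set(persons[: config.careless_cluster_size])
    in_cluster = np.array([p in cluster_ids for p in df["person_id"]])

    def _draw(n_target: int, exclude: np.ndarray) -> np.ndarray:
        """Pick n_target completed rows, a cluster share first, rest uniform."""
        if n_target <= 0:
            return np.empty(0, dtype=int)
        avail = comp_idx[~np.isin(comp_idx, exclude)]
        clus = avail[in_cluster[avail]]
        rest = avail[~in_cluster[avail]]
        n_clus = min(int(round(config.careless_cluster_share * n_target)), len(clus))
        pick = [rng.choice(clus, size=n_clus, replace=False)] if n_clus else []
        n_rest = min(n_target - n_clus, len(rest))
        if n_rest > 0:
            pick.append(rng.choice(rest, size=n_rest, replace=False))
        return np.concatenate(pick) if pick else np.empty(0, dtype=int)

    n_fast = int(round(config.careless_fraction_fast * len(comp_idx)))
    n_straight = int(round(config.careless_fraction_straightline * len(comp_idx)))
    fast_rows = _draw(n_fast, np.empty(0, dtype=int))
    straight_rows = _draw(n_straight, fast_rows)
    if len(fast_rows):
        injected[fast_rows] = "fast"
        items[fast_rows] = rng.integers(
            design.likert_min, design.likert_max + 1, size=(len(fast_rows), design.n_items_common)
        )
    if len(straight_rows):
        injected[straight_rows] = "straightline"
        items[straight_rows] = rng.integers(
            design.likert_min, design.likert_max + 1, size=(len(straight_rows), 1)
        )

    # --- timestamps ---------------------------------------------------------
    lat_rate = np.log(2.0) / config.latency_median_minutes
    latency_min = np.minimum(
        rng.exponential(1.0 / lat_rate, size=n_rows), design.window_length_minutes - 10.0
    )
    tpi = rng.lognormal(np.log(config.tpi_median_seconds), config.tpi_log_sd, size=n_rows)
    lo, hi = config.fast_tpi_range
    tpi[injected == "fast"] = rng.uniform(lo, hi, size=(injected == "fast").sum())
    duration_s = tpi * df["n_items"].to_numpy()

    out = df.copy()
    out["completed"] = completed
    start = out["prompt_time"] + pd.to_timedelta(latency_min, unit="m")
    end = start + pd.to_timedelta(duration_s, unit="s")
    out["start_time"] = start.where(completed == 1, pd.NaT)
    out["end_time"] = end.where(completed == 1, pd.NaT)
    items_df = pd.DataFrame(items, columns=item_cols)
    items_df[completed == 0] = pd.NA
    out[item_cols] = items_df.astype("Int64")

    truth = df[["person_id", "day", "window"]].copy()
    truth["injected_careless"] = np.where(completed == 1, injected, "none")
    truth["latent_pa_person"] = p_pa[row_p]
    truth["latent_na_person"] = p_na[row_p]
    truth["latent_pa_moment"] = pa_occ
    truth["latent_na_moment"] = na_occ
    return out, truth


def _apply_ar1(dev: np.ndarray, row_p: np.ndarray, rho: float) -> np.ndarray:
    """Impose lag-1 autocorrelation within each person, preserving variance."""
    out = dev.copy()
    scale = np.sqrt(1 - rho**2)
    for start in np.flatnonzero(np.r_[True, np.diff(row_p) != 0]):
        end = start
        while end + 1 < len(row_p) and row_p[end + 1] == row_p[start]:
            end += 1
        for t in range(start + 1, end + 1):
            out[t] = rho * out[t - 1] + scale * dev[t]
    return out


def finalize_participants(
    cohort: pd.DataFrame, assessments: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Attach realized n_completed / compliance and reconcile participation."""
    counts = (
        assessments[assessments["completed"] == 1]
        .groupby("person_id")
        .size()
        .rename("n_completed")
    )
    out = cohort.merge(counts, on="person_id", how="left")
    out["n_completed"] = out["n_completed"].fillna(0).astype(int)
    out["participated"] = (out["n_completed"] > 0).astype(int)
    out["compliance"] = out["n_completed"] / design.max_prompts
    return out


def simulate_cohort(
    config: GeneratorConfig, design: StudyDesign = DEFAULT_DESIGN
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """End-to-end generation: (participants, assessments, truth).

    Prompts are only scheduled for invited students who enter the study;
    non-participants appear in the participant table with zero completions.
    """
    cohort = generate_cohort(config, design)
    entrants = cohort[cohort["participated"] == 1]
    prompts = generate_prompt_schedule(entrants, design, seed=config.seed)
    assessments, truth = generate_responses(prompts, config, design, cohort=entrants)
    participants = finalize_participants(cohort, assessments, design)
    return participants, assessments, truth


def simulate_two_level_scores(
    n_persons: int,
    n_occasions: int,
    sigma2_between: float,
    sigma2_within: float,
    mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Continuous person x occasion scores from a plain two-level model.

    Used for variance-decomposition calibration: no discretization, no
    missingness — the estimand is exactly (sigma2_between, sigma2_within).
    """
    rng = np.random.default_rng(seed)
    person = np.repeat(np.arange(n_persons), n_occasions)
    intercept = rng.normal(0.0, np.sqrt(sigma2_between), size=n_persons)
    score = mean + intercept[person] + rng.normal(
        0.0, np.sqrt(sigma2_within), size=n_persons * n_occasions
    )
    return pd.DataFrame(
        {
            "person_id": [f"p{i:05d}" for i in person],
            "occasion": np.tile(np.arange(n_occasions), n_persons),
            "score": score,
        }
    )
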