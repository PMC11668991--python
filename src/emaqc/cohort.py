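"""Participation and compliance metrics and their covariate-adjusted models.

Participation is the share of invited students completing at least one
momentary assessment; a participant's compliance is their completed count
over the design maximum (56).  Predictors are assessed one exposure at a
time — logistic regression for participation (odds ratios) and Poisson
regression with a log(56) offset for completed counts (rate ratios,
exp(beta)) — each model adjusting for the four sociodemographic /
college-related covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .design import DEFAULT_DESIGN, StudyDesign

#: Adjustment covariates with their reference level first.
ADJUSTMENT_COVARIATES: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "nationality": ("spanish", "other"),
    "age_group": ("18-21", "22-25", "26-29", ">=30"),
    "field_of_study": (
        "arts_humanities",
        "sciences",
        "health_sciences",
        "social_legal",
        "engineering_architecture",
    ),
}


class MetricError(ValueError):
    pass


@dataclass
class RegressionResult:
    """One exposure's effect from a covariate-adjusted model.

    ``estimate`` is an odds ratio (participation) or exp(beta) rate ratio
    (compliance); CIs are 95% Wald intervals on the log scale.  When a model
    is non-estimable (separation, empty cells) ``estimable`` is False and a
    diagnostic explains why, rather than raising.
    """

    term: str
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    model: str
    n: int
    adjusted_for: list[str] = field(default_factory=list)
    estimable: bool = True
    diagnostic: str = ""

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "model": self.model,
            "n": self.n,
            "adjusted_for": list(self.adjusted_for),
            "estimable": self.estimable,
            "diagnostic": self.diagnostic,
        }


def participation_rate(n_invited: int, n_participated: int) -> float:
    """Participants (>=1 completed assessment) over all personal invitations."""
    if n_invited <= 0:
        raise MetricError("participation rate undefined for zero invitations")
    if not 0 <= n_participated <= n_invited:
        raise MetricError("n_participated must lie in [0, n_invited]")
    return n_participated / n_invited


def person_compliance(n_completed: int, design: StudyDesign = DEFAULT_DESIGN) -> float:
    """Completed assessments over the design maximum (no pro-rating)."""
    if not 0 <= n_completed <= design.max_prompts:
        raise MetricError(
            f"n_completed {n_completed} outside [0, {design.max_prompts}]"
        )
    return n_completed / design.max_prompts


def format_percent(p: float, decimals: int = 1) -> str:
    """Reporting helper: 0.446 -> '44.6%' (decimals=1) or '45%' (decimals=0)."""
    return f"{round(p * 100, decimals if decimals else None):.{decimals}f}%"


def compliance_summary(
    participants: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN, by: str | None = None
) -> pd.DataFrame:
    """Mean/SD/median/mode/range of per-person compliance, optionally by group.

    Statistics are over participants (not assessments); the mode lives on the
    discrete n_completed/max_prompts grid.
    """
    part = participants[participants["participated"] == 1]
    if part.empty:
        raise MetricError("no participants to summarize")

    def one(group: pd.DataFrame) -> pd.Series:
        c = group["n_completed"] / design.max_prompts
        return pd.Series(
            {
                "n": len(c),
                "mean": c.mean(),
                "sd": c.std(ddof=1) if len(c) > 1 else 0.0,
                "median": c.median(),
                "mode": c.mode().iloc[0],
                "min": c.min(),
                "max": c.max(),
            }
        )

    if by is None:
        return one(part).to_frame().T.assign(group="all").set_index("group")
    out = part.groupby(by).apply(one, include_groups=False)
    out.loc["all"] = one(part)
    return out


def compliance_by_day(
    assessments: pd.DataFrame, by: pd.Series | None = None
) -> tuple[pd.DataFrame, float | None]:
    """Per-day completion proportions and the fitted linear slope.

    Returns ``(table, slope)``; the slope (completion proportion per day,
    ordinary least squares on the daily means) is None when fewer than two
    days are observed.
    """
    df = assessments
    daily = df.groupby("day")["completed"].mean().rename("completion").reset_index()
    if by is not None:
        strat = df.assign(_g=by.to_numpy()).groupby(["_g", "day"])["completed"].mean()
        wide = strat.unstack(0)
        wide.columns = [str(c) for c in wide.columns]
        daily = daily.merge(wide, on="day")
    if daily["day"].nunique() < 2:
        return daily, None
    slope = float(np.polyfit(daily["day"], daily["completion"], 1)[0])
    return daily, slope


def _prepare_model_frame(
    df: pd.DataFrame, exposure: str, covariates: dict[str, tuple[str, ...]]
) -> tuple[pd.DataFrame, list[str]]:
    adj = [c for c in covariates if c in df.columns and c != exposure]
    cols = [exposure] + adj
    frame = df[cols].copy()
    for c in adj:
        frame[c] = pd.Categorical(
            frame[c], categories=[l for l in covariates[c] if l in set(frame[c])]
        )
    return frame, adj


def _wald_ci(params: pd.Series, bse: pd.Series, name: str) -> tuple[float, float, float]:
    est = float(np.exp(params[name]))
    half = 1.959963984540054 * float(bse[name])
    return est, float(np.exp(params[name] - half)), float(np.exp(params[name] + half))


def _exposure_term(fitted_params: pd.Series, exposure: str) -> str | None:
    for name in fitted_params.index:
        if name == exposure or name.startswith(f"C({exposure})") or name.startswith(
            f"{exposure}["
        ):
            return name
    return None


def fit_participation_model(
    invited: pd.DataFrame,
    exposure: str,
    covariates: dict[str, tuple[str, ...]] = ADJUSTMENT_COVARIATES,
) -> RegressionResult:
    """Logistic model of participation on one exposure plus the four
    adjustment covariates; separate model per exposure, never joint."""
    if exposure not in invited.columns:
        raise MetricError(f"exposure column {exposure!r} missing")
    frame, adj = _prepare_model_frame(invited, exposure, covariates)
    frame["participated"] = invited["participated"].to_numpy()
    rhs = " + ".join([exposure] + [f"C({c})" for c in adj]) or "1"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm(
                f"participated ~ {rhs}", data=frame, family=sm.families.Binomial()
            ).fit()
        term = _exposure_term(fit.params, exposure)
        if term is None or not np.isfinite(fit.bse[term]) or fit.bse[term] > 50:
            raise ValueError("exposure effect not estimable (separation or empty cell)")
        est, lo, hi = _wald_ci(fit.params, fit.bse, term)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return RegressionResult(
            exposure, None, None, None, "logistic", len(frame), adj, False, str(exc)
        )
    return RegressionResult(exposure, est, lo, hi, "logistic", len(frame), adj)


def fit_compliance_model(
    participants: pd.DataFrame,
    exposure: str,
    design: StudyDesign = DEFAULT_DESIGN,
    covariates: dict[str, tuple[str, ...]] = ADJUSTMENT_COVARIATES,
    robust: bool = False,
) -> RegressionResult:
    """Poisson model of completed counts with a log(max_prompts) offset.

    Counts out of 56 are not truly Poisson (they are under/over-dispersed),
    so ``robust=True`` switches to HC1 sandwich standard errors; the plain
    Poisson Wald CI is the default reporting convention.
    """
    if exposure not in participants.columns:
        raise MetricError(f"exposure column {exposure!r} missing")
    part = participants[participants["participated"] == 1]
    frame, adj = _prepare_model_frame(part, exposure, covariates)
    frame["n_completed"] = part["n_completed"].to_numpy()
    frame["offset"] = np.log(design.max_prompts)
    rhs = " + ".join([exposure] + [f"C({c})" for c in adj]) or "1"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(
                f"n_completed ~ {rhs}",
                data=frame,
                family=sm.families.Poisson(),
                offset=frame["offset"],
            )
            fit = model.fit(cov_type="HC1") if robust else model.fit()
        term = _exposure_term(fit.params, exposure)
        if term is None or not np.isfinite(fit.bse[term]) or fit.bse[term] > 50:
            raise ValueError("exposure effect not estimable (empty stratum)")
        est, lo, hi = _wald_ci(fit.params, fit.bse, term)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return RegressionResult(
            exposure, None, None, None, "poisson", len(frame), adj, False, str(exc)
        )
    return RegressionResult(exposure, est, lo, hi, "poisson", len(frame), adj)


def results_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Tidy (term, estimate, ci_low, ci_high, model, n) frame."""
    return pd.DataFrame([r.to_dict() for r in results])
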