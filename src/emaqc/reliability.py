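"""Multilevel variance decomposition and reliability of momentary affect.

Two complementary decompositions are provided.

*Two-level* (score level): a random-intercept model splits a PA/NA score's
variance into a between-person part ``sigma2_between`` and a momentary
within-person part ``sigma2_within``; their ratio gives the intraclass
correlation ICC = sB / (sB + sW).  An ICC below 0.5 means the score moves
mostly within persons, which is what justifies momentary sampling at all.

*Three-level* (item level): items nested in assessments nested in persons,
with a person effect sP, a time-within-person effect sT, an item effect sI,
a person-by-item interaction sPI and an item residual sE.  From these the
generalizability-theory coefficients of Shrout & Lane are formed:

    R_kRn = (sP + sPI/k) / (sP + sPI/k + sT/n + sE/(k*n))   (between-person)
    R_cn  = sT / (sT + sE/k)                                 (within-person)

with k items per scale and n time points per person.  For unbalanced data n
is the harmonic mean of per-person occasion counts (the balanced case
reduces to the common n).  Estimation uses REML; on perfectly balanced data
the REML solution coincides with the classical expected-mean-squares
estimator, which is also implemented and used for fast balanced fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DEFAULT_DESIGN, StudyDesign

#: Classic test-theory interpretation bands for reliability coefficients.
RELIABILITY_BANDS = (
    (0.105, "practically none"),
    (0.405, "slight"),
    (0.605, "fair"),
    (0.805, "moderate"),
    (np.inf, "substantial"),
)


class ReliabilityError(ValueError):
    pass


def reliability_band(value: float) -> str:
    """Interpretation label; the value is rounded to 2 decimals first, so
    band edges follow the printed convention (0.11-0.40 slight, ...)."""
    v = round(value, 2)
    for upper, label in RELIABILITY_BANDS:
        if v < upper:
            return label
    return "substantial"


@dataclass
class TwoLevelComponents:
    sigma2_between: float
    sigma2_within: float
    n_persons: int = 0
    n_obs: int = 0
    diagnostics: list[str] = field(default_factory=list)

    @property
    def icc(self) -> float | None:
        return icc_from_components(self.sigma2_between, self.sigma2_within)


@dataclass
class ThreeLevelComponents:
    sigma2_person: float
    sigma2_time_in_person: float
    sigma2_item: float
    sigma2_person_item: float
    sigma2_error: float
    k: int
    n: float
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class ReliabilityReport:
    r_krn: float
    r_cn: float
    band_between: str
    band_within: str


def icc_from_components(sigma2_between: float, sigma2_within: float) -> float | None:
    """Between-person variance over total; None when both components are 0."""
    if sigma2_between < 0 or sigma2_within < 0:
        raise ReliabilityError("variance components must be >= 0")
    total = sigma2_between + sigma2_within
    if total == 0:
        return None
    return sigma2_between / total


def _oneway_ems(scores: pd.DataFrame, value: str, group: str) -> tuple[float, float]:
    """Balanced one-way ANOVA estimator: sB = (MSB - MSW)/n, sW = MSW."""
    g = scores.groupby(group)[value]
    n = int(g.size().iloc[0])
    means = g.mean()
    grand = scores[value].mean()
    msb = n * ((means - grand) ** 2).sum() / (len(means) - 1)
    msw = ((scores[value] - means[scores[group]].to_numpy()) ** 2).sum() / (
        len(scores) - len(means)
    )
    return max((msb - msw) / n, 0.0), msw


def decompose_two_level(
    scores: pd.DataFrame,
    value: str = "score",
    person: str = "person_id",
    method: str = "auto",
) -> TwoLevelComponents:
    """Random-intercept decomposition of a long person x occasion table.

    ``method='auto'`` applies the closed-form one-way ANOVA estimator when
    every person has the same occasion count — on balanced data it is the
    REML solution, computed exactly — and REML for unbalanced data; an
    all-constant input returns (0, 0) with a diagnostic.
    """
    df = scores[[person, value]].dropna()
    if df[person].nunique() < 2 or df.groupby(person).size().min() < 1:
        raise ReliabilityError("need >= 2 persons with observations")
    diags: list[str] = []
    if np.ptp(df[value].to_numpy()) == 0:
        return TwoLevelComponents(
            0.0, 0.0, df[person].nunique(), len(df), ["all scores constant"]
        )
    balanced = df.groupby(person).size().nunique() == 1
    if method == "ems" or (method == "auto" and balanced):
        if not balanced:
            raise ReliabilityError("one-way EMS estimator requires balanced data")
        s_b, s_w = _oneway_ems(df, value, person)
        return TwoLevelComponents(s_b, s_w, df[person].nunique(), len(df), diags)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(f"{value} ~ 1", groups=person, data=df)
        try:
            fit = model.fit(reml=True)
            # warm restart with a tight gradient tolerance sharpens the
            # variance estimates to numerical precision
            fit = model.fit(reml=True, start_params=fit.params_object, gtol=1e-10)
            s_b = float(fit.cov_re.iloc[0, 0])
            s_w = float(fit.scale)
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            diags.append(f"REML failed ({exc}); one-way moment estimator used")
            s_b, s_w = _oneway_ems(df, value, person)
    if s_b < 0:
        diags.append("negative between-person estimate truncated to 0")
        s_b = 0.0
    return TwoLevelComponents(s_b, s_w, df[person].nunique(), len(df), diags)


def _is_balanced(df: pd.DataFrame, person: str, occasion: str, item: str) -> bool:
    per_occ = df.groupby(person)[occasion].nunique()
    per_item = df.groupby([person, occasion])[item].nunique()
    return (
        per_occ.nunique() == 1
        and per_item.nunique() == 1
        and len(df) == per_occ.iloc[0] * per_item.iloc[0] * df[person].nunique()
    )


def _ems_three_level(
    df: pd.DataFrame, value: str, person: str, occasion: str, item: str
) -> ThreeLevelComponents:
    """Expected-mean-squares solution for the balanced p x i, t:p design."""
    a = df[person].nunique()
    n = df.groupby(person)[occasion].nunique().iloc[0]
    k = df[item].nunique()
    y = df[value].astype(float)
    grand = y.mean()
    m_p = df.groupby(person)[value].transform("mean")
    m_pt = df.groupby([person, occasion])[value].transform("mean")
    m_i = df.groupby(item)[value].transform("mean")
    m_pi = df.groupby([person, item])[value].transform("mean")

    ss_p = ((m_p - grand) ** 2).sum()
    ss_t = ((m_pt - m_p) ** 2).sum()
    ss_i = ((m_i - grand) ** 2).sum()
    ss_pi = ((m_pi - m_p - m_i + grand) ** 2).sum()
    ss_e = ((y - m_pt - m_pi + m_p) ** 2).sum()

    ms_p = ss_p / (a - 1)
    ms_t = ss_t / (a * (n - 1)) if n > 1 else 0.0
    ms_i = ss_i / (k - 1)
    ms_pi = ss_pi / ((a - 1) * (k - 1))
    ms_e = ss_e / (a * (n - 1) * (k - 1)) if n > 1 else 0.0

    diags: list[str] = []

    def trunc(v: float, name: str) -> float:
        if v < 0:
            diags.append(f"negative {name} estimate truncated to 0")
            return 0.0
        return v

    s_e = ms_e
    s_pi = trunc((ms_pi - ms_e) / n, "person-x-item")
    s_t = trunc((ms_t - ms_e) / k, "time-in-person")
    s_i = trunc((ms_i - ms_pi) / (a * n), "item")
    s_p = trunc((ms_p - ms_t - ms_pi + ms_e) / (n * k), "person")
    return ThreeLevelComponents(s_p, s_t, s_i, s_pi, s_e, k, float(n), diags)


def decompose_three_level(
    responses: pd.DataFrame,
    value: str = "value",
    person: str = "person_id",
    occasion: str = "occasion",
    item: str = "item",
    method: str = "auto",
) -> ThreeLevelComponents:
    """Variance components of item responses: person, time-in-person, item,
    person-x-item and residual.

    ``method='auto'`` uses the closed-form expected-mean-squares solution
    when the design is balanced and REML otherwise.  The REML fit treats the
    (few) items as fixed effects and estimates sP, sT, sPI, sE as random
    components grouped by person; the item variance sI — which enters no
    reliability coefficient — is then recovered from the spread of the item
    means with a moment correction.
    """
    df = responses[[person, occasion, item, value]].dropna()
    if df[person].nunique() < 2 or df[item].nunique() < 2:
        raise ReliabilityError("need >= 2 persons and >= 2 items")
    if np.ptp(df[value].to_numpy()) == 0:
        k = df[item].nunique()
        n = float(df.groupby(person)[occasion].nunique().mean())
        return ThreeLevelComponents(0, 0, 0, 0, 0, k, n, ["all responses constant"])
    balanced = _is_balanced(df, person, occasion, item)
    if method == "ems" or (method == "auto" and balanced):
        if not balanced:
            raise ReliabilityError("EMS estimator requires a balanced design")
        return _ems_three_level(df, value, person, occasion, item)

    counts = df.groupby(person)[occasion].nunique()
    n_harm = float(len(counts) / (1.0 / counts).sum())
    k = df[item].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            f"{value} ~ C({item})",
            groups=person,
            re_formula="1",
            vc_formula={
                "occ": f"0 + C({occasion})",
                "pxi": f"0 + C({item})",
            },
            data=df,
        )
        fit = model.fit(reml=True)
        fit = model.fit(reml=True, start_params=fit.params_object, gtol=1e-10)
    s_p = max(float(fit.cov_re.iloc[0, 0]), 0.0)
    s_t = max(float(fit.vcomp[0]), 0.0)
    s_pi = max(float(fit.vcomp[1]), 0.0)
    s_e = float(fit.scale)
    # item main-effect variance from the item means (moment correction for
    # the person-x-item and residual noise they carry)
    item_means = df.groupby(item)[value].mean()
    n_per_item = df.groupby(item)[value].size()
    a = df[person].nunique()
    s_i = max(
        float(item_means.var(ddof=1))
        - s_pi / a
        - s_e * float((1.0 / n_per_item).mean()),
        0.0,
    )
    diags = [d for d in ["REML (unbalanced)"]]
    return ThreeLevelComponents(s_p, s_t, s_i, s_pi, s_e, k, n_harm, diags)


def multilevel_reliability(components: ThreeLevelComponents) -> ReliabilityReport:
    """Shrout-Lane between-person (R_kRn) and within-person (R_cn)
    reliability from the three-level components."""
    k, n = components.k, components.n
    if k < 2 or n < 2:
        raise ReliabilityError("need k >= 2 items and n >= 2 time points")
    s_p, s_t = components.sigma2_person, components.sigma2_time_in_person
    s_pi, s_e = components.sigma2_person_item, components.sigma2_error
    num_b = s_p + s_pi / k
    den_b = num_b + s_t / n + s_e / (k * n)
    den_w = s_t + s_e / k
    if den_b == 0 or den_w == 0:
        r_krn = float("nan") if den_b == 0 else num_b / den_b
        r_cn = float("nan") if den_w == 0 else 0.0
    else:
        r_krn = num_b / den_b
        r_cn = s_t / den_w
    r_krn = float(np.clip(r_krn, 0.0, 1.0)) if np.isfinite(r_krn) else r_krn
    r_cn = float(np.clip(r_cn, 0.0, 1.0)) if np.isfinite(r_cn) else r_cn
    return ReliabilityReport(
        r_krn,
        r_cn,
        reliability_band(r_krn) if np.isfinite(r_krn) else "undefined",
        reliability_band(r_cn) if np.isfinite(r_cn) else "undefined",
    )


def person_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Raw Cronbach alpha of one person's occasion x item matrix across time.

    Returns NaN when fewer than 2 occasions exist or the occasion totals
    never vary (a participant answering identically throughout has no
    defined internal consistency).  Alpha may legitimately be negative.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ReliabilityError("need an occasion x item matrix with >= 2 items")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n_occ, k = arr.shape
    if n_occ < 2:
        return float("nan")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def person_alpha_table(
    assessments: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Per-person raw alpha for the PA and NA item sets across occasions."""
    pa_cols = [f"item_{i:02d}" for i in design.pa_item_ids]
    na_cols = [f"item_{i:02d}" for i in design.na_item_ids]
    done = assessments[assessments["completed"] == 1]
    rows = []
    for pid, grp in done.groupby("person_id"):
        rows.append(
            {
                "person_id": pid,
                "n_completed": len(grp),
                "alpha_pa": person_alpha(grp[pa_cols]) if len(grp) else float("nan"),
                "alpha_na": person_alpha(grp[na_cols]) if len(grp) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def stability_icc(pairs: pd.DataFrame | np.ndarray) -> float:
    """Two-way single-rater absolute-agreement ICC of an N x 2 table
    (persons x measurements), e.g. subset statistic vs gold standard.

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/N (MSC - MSE)).
    Negative values are reported as-is (near-zero agreement), not clamped.
    """
    arr = np.asarray(pairs, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ReliabilityError("need >= 3 persons with exactly 2 measurements")
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((arr - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def harmonic_mean_occasions(assessments: pd.DataFrame) -> float:
    """Harmonic mean of completed-occasion counts per person."""
    counts = (
        assessments[assessments["completed"] == 1].groupby("person_id").size()
    )
    counts = counts[counts > 0]
    return float(len(counts) / (1.0 / counts).sum())


def affect_items_long(
    assessments: pd.DataFrame, scale: str, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Completed assessments in long person x occasion x item form for one
    affect scale ('pa' or 'na')."""
    ids = design.pa_item_ids if scale == "pa" else design.na_item_ids
    cols = [f"item_{i:02d}" for i in ids]
    done = assessments[assessments["completed"] == 1].copy()
    done["occasion"] = done["day"].astype(int) * 10 + done["window"].astype(int)
    long = done.melt(
        id_vars=["person_id", "occasion"],
        value_vars=cols,
        var_name="item",
        value_name="value",
    )
    long["value"] = long["value"].astype(float)
    return long
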