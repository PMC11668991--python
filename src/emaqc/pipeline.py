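"""End-to-end data-quality pipeline and consolidated report.

Stages: (optional) simulate -> score -> compliance -> reliability ->
careless -> report.  The report is a nested, JSON-serializable dictionary
whose blocks mirror the analysis stages; identical configuration and seed
give an identical report.  Internal EMA days 1..14 correspond to study days
2..15 (the first and last study day carry questionnaires, not momentary
prompts); the mapping is recorded in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ema_io
from .careless import (
    CarelessRuleConfig,
    antonym_threshold_curve,
    careless_response_summary,
    careless_responder_summary,
    flag_careless_responders,
    flag_careless_responses,
    minimum_valid_assessments,
    select_antonyms,
)
from .cohort import (
    compliance_by_day,
    compliance_summary,
    fit_compliance_model,
    fit_participation_model,
    participation_rate,
    results_table,
)
from .design import DEFAULT_DESIGN, StudyDesign
from .generator import GeneratorConfig, simulate_cohort
from .reliability import (
    affect_items_long,
    decompose_three_level,
    decompose_two_level,
    multilevel_reliability,
    person_alpha_table,
)
from .scores import enrich_assessments

log = logging.getLogger("emaqc")

SCHEMA_VERSION = "1.0"


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``generator`` (simulate a cohort) or
    ``participants_path``/``assessments_path`` (load tables) must be given.
    """

    generator: GeneratorConfig | None = None
    participants_path: str | None = None
    assessments_path: str | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    careless: CarelessRuleConfig = field(default_factory=CarelessRuleConfig)
    exposures: list[str] = field(default_factory=list)
    #: persons entering the item-level (three-level) reliability fit; None
    #: fits everyone.  The REML fit cost grows with persons x occasions x
    #: items, so large cohorts can be decomposed on a person subsample.
    three_level_max_persons: int | None = 250
    include_three_level: bool = True
    include_stability: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_tables = self.participants_path is not None and self.assessments_path is not None
        if (self.generator is None) == (not has_tables):
            raise PipelineError(
                "supply exactly one of a generator config or both table paths"
            )


def _round(x, nd=4):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return None
    return round(float(x), nd)


def _strata(participants: pd.DataFrame) -> dict[str, pd.Index]:
    """Analysis strata: everyone, control subsample, pooled mental-health."""
    out = {"all": participants["person_id"]}
    if "subsample" in participants.columns:
        out["control"] = participants.loc[
            participants["subsample"] == "control", "person_id"
        ]
        out["mental_health"] = participants.loc[
            participants["subsample"] != "control", "person_id"
        ]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the quality report."""
    design = config.design
    if config.generator is not None:
        log.info("simulating cohort (seed=%d)", config.generator.seed)
        participants, assessments, _truth = simulate_cohort(config.generator, design)
    else:
        participants = ema_io.read_participants(config.participants_path)
        assessments = ema_io.read_assessments(config.assessments_path, design)
    log.info(
        "inputs: %d invited, %d assessment rows", len(participants), len(assessments)
    )

    enriched = enrich_assessments(assessments, design)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "day_labeling": "internal EMA days 1-14 = study days 2-15",
        "n_invited": int(participants["invited"].sum()),
        "n_participants": int(participants["participated"].sum()),
    }

    # --- participation / compliance ----------------------------------------
    n_inv = int(participants["invited"].sum())
    n_part = int(participants["participated"].sum())
    rate = participation_rate(n_inv, n_part)
    summ = compliance_summary(participants, design, by="subsample" if "subsample" in participants.columns else None)
    part_assess = enriched[
        enriched["person_id"].isin(
            participants.loc[participants["participated"] == 1, "person_id"]
        )
    ]
    daily, slope = compliance_by_day(part_assess)
    participation_models = [
        fit_participation_model(participants[participants["invited"] == 1], e)
        for e in config.exposures
    ]
    compliance_models = [
        fit_compliance_model(participants, e, design) for e in config.exposures
    ]
    report["participation"] = {
        "rate": _round(rate),
        "n_invited": n_inv,
        "n_participated": n_part,
        "models": results_table(participation_models).to_dict("records")
        if participation_models
        else [],
    }
    report["compliance"] = {
        "summary": {
            g: {k: _round(v) for k, v in row.items()}
            for g, row in summ.to_dict("index").items()
        },
        "by_day": {
            "day": daily["day"].tolist(),
            "completion": [_round(v) for v in daily["completion"]],
            "slope_per_day": _round(slope, 5),
        },
        "models": results_table(compliance_models).to_dict("records")
        if compliance_models
        else [],
    }

    # --- reliability --------------------------------------------------------
    rel_block: dict = {"two_level": {}, "three_level": {}}
    strata = _strata(participants)
    for stratum, ids in strata.items():
        sub = part_assess[part_assess["person_id"].isin(set(ids))]
        if sub["person_id"].nunique() < 2:
            continue
        for scale in ("pa", "na"):
            scores = sub[sub["completed"] == 1][["person_id", f"{scale}_score"]]
            comp = decompose_two_level(scores, value=f"{scale}_score")
            rel_block["two_level"][f"{stratum}_{scale}"] = {
                "sigma2_between": _round(comp.sigma2_between),
                "sigma2_within": _round(comp.sigma2_within),
                "icc": _round(comp.icc, 2),
                "n_persons": comp.n_persons,
                "n_obs": comp.n_obs,
            }
    if config.include_three_level:
        rng = np.random.default_rng(config.seed)
        for scale in ("pa", "na"):
            long = affect_items_long(part_assess, scale, design)
            persons = long["person_id"].unique()
            if config.three_level_max_persons and len(persons) > config.three_level_max_persons:
                keep = rng.choice(
                    persons, size=config.three_level_max_persons, replace=False
                )
                long = long[long["person_id"].isin(set(keep))]
            comp3 = decompose_three_level(
                long, value="value", occasion="occasion", item="item"
            )
            rel = multilevel_reliability(comp3)
            rel_block["three_level"][scale] = {
                "sigma2_person": _round(comp3.sigma2_person),
                "sigma2_time_in_person": _round(comp3.sigma2_time_in_person),
                "sigma2_item": _round(comp3.sigma2_item),
                "sigma2_person_item": _round(comp3.sigma2_person_item),
                "sigma2_error": _round(comp3.sigma2_error),
                "k": comp3.k,
                "n_harmonic": _round(comp3.n),
                "r_krn": _round(rel.r_krn, 2),
                "r_cn": _round(rel.r_cn, 2),
                "band_between": rel.band_between,
                "band_within": rel.band_within,
            }
    alphas = person_alpha_table(part_assess, design)
    rel_block["person_alpha"] = {
        "n": len(alphas),
        "n_undefined_pa": int(alphas["alpha_pa"].isna().sum()),
        "n_undefined_na": int(alphas["alpha_na"].isna().sum()),
        "n_negative": int(
            ((alphas["alpha_pa"] < 0) | (alphas["alpha_na"] < 0)).sum()
        ),
        "median_pa": _round(alphas["alpha_pa"].median(), 2),
        "median_na": _round(alphas["alpha_na"].median(), 2),
    }
    report["reliability"] = rel_block

    # --- careless -----------------------------------------------------------
    flagged = flag_careless_responses(part_assess, config.careless)
    resp_summary = careless_response_summary(flagged)
    pair, full_r, diags = select_antonyms(part_assess, design=design)
    curves = {
        "time_per_item": antonym_threshold_curve(
            flagged, "time_per_item", [0.5, 1.0, 2.0, 3.0, 5.0], pair
        ),
        "sd_items": antonym_threshold_curve(
            flagged, "sd_items", [0.0, 0.25, 0.5, 1.0, 2.0], pair
        ),
        "pct_mode": antonym_threshold_curve(
            flagged, "pct_mode", [0.4, 0.6, 0.8, 1.0], pair
        ),
    }
    careless_block: dict = {
        "responses": resp_summary,
        "antonyms": {"pair": list(pair), "full_sample_r": _round(full_r),
                     "diagnostics": diags},
        "threshold_curves": {
            k: v.drop(columns="parameter").to_dict("records") for k, v in curves.items()
        },
    }
    minimum = None
    if config.include_stability:
        try:
            curve = minimum_valid_assessments(part_assess, config.careless, config.seed)
            minimum = curve.minimum_valid_assessments
            careless_block["stability"] = {
                "minimum_valid_assessments": minimum,
                "reached": curve.reached,
                "n_persons": curve.n_persons,
                "curves": curve.curves.round(4).to_dict("records"),
            }
        except Exception as exc:  # too few eligible persons etc.
            careless_block["stability"] = {"error": str(exc)}
    if minimum is None:
        minimum = config.careless.subset_max  # conservative fallback
    responders = flag_careless_responders(
        participants, flagged, alphas, minimum, config.careless
    )
    careless_block["responders"] = careless_responder_summary(responders)
    careless_block["responders"]["minimum_valid_assessments_used"] = int(minimum)
    report["careless"] = careless_block

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ema_io.write_participants(participants, out / "participants.csv")
        ema_io.write_assessments(enriched, out / "assessments_enriched.csv")
        responders.to_csv(out / "careless_responders.csv", index=False)
        alphas.to_csv(out / "person_alpha.csv", index=False)
        (out / "quality_report.json").write_text(json.dumps(report, indent=2))
        (out / "quality_report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering: percentages to 1 decimal, coefficients to 2."""
    lines = [
        "EMA data-quality report",
        f"schema {report['schema_version']}, seed {report['seed']}",
        f"({report['day_labeling']})",
        "",
        "Participation",
        f"  invited: {report['participation']['n_invited']}",
        f"  participated: {report['participation']['n_participated']}"
        f" ({report['participation']['rate'] * 100:.1f}%)",
        "",
        "Compliance",
    ]
    for group, s in report["compliance"]["summary"].items():
        lines.append(
            f"  {group}: mean {s['mean'] * 100:.1f}% (SD {s['sd'] * 100:.1f}%), "
            f"median {s['median'] * 100:.1f}%, mode {s['mode'] * 100:.1f}%, "
            f"range {s['min'] * 100:.1f}%-{s['max'] * 100:.1f}%"
        )
    slope = report["compliance"]["by_day"]["slope_per_day"]
    if slope is not None:
        lines.append(f"  linear day trend: {slope * 100:+.2f} points/day")
    lines += ["", "Reliability (two-level ICC)"]
    for key, c in report["reliability"]["two_level"].items():
        lines.append(
            f"  {key}: between {c['sigma2_between']:.2f}, within "
            f"{c['sigma2_within']:.2f}, ICC {c['icc']:.2f}"
        )
    if report["reliability"]["three_level"]:
        lines.append("Reliability (multilevel)")
        for scale, c in report["reliability"]["three_level"].items():
            lines.append(
                f"  {scale}: R_kRn {c['r_krn']:.2f} ({c['band_between']}), "
                f"R_cn {c['r_cn']:.2f} ({c['band_within']})"
            )
    cr = report["careless"]["responses"]
    lines += [
        "",
        "Careless responses",
        f"  flagged: {cr['n_flagged']}/{cr['n_completed']}"
        f" ({cr['share_flagged'] * 100:.2f}%)"
        f" [fast {cr['n_fast']}, straight-line {cr['n_straightline']},"
        f" both {cr['n_both']}]",
    ]
    rd = report["careless"]["responders"]
    lines.append(
        f"  responders flagged: {rd['n_flagged']}/{rd['n_participants']}"
        f" ({rd['share_flagged'] * 100:.1f}%)"
        f" [low valid {rd['n_low_valid']}, low alpha {rd['n_low_alpha']},"
        f" both {rd['n_both']}]"
    )
    stab = report["careless"].get("stability", {})
    if "minimum_valid_assessments" in stab:
        m = stab["minimum_valid_assessments"]
        lines.append(
            "  minimum valid assessments: "
            + (str(m) if m is not None else "not reached")
        )
    return "\n".join(lines) + "\n"
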