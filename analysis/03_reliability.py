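#!/usr/bin/env python
"""Variance decomposition and reliability of momentary affect.

Two-level decomposition of the PA/NA scores per stratum (all participants,
control subsample, pooled mental-health subsamples) with ICCs; three-level
item decomposition feeding the Shrout-Lane between-person (R_kRn) and
within-person (R_cn) reliability coefficients; per-person raw Cronbach
alpha distribution.  The item-level REML fit runs on a person subsample to
keep the mixed-model cost modest (estimates are person-level averages and
stabilize well before the full cohort size).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from emaqc import (
    GeneratorConfig,
    decompose_three_level,
    decompose_two_level,
    enrich_assessments,
    multilevel_reliability,
    person_alpha_table,
    simulate_cohort,
)
from emaqc.reliability import affect_items_long

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-participants", type=int, default=780)
    parser.add_argument("--three-level-persons", type=int, default=200)
    args = parser.parse_args()

    config = GeneratorConfig(n_participants=args.n_participants, seed=args.seed)
    participants, assessments, _ = simulate_cohort(config)
    enriched = enrich_assessments(assessments)
    done = enriched[enriched["completed"] == 1]
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    by_person = participants.set_index("person_id")["subsample"]
    strata = {
        "all": set(participants["person_id"]),
        "control": set(by_person[by_person == "control"].index),
        "mental_health": set(by_person[by_person != "control"].index),
    }
    rows = []
    for stratum, ids in strata.items():
        sub = done[done["person_id"].isin(ids)]
        for scale in ("pa", "na"):
            comp = decompose_two_level(
                sub[["person_id", f"{scale}_score"]], value=f"{scale}_score"
            )
            rows.append(
                {
                    "stratum": stratum,
                    "scale": scale,
                    "sigma2_between": round(comp.sigma2_between, 3),
                    "sigma2_within": round(comp.sigma2_within, 3),
                    "icc": round(comp.icc, 2),
                    "n_persons": comp.n_persons,
                }
            )
    two_level = pd.DataFrame(rows)
    two_level.to_csv(out / "03_variance_components.csv", index=False)

    rng = np.random.default_rng(args.seed)
    rel_rows = []
    for scale in ("pa", "na"):
        long = affect_items_long(enriched, scale)
        persons = long["person_id"].unique()
        if len(persons) > args.three_level_persons:
            keep = set(rng.choice(persons, args.three_level_persons, replace=False))
            long = long[long["person_id"].isin(keep)]
        comp = decompose_three_level(long, occasion="occasion")
        rel = multilevel_reliability(comp)
        rel_rows.append(
            {
                "scale": scale,
                "k_items": comp.k,
                "n_harmonic": round(comp.n, 1),
                "sigma2_person": round(comp.sigma2_person, 3),
                "sigma2_time_in_person": round(comp.sigma2_time_in_person, 3),
                "sigma2_item": round(comp.sigma2_item, 3),
                "sigma2_person_item": round(comp.sigma2_person_item, 3),
                "sigma2_error": round(comp.sigma2_error, 3),
                "r_krn": round(rel.r_krn, 2),
                "r_cn": round(rel.r_cn, 2),
                "band_between": rel.band_between,
                "band_within": rel.band_within,
            }
        )
    multilevel = pd.DataFrame(rel_rows)
    multilevel.to_csv(out / "03_multilevel_reliability.csv", index=False)

    alphas = person_alpha_table(enriched)
    alpha_summary = {
        "n": len(alphas),
        "undefined_pa": int(alphas["alpha_pa"].isna().sum()),
        "undefined_na": int(alphas["alpha_na"].isna().sum()),
        "negative_either": int(
            ((alphas["alpha_pa"] < 0) | (alphas["alpha_na"] < 0)).sum()
        ),
        "share_above_0.60_pa": round(float((alphas["alpha_pa"] > 0.6).mean()), 3),
        "share_above_0.60_na": round(float((alphas["alpha_na"] > 0.6).mean()), 3),
        "median_pa": round(float(alphas["alpha_pa"].median()), 3),
        "median_na": round(float(alphas["alpha_na"].median()), 3),
    }
    (out / "03_person_alpha_summary.json").write_text(
        json.dumps(alpha_summary, indent=2)
    )

    print(two_level.to_string(index=False))
    print()
    print(multilevel[["scale", "r_krn", "r_cn", "band_between", "band_within"]]
          .to_string(index=False))
    print(f"\nperson alpha: median PA {alpha_summary['median_pa']}, "
          f"NA {alpha_summary['median_na']}; "
          f"{alpha_summary['undefined_pa']} undefined (PA)")


if __name__ == "__main__":
    main()
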