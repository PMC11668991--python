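#!/usr/bin/env python
"""Careless-response and careless-responder detection.

Selects the psychometric antonym pair, traces the antonym correlation
across thresholds of the three careless parameters (time per item, item
SD, share at mode), applies the response rule (TPI <= 1 s or zero
variance), runs the resampling stability analysis that sets the minimum
number of valid assessments, and flags potential careless responders.
Detection quality is scored against the generator's injected truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from emaqc import (
    CarelessRuleConfig,
    GeneratorConfig,
    antonym_threshold_curve,
    enrich_assessments,
    flag_careless_responders,
    flag_careless_responses,
    minimum_valid_assessments,
    person_alpha_table,
    select_antonyms,
    simulate_cohort,
)
from emaqc.careless import careless_responder_summary, careless_response_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-participants", type=int, default=780)
    args = parser.parse_args()

    config = GeneratorConfig(n_participants=args.n_participants, seed=args.seed)
    participants, assessments, truth = simulate_cohort(config)
    enriched = enrich_assessments(assessments)
    rules = CarelessRuleConfig()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    pair, full_r, diags = select_antonyms(enriched)
    curves = pd.concat(
        [
            antonym_threshold_curve(enriched, "time_per_item",
                                    [0.5, 1.0, 2.0, 3.0, 5.0, 10.0], pair),
            antonym_threshold_curve(enriched, "sd_items",
                                    [0.0, 0.25, 0.5, 1.0, 1.5, 2.0], pair),
            antonym_threshold_curve(enriched, "pct_mode",
                                    [0.4, 0.5, 0.6, 0.8, 1.0], pair),
        ]
    )
    curves.to_csv(out / "04_antonym_threshold_curves.csv", index=False)

    flagged = flag_careless_responses(enriched, rules)
    resp = careless_response_summary(flagged)

    merged = flagged.merge(truth, on=["person_id", "day", "window"])
    injected = merged["injected_careless"] != "none"
    detected = merged["careless"] == 1
    sensitivity = float((detected & injected).sum() / injected.sum())
    false_rate = float((detected & ~injected).sum() / (~injected & (merged["completed"] == 1)).sum())

    curve = minimum_valid_assessments(enriched, rules, seed=args.seed)
    curve.curves.to_csv(out / "04_stability_curves.csv", index=False)
    minimum = curve.minimum_valid_assessments or rules.subset_max

    alphas = person_alpha_table(enriched)
    responders = flag_careless_responders(participants, flagged, alphas, minimum, rules)
    responders.to_csv(out / "04_careless_responders.csv", index=False)
    rd = careless_responder_summary(responders)

    blob = {
        "seed": args.seed,
        "antonym_pair": list(pair),
        "antonym_full_sample_r": round(full_r, 3),
        "responses": resp,
        "injected_sensitivity": round(sensitivity, 3),
        "false_positive_rate": round(false_rate, 5),
        "minimum_valid_assessments": int(minimum),
        "stability_reached": curve.reached,
        "responders": rd,
    }
    (out / "04_careless_summary.json").write_text(json.dumps(blob, indent=2))

    print(f"antonyms: {pair[0]} vs {pair[1]} (r = {full_r:.2f})")
    print(f"careless responses: {resp['n_flagged']}/{resp['n_completed']} "
          f"({resp['share_flagged']:.2%}); sensitivity vs injected truth "
          f"{sensitivity:.0%}, false-positive rate {false_rate:.3%}")
    print(f"minimum valid assessments: {minimum} (target ICC >= {rules.icc_stability_target})")
    print(f"careless responders: {rd['n_flagged']}/{rd['n_participants']} "
          f"({rd['share_flagged']:.1%}) "
          f"[low valid {rd['n_low_valid']}, low alpha {rd['n_low_alpha']}]")


if __name__ == "__main__":
    main()
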