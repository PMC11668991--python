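#!/usr/bin/env python
"""Consolidated data-quality report for a simulated study-scale cohort.

Runs the full pipeline (simulate -> score -> compliance -> reliability ->
careless) under one seed and writes the machine-readable and human-readable
reports to results/.
"""

import argparse
from pathlib import Path

from emaqc import GeneratorConfig, PipelineConfig, render_report, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-participants", type=int, default=780)
    args = parser.parse_args()

    config = PipelineConfig(
        generator=GeneratorConfig(n_participants=args.n_participants, seed=args.seed),
        seed=args.seed,
        three_level_max_persons=200,
        out_dir=str(ROOT / "scratch" / "report"),
    )
    report = run_pipeline(config)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    text = render_report(report)
    (out / "05_quality_report.txt").write_text(text)
    import json

    (out / "05_quality_report.json").write_text(json.dumps(report, indent=2))
    print(text)


if __name__ == "__main__":
    main()
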