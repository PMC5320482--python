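"""Stage 5 — Monitoring-survey aggregation.

Aggregates the reference 85-sample market survey (positive rates per
commodity, overall rate, maximum residue) and cross-checks the aggregation
against a simulated survey with the same commodity layout.

Run:  python analysis/05_survey.py [seed]
"""

import json
import sys
from pathlib import Path

from quechemo import datasets, validation
from quechemo.synthetic import make_default_truth, simulate_survey

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    summary = validation.survey_summary(
        datasets.load_survey_records(), datasets.LOQS,
        datasets.SURVEY_COMMODITY_COUNTS)
    (OUT / "survey_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    print(f"reference survey: {summary['n_positive']} of {summary['n_samples']} "
          f"samples positive ({summary['positive_pct']}%)")
    m = summary["max_concentration"]
    print(f"highest residue: {m['analyte']} in {m['commodity']} at "
          f"{m['conc_ugkg']} ug/kg")

    truth = make_default_truth(seed)
    sim = simulate_survey(truth, datasets.SURVEY_COMMODITY_COUNTS, seed=seed)
    sim_summary = validation.survey_summary(sim, datasets.LOQS,
                                            datasets.SURVEY_COMMODITY_COUNTS)
    print(f"simulated survey (same layout, default prevalences): "
          f"{sim_summary['positive_pct']}% positive")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
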