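"""Build the ordinal-to-interval conversion table for the short form.

Fits the selected 12-item instrument on the full cohort (the larger sample
gives more precise score estimates), derives the raw-mean -> logit ->
1-5 interval-metric table (49 rows), and demonstrates the conversion on a
handful of simulated respondents.

Requires analysis/01 and 02 to have been run first.
"""

from pathlib import Path

import pandas as pd

from raschshort import io as rio, testlets as tl
from raschshort.pcm import fit_items_cml

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = rio.AnalysisConfig.from_yaml(SCRATCH / "config.yaml")
    cohort = rio.read_responses_csv(SCRATCH / "responses.csv", cfg)
    roster = sorted(pd.read_csv(RESULTS / "final_rosters.csv")["sample1"])
    short = cohort.subset_items(roster)

    items = fit_items_cml(short)
    table = tl.build_conversion_table(items)
    rio.write_conversion_csv(table, RESULTS / "conversion_table.csv")
    print(f"conversion table: {len(table.table)} rows, anchors "
          f"{table.theta_min:.2f} .. {table.theta_max:.2f} logits")
    print(table.to_csv_frame().head(6).to_string(index=False))

    raw_means = 1.0 + 4.0 * short.scores.sum(axis=1) / items.max_total
    metric = tl.apply_conversion(raw_means.iloc[:5], table)
    demo = pd.DataFrame({"raw_mean": raw_means.iloc[:5].round(2), "metric": metric.round(2)})
    print("\nexample conversions (first five respondents):")
    print(demo.to_string(index=False))


if __name__ == "__main__":
    main()
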