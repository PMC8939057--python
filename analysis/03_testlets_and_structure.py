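"""Testlet analysis and latent structure of the shortened instrument.

Takes the 12-item roster selected on subsample 1, groups its items into
the four subscale testlets, and reports (a) the testlet-level model fit,
(b) DIF for the testlets with artificial-DIF resolution when anything is
flagged, and (c) the disattenuated latent correlations between subscales
and the explained common variance.

Requires analysis/01 and 02 to have been run first.
"""

from pathlib import Path

import pandas as pd

from raschshort import diagnostics as dg, invariance as inv, io as rio, testlets as tl
from raschshort.pcm import estimate_persons, fit_items_cml

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = rio.AnalysisConfig.from_yaml(SCRATCH / "config.yaml")
    rm = rio.read_responses_csv(SCRATCH / "subsample1.csv", cfg)
    roster = sorted(pd.read_csv(RESULTS / "final_rosters.csv")["sample1"])
    short = rm.subset_items(roster)

    structure = tl.form_testlets(short)
    t_rm = structure.responses
    items = fit_items_cml(t_rm)
    persons = estimate_persons(t_rm, items)
    smith = inv.smith_unidimensionality(t_rm, items, persons)
    report = dg.summary_fit(
        "BAT12 4 testlets", t_rm, items, persons,
        unidim=(smith.pct_significant, smith.ci),
    )
    pd.DataFrame([report.summary_row()]).to_csv(
        RESULTS / "testlet_fit.csv", index=False
    )
    print("testlet-level fit:")
    for k, v in report.summary_row().items():
        print(f"  {k}: {v if isinstance(v, str) else round(v, 3)}")

    # DIF screen on the testlets, with artificial-DIF resolution
    z = dg.standardized_residuals(t_rm, items, persons)
    ci = dg.class_intervals(
        persons.persons.loc[z.index, "theta"], dg.default_class_intervals(len(z))
    )
    pf = t_rm.person_factors.copy()
    pf["age_group"] = inv.median_split(pf["age"])
    dif = inv.dif_anova(z, pf, ci, ["gender", "age_group", "country"])
    dif.table.to_csv(RESULTS / "testlet_dif.csv", index=False)
    flagged = dif.flagged()
    print(f"\ntestlet DIF flags: {len(flagged)}")
    if len(flagged):
        res = inv.resolve_artificial_dif(t_rm, items, persons, dif, person_factors=pf)
        print(f"  split {res.split_item} by {res.factor}: group locations "
              f"{ {k: round(v, 2) for k, v in res.group_locations.items()} }, "
              f"difference p={res.difference_p:.3f}")
        print(f"  artificial DIF vanished for: {res.vanished or 'none'}")

    latent = tl.latent_structure(short)
    latent.latent_correlations.round(3).to_csv(RESULTS / "latent_correlations.csv")
    print(f"\naverage latent correlation: {latent.average_latent_correlation:.2f}")
    print(f"explained common variance: {100 * latent.ecv:.0f}%")
    print(f"subscale reliabilities: "
          f"{ {k: round(v, 2) for k, v in latent.reliabilities.items()} }")


if __name__ == "__main__":
    main()
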