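#!/usr/bin/env python
"""Transect statistics on the deconvolved study.

Computes the per-row category percentages, the cross-pollen source
composition among cross-carrying bees, and the binomial GLMM of
cross-pollen carriage on row distance, orchard type and their
interaction (random transect intercept).  Writes tables and the stacked
bar figure under results/.
"""

from pathlib import Path

import pandas as pd

from pollenflow.glmm import fit_glmm
from pollenflow.stats import (
    distance_effect_report,
    plot_proportions,
    summarize_cross_sources,
    summarize_proportions,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bees = pd.read_csv(ROOT / "study" / "bees.csv",
                       dtype={"bee_id": str, "host_cultivar": str,
                              "transect_id": str, "cross_cultivars": str,
                              "confirmed": str})
    proportions = summarize_proportions(bees)
    sources = summarize_cross_sources(bees)
    fit = fit_glmm(bees)
    report = distance_effect_report(fit, alpha=0.05)

    proportions["by_row"].to_csv(ROOT / "proportions.csv", index=False)
    proportions["row_means"].to_csv(ROOT / "proportions_row_means.csv",
                                    index=False)
    sources.to_csv(ROOT / "cross_sources.csv", index=False)
    report.table.to_csv(ROOT / "glmm_fit.csv", index=False)
    plot_proportions(proportions["by_row"], ROOT / "proportions.png")

    print(proportions["by_row"].round(1).to_string(index=False))
    print()
    print(report.to_text())
    one = sources.groupby("orchard_type")["pct_one_cultivar"].mean()
    print("\n% of cross-carrying bees with a single cross cultivar:")
    print(one.round(1).to_string())
    print(f"\nwrote tables and figure under {ROOT}")


if __name__ == "__main__":
    main()
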