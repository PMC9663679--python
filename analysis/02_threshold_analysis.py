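#!/usr/bin/env python
"""Cumulative threshold sweeps and sensitivity-constrained cutoff selection.

Sweeps both scores over rule-out cutoffs 0..17, selects the largest cutoff
keeping sensitivity >= 98% for each, and tabulates the performance of the two
resulting rules (plus the aspirate-only rule) with exact 95% CIs.
"""

from pathlib import Path

import numpy as np

from nvugib.algorithm import combined_score
from nvugib.cohort import study_cohort
from nvugib.diagnostics import (
    compare_proportions,
    select_optimal_threshold,
    threshold_sweep,
)
from nvugib.reports import run_full_analysis, sweep_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = study_cohort()
    gbs = np.array([r.gbs for r in records])
    comb = np.array([combined_score(r.gbs, r.bloody).value for r in records])

    sweep_g = threshold_sweep(records, gbs)
    sweep_c = threshold_sweep(records, comb)
    sweep_frame(sweep_g).to_csv(OUT / "sweep_gbs.tsv", sep="\t", index=False)
    sweep_frame(sweep_c).to_csv(OUT / "sweep_algorithm.tsv", sep="\t",
                                index=False)

    thr_g = select_optimal_threshold(sweep_g, 98.0)
    thr_c = select_optimal_threshold(sweep_c, 98.0)
    print(f"optimal rule-out thresholds (sens >= 98%): "
          f"GBS <= {thr_g}, combined score <= {thr_c}")

    bundle = run_full_analysis(records, n_boot=500)
    bundle.performance.to_csv(OUT / "rule_performance.tsv", sep="\t",
                              index=False)
    lg = bundle.headline["low_risk_gbs_pct"]
    lc = bundle.headline["low_risk_algorithm_pct"]
    p = compare_proportions(
        int(round(lc * len(records) / 100)), len(records),
        int(round(lg * len(records) / 100)), len(records),
    )
    print(f"low-risk fraction: combined rule {lc}% vs GBS alone {lg}% "
          f"(chi-square p = {p:.2g})")
    print(f"wrote sweeps and {OUT / 'rule_performance.tsv'}")


if __name__ == "__main__":
    main()
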