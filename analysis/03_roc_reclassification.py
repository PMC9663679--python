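#!/usr/bin/env python
"""Discrimination analysis: AUCs with the DeLong comparison, then NRI/IDI.

Compares the GBS against the combined GBS+NGA score on the reconstructed
cohort: tie-corrected empirical AUCs with DeLong CIs, the paired DeLong test,
and logistic-calibrated continuous NRI and IDI with bootstrap CIs.
"""

import json
from pathlib import Path

import numpy as np

from nvugib.algorithm import combined_score
from nvugib.cohort import study_cohort
from nvugib.reclassification import bootstrap_ci, compare_scores
from nvugib.roc import delong_paired_test, empirical_auc

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240901


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = study_cohort()
    gbs = np.array([r.gbs for r in records])
    comb = np.array([combined_score(r.gbs, r.bloody).value for r in records])
    hrel = np.array([r.hrel for r in records])

    r_g = empirical_auc(gbs[hrel], gbs[~hrel])
    r_c = empirical_auc(comb[hrel], comb[~hrel])
    paired = delong_paired_test(gbs, comb, hrel)
    print(f"GBS AUC {r_g.auc:.3f} (95% CI {r_g.ci_low:.3f}-{r_g.ci_high:.3f})")
    print(f"combined AUC {r_c.auc:.3f} "
          f"(95% CI {r_c.ci_low:.3f}-{r_c.ci_high:.3f})")
    print(f"paired DeLong: z = {paired.z:.3f}, p = {paired.p_value:.2g}")

    res, cal_old, cal_new = compare_scores(gbs, comb, hrel)
    ci = bootstrap_ci(gbs, comb, hrel, n_boot=2000, seed=SEED)
    print(f"continuous NRI {res.nri_total:.3f} "
          f"(events {res.nri_events:.3f}, non-events {res.nri_nonevents:.3f})")
    print(f"IDI {res.idi:.3f}")

    payload = {
        "auc_gbs": r_g.auc, "auc_gbs_ci": [r_g.ci_low, r_g.ci_high],
        "auc_combined": r_c.auc, "auc_combined_ci": [r_c.ci_low, r_c.ci_high],
        "delong_z": paired.z, "delong_p": paired.p_value,
        "nri_events": res.nri_events, "nri_nonevents": res.nri_nonevents,
        "nri_total": res.nri_total, "idi": res.idi,
        "bootstrap_ci": {k: list(v) for k, v in ci.items()},
        "calibration_converged": cal_old.converged and cal_new.converged,
    }
    with open(OUT / "discrimination.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    print(f"wrote {OUT / 'discrimination.json'}")


if __name__ == "__main__":
    main()
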