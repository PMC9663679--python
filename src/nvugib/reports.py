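"""Full-analysis pipeline and report rendering.

:func:`run_full_analysis` chains every stage — summary, threshold sweeps for
the GBS and the combined score, sensitivity-constrained threshold selection,
ROC/AUC with the paired DeLong comparison, logistic-calibrated NRI/IDI, and
2x2 metrics for the aspirate rule and both selected rule-out rules — into one
bundle whose tables all derive from a single cohort snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import algorithm, diagnostics, reclassification, roc
from .cohort import PatientRecord, summarize_cohort

logger = logging.getLogger("nvugib")


@dataclass
class ReportBundle:
    summary: pd.DataFrame
    sweep_gbs: pd.DataFrame
    sweep_algorithm: pd.DataFrame
    performance: pd.DataFrame
    histograms: dict[str, pd.DataFrame]
    headline: dict


class StageError(RuntimeError):
    """Wraps a pipeline failure with the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


def sweep_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([{
        "cutoff": r.cutoff,
        "cum_with_hrel": r.cum_with,
        "cum_with_hrel_pct": r.cum_with_pct,
        "cum_without_hrel": r.cum_without,
        "cum_without_hrel_pct": r.cum_without_pct,
        "sensitivity_pct": r.sensitivity,
        "specificity_pct": r.specificity,
    } for r in rows])


def render_histograms(records: list[PatientRecord]) -> dict[str, pd.DataFrame]:
    """Score-distribution count matrices (rows = GBS 0..23, columns = HREL
    stratum) for all patients and the bloody / non-bloody aspirate subgroups."""
    out = {}
    for name, keep in (
        ("all", lambda r: True),
        ("bloody", lambda r: r.bloody),
        ("non_bloody", lambda r: not r.bloody),
    ):
        counts = np.zeros((24, 2), dtype=int)
        for r in records:
            if keep(r):
                counts[r.gbs, 0 if r.hrel else 1] += 1
        out[name] = pd.DataFrame(
            counts, index=pd.RangeIndex(24, name="gbs"),
            columns=["with_hrel", "without_hrel"],
        )
    return out


def _metrics_row(label: str, cutoff, low_risk_n: int, n: int, t) -> dict:
    m = diagnostics.diagnostic_metrics(t)
    row = {
        "rule": label,
        "cutoff": cutoff,
        "low_risk_n": low_risk_n,
        "low_risk_pct": diagnostics.table_round(100.0 * low_risk_n / n),
    }
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        mc = m[name]
        if mc is None:
            row[f"{name}_pct"] = row[f"{name}_ci_low"] = row[f"{name}_ci_high"] = None
        else:
            row[f"{name}_pct"] = diagnostics.table_round(mc.estimate)
            row[f"{name}_ci_low"] = diagnostics.table_round(mc.ci_low)
            row[f"{name}_ci_high"] = diagnostics.table_round(mc.ci_high)
    return row


def run_full_analysis(
    records: list[PatientRecord],
    min_sensitivity: float = 98.0,
    seed: int = 0,
    n_boot: int = 2000,
) -> ReportBundle:
    """Run the whole evaluation on one cohort; see module docstring."""
    if not records:
        raise StageError("cohort_data", ValueError("empty cohort"))
    if any(r.gbs is None for r in records):
        raise StageError("cohort_data", ValueError("records must carry gbs"))
    n = len(records)
    logger.info("cohort: %d records, %d with HREL",
                n, sum(r.hrel for r in records))

    gbs_scores = np.array([r.gbs for r in records])
    comb_scores = np.array([
        algorithm.combined_score(r.gbs, r.bloody).value for r in records
    ])
    hrel = np.array([r.hrel for r in records])

    try:
        summary = summarize_cohort(records)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("summarize", exc) from exc

    sweep_g = diagnostics.threshold_sweep(records, gbs_scores)
    sweep_a = diagnostics.threshold_sweep(records, comb_scores)
    logger.info("threshold sweeps: %d cutoffs", len(sweep_g))

    thr_g = diagnostics.select_optimal_threshold(sweep_g, min_sensitivity)
    thr_a = diagnostics.select_optimal_threshold(sweep_a, min_sensitivity)
    logger.info("selected thresholds: GBS <=%d, algorithm <=%d", thr_g, thr_a)

    roc_g = roc.empirical_auc(gbs_scores[hrel], gbs_scores[~hrel])
    roc_a = roc.empirical_auc(comb_scores[hrel], comb_scores[~hrel])
    paired = roc.delong_paired_test(gbs_scores, comb_scores, hrel)
    logger.info("AUCs: GBS %.3f, algorithm %.3f, DeLong p %.2g",
                roc_g.auc, roc_a.auc, paired.p_value)

    reclass, cal_old, cal_new = reclassification.compare_scores(
        gbs_scores, comb_scores, hrel
    )
    reclass_ci = reclassification.bootstrap_ci(
        gbs_scores, comb_scores, hrel, n_boot=n_boot, seed=seed
    )

    strat_g = algorithm.stratify_cohort(records, thr_g, gbs_only=True)
    strat_a = algorithm.stratify_cohort(records, thr_a)
    p_low_risk = diagnostics.compare_proportions(
        strat_a["low_risk_n"], n, strat_g["low_risk_n"], n, method="chi_square"
    )

    performance = pd.DataFrame([
        _metrics_row(
            "gbs", thr_g, strat_g["low_risk_n"], n,
            diagnostics.two_by_two(records, lambda r: r.gbs > thr_g),
        ),
        _metrics_row(
            "algorithm", thr_a, strat_a["low_risk_n"], n,
            diagnostics.two_by_two(
                records, lambda r: r.bloody or r.gbs > thr_a
            ),
        ),
        _metrics_row(
            "bloody_nga", None,
            sum(1 for r in records if not r.bloody), n,
            diagnostics.two_by_two(records, lambda r: r.bloody),
        ),
    ])

    headline = {
        "n": n,
        "n_with_hrel": int(hrel.sum()),
        "auc_gbs": roc_g.auc,
        "auc_gbs_ci": (roc_g.ci_low, roc_g.ci_high),
        "auc_algorithm": roc_a.auc,
        "auc_algorithm_ci": (roc_a.ci_low, roc_a.ci_high),
        "delong_z": paired.z,
        "delong_p": paired.p_value,
        "threshold_gbs": thr_g,
        "threshold_algorithm": thr_a,
        "low_risk_gbs_pct": diagnostics.table_round(strat_g["low_risk_pct"]),
        "low_risk_algorithm_pct": diagnostics.table_round(strat_a["low_risk_pct"]),
        "low_risk_comparison_p": p_low_risk,
        "nri_events": reclass.nri_events,
        "nri_nonevents": reclass.nri_nonevents,
        "nri_total": reclass.nri_total,
        "idi": reclass.idi,
        "nri_idi_ci": reclass_ci,
        "calibration_converged": (
            cal_old is None or (cal_old.converged and cal_new.converged)
        ),
    }

    return ReportBundle(
        summary=summary,
        sweep_gbs=sweep_frame(sweep_g),
        sweep_algorithm=sweep_frame(sweep_a),
        performance=performance,
        histograms=render_histograms(records),
        headline=headline,
    )
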