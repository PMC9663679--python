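"""Empirical ROC/AUC with midrank tie handling and the DeLong machinery.

The AUC is the Mann-Whitney estimator
``[#(case > control) + 0.5 · #(case = control)] / (n_case · n_control)``;
with heavily tied integer scores the 0.5 tie weight is essential.  Variances
come from DeLong's placement values: the placement of a case is the fraction
of controls it beats (ties half), and vice versa.  Placements are computed
from midranks in O(N log N), which equals the explicit pairwise double loop.

The paired test compares two scores measured on the same patients: the
variance of the AUC difference subtracts twice the placement covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class RocResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    case_placements: np.ndarray
    control_placements: np.ndarray


@dataclass(frozen=True)
class PairedAucTest:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks (Sun & Xu style).

    Case i's placement = (midrank in pooled sample − midrank among cases) / m;
    control j's placement = 1 − (pooled midrank − within-group midrank) / n.
    """
    n, m = len(cases), len(controls)
    pooled = rankdata(np.concatenate([cases, controls]))
    v10 = (pooled[:n] - rankdata(cases)) / m
    v01 = 1.0 - (pooled[n:] - rankdata(controls)) / n
    return v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    n, m = len(v10), len(v01)
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    return float(s10 / n + s01 / m)


def empirical_auc(case_scores, control_scores, alpha: float = 0.05) -> RocResult:
    """Tie-corrected empirical AUC with DeLong variance and normal CI.

    Higher score = more likely a case; no automatic direction flipping.
    The CI is truncated to [0, 1].
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())
    var = _delong_variance(v10, v01)
    zq = norm.ppf(1.0 - alpha / 2.0)
    half = zq * np.sqrt(var)
    return RocResult(
        auc=auc,
        variance=var,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        case_placements=v10,
        control_placements=v01,
    )


def delong_paired_test(scores_a, scores_b, outcome) -> PairedAucTest:
    """DeLong test for two correlated ROC curves on the same patients.

    ``scores_a``/``scores_b`` are aligned per-patient; ``outcome`` is the
    boolean case label.  Identical scores (zero variance of the difference)
    return z = 0, p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores and outcome must be aligned")
    if y.all() or not y.any():
        raise ValueError("both outcome strata must be non-empty")

    v10a, v01a = _placements(a[y], a[~y])
    v10b, v01b = _placements(b[y], b[~y])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n, m = int(y.sum()), int((~y).sum())

    def var_diff(pa: np.ndarray, pb: np.ndarray, size: int) -> float:
        if size < 2:
            return 0.0
        cov = np.cov(np.vstack([pa, pb]), ddof=1)
        return float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]) / size

    var = var_diff(v10a, v10b, n) + var_diff(v01a, v01b, m)
    diff = auc_b - auc_a
    if var <= 0.0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return PairedAucTest(auc_a, auc_b, diff, var, float(z), p)


def roc_points(case_scores, control_scores) -> np.ndarray:
    """Empirical ROC curve as (fpr, tpr) rows over all observed cutoffs."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    thresholds = np.unique(np.concatenate([cases, controls]))
    pts = [(1.0, 1.0)]
    for t in thresholds:
        pts.append((float((controls > t).mean()), float((cases > t).mean())))
    return np.array(sorted(set(pts)))
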