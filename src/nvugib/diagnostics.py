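"""Diagnostic-accuracy machinery.

2x2 metrics with Clopper-Pearson exact 95% CIs, cumulative threshold sweeps,
rule-out threshold selection under a sensitivity floor, and the two-group
comparison tests used for the baseline table (pooled-variance t-test,
chi-square without continuity correction, Fisher's exact test).

Conventions: the condition is "high-risk endoscopic lesion present"; the
positive test is "predicted high-risk" (score above the cutoff, or bloody
aspirate for the aspirate-only rule).  Report percentages are rounded to one
decimal with ties to even (the R convention; exact ties such as 33/80 =
41.25% do occur in cumulative tables and round to 41.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import PatientRecord


def table_round(x: float, ndigits: int = 1) -> float:
    """One-decimal table rounding, ties to even."""
    return round(x, ndigits)


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion counts; condition = HREL present, positive = predicted high-risk."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def n_with(self) -> int:
        return self.tp + self.fn

    @property
    def n_without(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricWithCi:
    """A proportion in percent with its exact (Clopper-Pearson) 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


def two_by_two(
    records: Sequence[PatientRecord],
    rule: Callable[[PatientRecord], bool],
) -> TwoByTwo:
    """Cross-tabulate a high-risk predicate against HREL status."""
    tp = fp = fn = tn = 0
    for r in records:
        positive = rule(r)
        if r.hrel:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return TwoByTwo(tp, fp, fn, tn)


def proportion_ci(successes: int, n: int, alpha: float = 0.05) -> MetricWithCi:
    """Clopper-Pearson exact binomial CI, on the percent scale."""
    if n == 0:
        raise ValueError("undefined proportion: zero denominator")
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="beta")
    return MetricWithCi(100.0 * successes / n, 100.0 * lo, 100.0 * hi,
                        successes, n)


def diagnostic_metrics(t: TwoByTwo) -> dict[str, MetricWithCi | None]:
    """Sensitivity, specificity, PPV and NPV with exact 95% CIs.

    A metric whose denominator is zero is reported as None (undefined).
    """
    if t.tp + t.fp + t.fn + t.tn == 0:
        raise ValueError("all-zero 2x2 table")

    def metric(num: int, den: int) -> MetricWithCi | None:
        return proportion_ci(num, den) if den > 0 else None

    return {
        "sensitivity": metric(t.tp, t.tp + t.fn),
        "specificity": metric(t.tn, t.fp + t.tn),
        "ppv": metric(t.tp, t.tp + t.fp),
        "npv": metric(t.tn, t.tn + t.fn),
    }


@dataclass(frozen=True)
class ThresholdSweepRow:
    """One cumulative rule-out row: patients at or below the cutoff.

    ``cum_*_pct`` are out of the whole cohort; sensitivity/specificity follow
    from the stratum totals: sens = 100·(n_with − cum_with)/n_with,
    spec = 100·cum_without/n_without.  Percentages rounded to 1 d.p., ties to
    even.
    """

    cutoff: int
    cum_with: int
    cum_with_pct: float
    cum_without: int
    cum_without_pct: float
    sensitivity: float
    specificity: float


def threshold_sweep(
    records: Sequence[PatientRecord],
    scores: Sequence[int],
    cutoffs: Iterable[int] = range(18),
) -> list[ThresholdSweepRow]:
    """Cumulative sensitivity/specificity of the rule "score <= cutoff rules out"."""
    scores = np.asarray(scores)
    hrel = np.array([r.hrel for r in records])
    if scores.min() < 0 or scores.max() > 23:
        raise ValueError("scores must lie in [0, 23]")
    n = len(records)
    n_with = int(hrel.sum())
    n_without = n - n_with
    rows = []
    for k in cutoffs:
        cw = int(((scores <= k) & hrel).sum())
        cwo = int(((scores <= k) & ~hrel).sum())
        rows.append(ThresholdSweepRow(
            cutoff=int(k),
            cum_with=cw,
            cum_with_pct=table_round(100.0 * cw / n),
            cum_without=cwo,
            cum_without_pct=table_round(100.0 * cwo / n),
            sensitivity=table_round(100.0 * (n_with - cw) / n_with),
            specificity=table_round(100.0 * cwo / n_without),
        ))
    return rows


def select_optimal_threshold(
    sweep: Sequence[ThresholdSweepRow],
    min_sensitivity: float = 98.0,
) -> int:
    """Largest rule-out cutoff keeping sensitivity at or above the floor.

    Sensitivity emphasised because raising the cutoff further would start
    misclassifying patients who need endoscopic treatment.
    """
    if not sweep:
        raise ValueError("empty sweep")
    eligible = [row.cutoff for row in sweep if row.sensitivity >= min_sensitivity]
    if not eligible:
        raise ValueError(
            f"no cutoff reaches sensitivity >= {min_sensitivity}%"
        )
    return max(eligible)


def compare_proportions(
    x1: int, n1: int, x2: int, n2: int, method: str = "chi_square"
) -> float:
    """Two-sided p for H0: equal proportions (chi-square, no continuity
    correction, or Fisher's exact)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("zero group size")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must satisfy 0 <= x <= n")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    if method == "chi_square":
        return float(stats.chi2_contingency(table, correction=False)[1])
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")


def compare_means(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided pooled-variance (Student) two-sample t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("degenerate: zero variance in both groups")
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
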