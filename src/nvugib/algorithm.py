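"""Combined GBS + nasogastric-aspirate score and the two-way triage rule.

The combined score adds 23 points to the GBS when the nasogastric aspirate
(NGA) is bloody and caps the total at 23, so a bloody aspirate always yields
the maximal score.  The triage rule calls a patient low-risk (no emergent
endoscopy) exactly when the aspirate is non-bloody AND the GBS is at or below
a chosen threshold; everyone else is high-risk.  For thresholds below 23 the
rule is equivalent to "combined score <= threshold".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import GBS_MAX, GBS_MIN, PatientRecord

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"


@dataclass(frozen=True)
class CombinedScore:
    value: int
    source_gbs: int
    bloody: bool


@dataclass(frozen=True)
class RiskClass:
    value: str  # LOW_RISK or HIGH_RISK
    threshold: int


def _check_range(name: str, v: int, lo: int = GBS_MIN, hi: int = GBS_MAX) -> None:
    if not lo <= v <= hi:
        raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def combined_score(gbs: int, bloody: bool) -> CombinedScore:
    """min(gbs + 23·[bloody], 23): bloody aspirate saturates the score."""
    _check_range("gbs", gbs)
    return CombinedScore(
        value=min(gbs + GBS_MAX * int(bloody), GBS_MAX),
        source_gbs=gbs,
        bloody=bloody,
    )


def classify_patient(gbs: int, bloody: bool, threshold: int) -> RiskClass:
    """Low-risk iff non-bloody NGA and GBS <= threshold (inclusive cutoffs).

    Threshold 23 is rejected: it would label bloody patients low-risk, which
    the score cap exists to prevent.
    """
    _check_range("gbs", gbs)
    _check_range("threshold", threshold, GBS_MIN, GBS_MAX - 1)
    low = (not bloody) and gbs <= threshold
    return RiskClass(LOW_RISK if low else HIGH_RISK, threshold)


def stratify_cohort(
    records: Sequence[PatientRecord],
    threshold: int,
    gbs_only: bool = False,
) -> dict:
    """Low/high-risk counts and percentages at a threshold.

    With ``gbs_only`` the aspirate is ignored (rule: GBS <= threshold), which
    is the plain score-based rule the combined algorithm is compared against.
    """
    n = len(records)
    low = sum(
        1 for r in records
        if classify_patient(r.gbs, False if gbs_only else r.bloody,
                            threshold).value == LOW_RISK
    )
    high = n - low
    return {
        "n": n,
        "low_risk_n": low,
        "low_risk_pct": 100.0 * low / n if n else 0.0,
        "high_risk_n": high,
        "high_risk_pct": 100.0 * high / n if n else 0.0,
        "threshold": threshold,
    }
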