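"""Continuous net reclassification improvement (NRI) and integrated
discrimination improvement (IDI).

Both compare a new risk model against an old one on the same patients.
Continuous NRI counts directions of movement: among events, the proportion
whose predicted risk rises minus the proportion whose risk falls (ties count
zero); among non-events the signs reverse; the total is the sum of the two
components and lies in [-2, 2].  IDI is the change in the discrimination
slope: (mean risk in events − mean risk in non-events), new minus old.

Integer scores are mapped to predicted risks by a univariate logistic
calibration (:func:`calibrate_risk`); a raw-score mode that feeds the scores
straight into the NRI/IDI formulas is available for score-level analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata


@dataclass(frozen=True)
class CalibrationResult:
    probabilities: np.ndarray
    converged: bool  #: False when separation forced the rank fallback
    intercept: float | None
    slope: float | None


@dataclass(frozen=True)
class ReclassResult:
    nri_events: float
    nri_nonevents: float
    nri_total: float
    idi: float
    mean_old_events: float
    mean_old_nonevents: float
    mean_new_events: float
    mean_new_nonevents: float


def _check_strata(outcome: np.ndarray) -> None:
    if outcome.all() or not outcome.any():
        raise ValueError("both outcome strata must be non-empty")


def calibrate_risk(scores, outcome) -> CalibrationResult:
    """Univariate logistic fit of outcome on score; returns fitted risks.

    Perfect separation (the fit diverges) is flagged and the probabilities
    fall back to score midranks rescaled to (0, 1), which preserves the score
    ordering — all NRI/IDI quantities then reduce to rank statements.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    _check_strata(y)
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y.astype(float), exog).fit(disp=0, maxiter=100)
        params = fit.params
        if not fit.mle_retvals.get("converged", False) or np.abs(params).max() > 1e3:
            raise sm.tools.sm_exceptions.PerfectSeparationError("diverged")
        return CalibrationResult(
            probabilities=np.asarray(fit.predict(exog)),
            converged=True,
            intercept=float(params[0]),
            slope=float(params[1]),
        )
    except Exception:
        probs = rankdata(x) / (len(x) + 1.0)
        return CalibrationResult(probs, converged=False, intercept=None, slope=None)


def reclassification_metrics(p_old, p_new, outcome) -> ReclassResult:
    """Continuous NRI components and IDI for aligned per-patient risks."""
    old = np.asarray(p_old, dtype=float)
    new = np.asarray(p_new, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("risk vectors and outcome must be aligned")
    _check_strata(y)

    up = new > old
    down = new < old
    nri_events = float(up[y].mean() - down[y].mean())
    nri_nonevents = float(down[~y].mean() - up[~y].mean())

    mo_e, mo_ne = float(old[y].mean()), float(old[~y].mean())
    mn_e, mn_ne = float(new[y].mean()), float(new[~y].mean())
    return ReclassResult(
        nri_events=nri_events,
        nri_nonevents=nri_nonevents,
        nri_total=nri_events + nri_nonevents,
        idi=(mn_e - mn_ne) - (mo_e - mo_ne),
        mean_old_events=mo_e,
        mean_old_nonevents=mo_ne,
        mean_new_events=mn_e,
        mean_new_nonevents=mn_ne,
    )


def continuous_nri(p_old, p_new, outcome) -> ReclassResult:
    return reclassification_metrics(p_old, p_new, outcome)


def idi(p_old, p_new, outcome) -> float:
    return reclassification_metrics(p_old, p_new, outcome).idi


def compare_scores(
    scores_old, scores_new, outcome,
    raw_scores: bool = False,
) -> tuple[ReclassResult, CalibrationResult | None, CalibrationResult | None]:
    """NRI/IDI between two integer scores on the same cohort.

    Default path calibrates each score to risks by univariate logistic
    regression; ``raw_scores=True`` uses the scores themselves (directions of
    movement are then score comparisons, and IDI is on the score scale).
    """
    if raw_scores:
        return (
            reclassification_metrics(scores_old, scores_new, outcome),
            None, None,
        )
    cal_old = calibrate_risk(scores_old, outcome)
    cal_new = calibrate_risk(scores_new, outcome)
    res = reclassification_metrics(
        cal_old.probabilities, cal_new.probabilities, outcome
    )
    return res, cal_old, cal_new


def bootstrap_ci(
    scores_old, scores_new, outcome,
    n_boot: int = 2000,
    seed: int = 0,
    raw_scores: bool = False,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Seeded percentile bootstrap CIs for NRI components and IDI,
    stratified on the outcome so both strata persist in every resample."""
    old = np.asarray(scores_old, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    rng = np.random.default_rng(seed)
    ev = np.flatnonzero(y)
    ne = np.flatnonzero(~y)
    stats = {"nri_events": [], "nri_nonevents": [], "nri_total": [], "idi": []}
    for _ in range(n_boot):
        idx = np.concatenate([
            rng.choice(ev, size=len(ev), replace=True),
            rng.choice(ne, size=len(ne), replace=True),
        ])
        res, _, _ = compare_scores(old[idx], new[idx], y[idx], raw_scores=raw_scores)
        for k in stats:
            stats[k].append(getattr(res, k))
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {k: tuple(np.percentile(v, [lo, hi])) for k, v in stats.items()}
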