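"""Synthetic emergency-department cohorts with the study's statistical structure.

A patient is generated hierarchically: HREL status ~ Bernoulli(prevalence);
bloody aspirate ~ Bernoulli(conditional on stratum); GBS from a per-stratum
distribution on 0..23 (discretized truncated normal by default, or empirical
per-score weights, optionally per (stratum, bloody) cell); then raw clinical
variables are inverse-generated to realise exactly that GBS, by sampling a
uniform decomposition of the target into component points and drawing each raw
value uniformly inside the chosen band.  Open-ended bands use bounded
physiologic surrogate ranges (e.g. BUN >= 25 mmol/L is drawn in [25, 60]).

Defaults are the study conditions: HREL prevalence 30.4%, P(bloody | HREL)
0.686, P(bloody | no HREL) 0.138, stratum GBS means/SDs 11.3/3.7 and 9.4/4.2.
Non-score covariates (age, sex, hematemesis, non-bloody aspirate category) are
drawn independently at the study marginals purely for CSV realism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cohort import NON_BLOODY, PatientRecord
from .gbs import GbsInputs, compute_gbs

# Sampling bands per component-point value: (low, high) inclusive ranges in
# which the raw value is drawn uniformly; every value in a band scores exactly
# that band's points.
BUN_BANDS = {0: (2.0, 6.4), 2: (6.5, 7.9), 3: (8.0, 9.9), 4: (10.0, 24.9),
             6: (25.0, 60.0)}
HB_BANDS = {
    "male": {0: (130.0, 170.0), 1: (120.0, 129.0), 3: (100.0, 119.0),
             6: (40.0, 99.0)},
    "female": {0: (120.0, 160.0), 1: (100.0, 119.0), 6: (40.0, 99.0)},
}
SBP_BANDS = {0: (110.0, 180.0), 1: (100.0, 109.0), 2: (90.0, 99.0),
             3: (60.0, 89.0)}
PULSE_BANDS = {0: (50.0, 99.0), 1: (100.0, 160.0)}
FLAG_POINTS = {"melena": 1, "syncope": 2, "hepatic_disease": 2,
               "cardiac_failure": 2}


@lru_cache(maxsize=None)
def decompositions(target: int, sex: str) -> tuple[tuple[int, ...], ...]:
    """All component-point tuples (bun, hb, sbp, pulse, melena, syncope,
    hepatic, cardiac) summing to ``target`` for the given sex."""
    out = []
    for combo in itertools.product(
        BUN_BANDS, HB_BANDS[sex], SBP_BANDS, PULSE_BANDS,
        (0, 1), (0, 2), (0, 2), (0, 2),
    ):
        if sum(combo) == target:
            out.append(combo)
    return tuple(out)


def feasible_targets(sex: str) -> list[int]:
    return [g for g in range(24) if decompositions(g, sex)]


def inverse_generate_raws(
    target_gbs: int, sex: str, rng: np.random.Generator
) -> GbsInputs:
    """Raw clinical variables whose GBS is exactly ``target_gbs``.

    Samples one decomposition of the target into component points uniformly
    over the exhaustive enumeration, then draws each raw value uniformly in
    the band that scores those points.
    """
    options = decompositions(target_gbs, sex)
    if not options:
        raise ValueError(f"no decomposition of GBS {target_gbs} for sex {sex!r}")
    bun_p, hb_p, sbp_p, pulse_p, mel_p, syn_p, hep_p, card_p = (
        options[rng.integers(len(options))]
    )

    def draw(band: tuple[float, float]) -> float:
        return float(rng.uniform(band[0], band[1]))

    return GbsInputs(
        bun=draw(BUN_BANDS[bun_p]),
        hemoglobin=draw(HB_BANDS[sex][hb_p]),
        sex=sex,
        sbp=draw(SBP_BANDS[sbp_p]),
        pulse=draw(PULSE_BANDS[pulse_p]),
        melena=bool(mel_p),
        syncope=bool(syn_p),
        hepatic_disease=bool(hep_p),
        cardiac_failure=bool(card_p),
    )


# ---------------------------------------------------------------------------
# GBS distributions

@dataclass(frozen=True)
class DiscretizedNormal:
    """Per-stratum normal, discretized to integers and truncated to 0..23."""

    mean_hrel: float = 11.3
    sd_hrel: float = 3.7
    mean_no_hrel: float = 9.4
    sd_no_hrel: float = 4.2

    def weights(self, hrel: bool, bloody: bool) -> np.ndarray:
        mu, sd = ((self.mean_hrel, self.sd_hrel) if hrel
                  else (self.mean_no_hrel, self.sd_no_hrel))
        edges = np.arange(25) - 0.5
        probs = np.diff(norm.cdf(edges, loc=mu, scale=sd))
        return probs / probs.sum()


@dataclass(frozen=True)
class EmpiricalWeights:
    """Per-score weights by HREL stratum, optionally refined by bloody status.

    ``with_hrel``/``without_hrel`` are length-24 weight vectors.  When the
    bloody-specific vectors are given they override the stratum vectors,
    reproducing the full (GBS, bloody) joint within each stratum.
    """

    with_hrel: tuple[float, ...]
    without_hrel: tuple[float, ...]
    with_hrel_bloody: tuple[float, ...] | None = None
    with_hrel_non_bloody: tuple[float, ...] | None = None
    without_hrel_bloody: tuple[float, ...] | None = None
    without_hrel_non_bloody: tuple[float, ...] | None = None

    def weights(self, hrel: bool, bloody: bool) -> np.ndarray:
        specific = {
            (True, True): self.with_hrel_bloody,
            (True, False): self.with_hrel_non_bloody,
            (False, True): self.without_hrel_bloody,
            (False, False): self.without_hrel_non_bloody,
        }[(hrel, bloody)]
        w = np.asarray(
            specific if specific is not None
            else (self.with_hrel if hrel else self.without_hrel),
            dtype=float,
        )
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("weights must be non-negative and normalizable")
        return w / w.sum()


def empirical_weights_from_cohort(
    records: Sequence[PatientRecord], by_bloody: bool = False
) -> EmpiricalWeights:
    """Per-score weight vectors tallied from an existing cohort."""

    def tally(hrel: bool, bloody: bool | None) -> tuple[float, ...]:
        w = np.zeros(24)
        for r in records:
            if r.hrel == hrel and (bloody is None or r.bloody == bloody):
                w[r.gbs] += 1
        return tuple(w)

    kwargs = {}
    if by_bloody:
        kwargs = {
            "with_hrel_bloody": tally(True, True),
            "with_hrel_non_bloody": tally(True, False),
            "without_hrel_bloody": tally(False, True),
            "without_hrel_non_bloody": tally(False, False),
        }
    return EmpiricalWeights(tally(True, None), tally(False, None), **kwargs)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the study conditions."""

    n_patients: int = 115
    prevalence_hrel: float = 0.304
    p_bloody_given_hrel: float = 0.686
    p_bloody_given_no_hrel: float = 0.138
    gbs_distribution: DiscretizedNormal | EmpiricalWeights = field(
        default_factory=DiscretizedNormal
    )
    seed: int = 0
    male_fraction: float = 0.635
    #: relative frequencies of coffee_ground / bile_like / clear aspirates
    non_bloody_split: tuple[float, float, float] = (52.0, 6.0, 22.0)
    age_mean: float = 74.8
    age_sd: float = 18.3

    def __post_init__(self) -> None:
        for name in ("prevalence_hrel", "p_bloody_given_hrel",
                     "p_bloody_given_no_hrel", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


def generate_cohort(config: SynthConfig) -> list[PatientRecord]:
    """Generate one cohort; identical configs (incl. seed) give identical output."""
    rng = np.random.default_rng(config.seed)
    split = np.asarray(config.non_bloody_split, dtype=float)
    split = split / split.sum()
    feasible_by_sex = {
        s: np.array([len(decompositions(g, s)) > 0 for g in range(24)])
        for s in ("male", "female")
    }

    records = []
    for i in range(config.n_patients):
        hrel = bool(rng.random() < config.prevalence_hrel)
        p_bloody = (config.p_bloody_given_hrel if hrel
                    else config.p_bloody_given_no_hrel)
        bloody = bool(rng.random() < p_bloody)
        weights = config.gbs_distribution.weights(hrel, bloody)
        sex = "male" if rng.random() < config.male_fraction else "female"
        w = weights * feasible_by_sex[sex]
        if w.sum() <= 0:
            raise ValueError("GBS distribution has no feasible support for "
                             f"sex {sex!r}")
        gbs = int(rng.choice(24, p=w / w.sum()))
        raws = inverse_generate_raws(gbs, sex, rng)
        nga = "bloody" if bloody else NON_BLOODY[int(rng.choice(3, p=split))]
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 100))
        records.append(PatientRecord(
            id=f"S{i + 1:06d}",
            nga=nga,
            hrel=hrel,
            gbs=gbs,
            age=round(age, 1),
            sex=sex,
            hematemesis=bool(rng.random() < 0.574),
            melena=raws.melena,
            syncope=raws.syncope,
            sbp=round(raws.sbp, 1),
            pulse=round(raws.pulse, 1),
            hemoglobin_g_dl=round(raws.hemoglobin / 10.0, 2),
            bun_value=round(raws.bun, 2),
            bun_unit="mmol_l",
            hepatic_disease=raws.hepatic_disease,
            cardiac_failure=raws.cardiac_failure,
        ))
    return records


def config_from_dict(d: dict) -> SynthConfig:
    """Build a config from a plain (YAML-loaded) mapping."""
    d = dict(d)
    dist = d.pop("gbs_distribution", None)
    if dist is not None:
        kind = dist.pop("kind", "discretized_normal")
        if kind == "discretized_normal":
            d["gbs_distribution"] = DiscretizedNormal(**dist)
        elif kind == "empirical":
            d["gbs_distribution"] = EmpiricalWeights(
                **{k: tuple(v) for k, v in dist.items()}
            )
        else:
            raise ValueError(f"unknown gbs_distribution kind {kind!r}")
    if "non_bloody_split" in d:
        d["non_bloody_split"] = tuple(d["non_bloody_split"])
    return SynthConfig(**d)
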