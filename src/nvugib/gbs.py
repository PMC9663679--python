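"""Glasgow-Blatchford score (GBS) from raw clinical variables.

The GBS is an integer 0-23 admission risk score for upper-GI bleeding built
from blood urea nitrogen (BUN), hemoglobin (sex-specific bands), systolic
blood pressure, pulse, melena, syncope, hepatic disease and cardiac failure.
Bands are closed on their printed endpoints (e.g. 6.5 <= BUN < 8.0 scores 2).

Internal units: BUN in mmol/L (urea nitrogen; convert from mg/dL with
:func:`convert_bun`), hemoglobin in g/L, systolic pressure in mmHg, pulse in
beats/min.
"""

from __future__ import annotations

from dataclasses import dataclass

#: mg/dL -> mmol/L for urea *nitrogen* (atomic weight of N2 in urea: 28 g/mol).
BUN_MG_DL_PER_MMOL_L = 2.8

SEXES = ("male", "female")


class GbsInputError(ValueError):
    pass


@dataclass(frozen=True)
class GbsInputs:
    """Raw clinical variables entering the score (units as module docstring)."""

    bun: float
    hemoglobin: float
    sex: str
    sbp: float
    pulse: float
    melena: bool
    syncope: bool
    hepatic_disease: bool
    cardiac_failure: bool

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise GbsInputError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in ("bun", "hemoglobin", "sbp", "pulse"):
            if not getattr(self, name) > 0:
                raise GbsInputError(f"{name} must be positive")


@dataclass(frozen=True)
class GbsBreakdown:
    """Per-component points and their total (0-23)."""

    bun: int
    hemoglobin: int
    sbp: int
    pulse: int
    melena: int
    syncope: int
    hepatic: int
    cardiac: int

    @property
    def total(self) -> int:
        return (self.bun + self.hemoglobin + self.sbp + self.pulse
                + self.melena + self.syncope + self.hepatic + self.cardiac)


def convert_bun(value: float, unit: str) -> float:
    """Express a urea-nitrogen measurement in mmol/L.

    ``unit`` is "mg_dl" (divide by 2.8) or "mmol_l" (identity).
    """
    if not value > 0:
        raise GbsInputError("BUN must be positive")
    if unit == "mmol_l":
        return float(value)
    if unit == "mg_dl":
        return float(value) / BUN_MG_DL_PER_MMOL_L
    raise GbsInputError(f"unknown BUN unit {unit!r} (use 'mg_dl' or 'mmol_l')")


def bun_points(bun: float) -> int:
    if bun >= 25.0:
        return 6
    if bun >= 10.0:
        return 4
    if bun >= 8.0:
        return 3
    if bun >= 6.5:
        return 2
    return 0


def hemoglobin_points(hemoglobin: float, sex: str) -> int:
    """Hemoglobin band points; hemoglobin in g/L, bands are sex-specific."""
    if sex == "male":
        if hemoglobin >= 130.0:
            return 0
        if hemoglobin >= 120.0:
            return 1
        if hemoglobin >= 100.0:
            return 3
        return 6
    if hemoglobin >= 120.0:
        return 0
    if hemoglobin >= 100.0:
        return 1
    return 6


def sbp_points(sbp: float) -> int:
    if sbp >= 110.0:
        return 0
    if sbp >= 100.0:
        return 1
    if sbp >= 90.0:
        return 2
    return 3


def compute_gbs(inputs: GbsInputs) -> GbsBreakdown:
    """Score one patient; returns the per-component breakdown (total 0-23)."""
    return GbsBreakdown(
        bun=bun_points(inputs.bun),
        hemoglobin=hemoglobin_points(inputs.hemoglobin, inputs.sex),
        sbp=sbp_points(inputs.sbp),
        pulse=1 if inputs.pulse >= 100.0 else 0,
        melena=1 if inputs.melena else 0,
        syncope=2 if inputs.syncope else 0,
        hepatic=2 if inputs.hepatic_disease else 0,
        cardiac=2 if inputs.cardiac_failure else 0,
    )


def gbs_from_record(record) -> GbsBreakdown:
    """Score a :class:`~nvugib.cohort.PatientRecord` carrying raw variables."""
    inputs = GbsInputs(
        bun=convert_bun(record.bun_value, record.bun_unit),
        hemoglobin=record.hemoglobin_g_dl * 10.0,  # g/dL -> g/L
        sex=record.sex,
        sbp=record.sbp,
        pulse=record.pulse,
        melena=bool(record.melena),
        syncope=bool(record.syncope),
        hepatic_disease=bool(record.hepatic_disease),
        cardiac_failure=bool(record.cardiac_failure),
    )
    return compute_gbs(inputs)
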