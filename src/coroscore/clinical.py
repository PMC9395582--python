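"""Clinical records, T2DM study eligibility and UKPDS risk-tier assignment.

The cohort design contrasts a non-diabetic, non-CHD control group with
type 2 diabetes patients split into three 10-year fatal-CHD risk tiers
(low <7.5%, moderate 7.5–15%, high >15%) as predicted by the UKPDS risk
engine. The engine itself is an external calculator; its output percentage
is a required input here, with :func:`stratify_risk` exposing a hook for
any user-supplied risk function.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Optional

__all__ = [
    "ClinicalRecord",
    "RiskTier",
    "RiskTierBounds",
    "meets_t2dm_criteria",
    "count_risk_factors",
    "is_eligible_dm",
    "stratify_risk",
    "InsufficientData",
]


class RiskTier(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class InsufficientData(ValueError):
    """Raised when no diagnostic lab or treatment flag is available."""


@dataclass(frozen=True)
class RiskTierBounds:
    """Tier cut points on the 10-year fatal-CHD risk percent.

    Both bounds belong to the moderate tier: low is risk < lower,
    moderate is lower ≤ risk ≤ upper, high is risk > upper.
    """

    lower: float = 7.5
    upper: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.lower <= self.upper <= 100:
            raise ValueError("require 0 < lower <= upper <= 100")


DEFAULT_TIER_BOUNDS = RiskTierBounds()


@dataclass(frozen=True)
class ClinicalRecord:
    """Covariates, diabetes labs/treatment and precomputed UKPDS risk.

    Optional fields default to ``None`` (missing). Units: age and
    dm_duration in years; pressures in mmHg; lipids, FBG and
    post-challenge glucose in mmol/L; HbA1c in percent; BMI in kg/m²;
    ukpds_fatal_risk_pct in percent.
    """

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    dm_status: bool = False
    dm_duration: Optional[float] = None
    hba1c: Optional[float] = None
    fbg: Optional[float] = None
    post_challenge_glucose: Optional[float] = None
    on_hypoglycemic_treatment: bool = False
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    on_antihypertensive: bool = False
    total_cholesterol: Optional[float] = None
    hdl: Optional[float] = None
    triglycerides: Optional[float] = None
    on_lipid_lowering: bool = False
    current_smoker: bool = False
    bmi: Optional[float] = None
    regular_exercise: bool = True
    family_history_mi: bool = False
    prior_chd_or_symptoms: bool = False
    abnormal_ecg: bool = False
    prior_mi_cabg_stent: bool = False
    ukpds_fatal_risk_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "age", "dm_duration", "hba1c", "fbg", "post_challenge_glucose",
            "sbp", "dbp", "total_cholesterol", "hdl", "triglycerides", "bmi",
        ):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("hba1c", "ukpds_fatal_risk_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percent in [0, 100], got {v}")


def meets_t2dm_criteria(r: ClinicalRecord) -> bool:
    """ADA-style diagnostic rule.

    HbA1c ≥ 6.5%, FBG ≥ 7.0 mmol/L, post-challenge glucose ≥ 11.1 mmol/L
    (2 h after 75 g oral glucose), or current hypoglycemic treatment.
    Raises :class:`InsufficientData` when all four are unavailable.
    """
    if (
        r.hba1c is None
        and r.fbg is None
        and r.post_challenge_glucose is None
        and not r.on_hypoglycemic_treatment
    ):
        raise InsufficientData(
            f"patient {r.patient_id!r}: no diagnostic labs and no treatment flag"
        )
    return (
        (r.hba1c is not None and r.hba1c >= 6.5)
        or (r.fbg is not None and r.fbg >= 7.0)
        or (r.post_challenge_glucose is not None and r.post_challenge_glucose >= 11.1)
        or r.on_hypoglycemic_treatment
    )


def count_risk_factors(r: ClinicalRecord) -> tuple[int, list[str]]:
    """Count the study's five cardiovascular risk factors.

    Factors: hypertension (BP ≥140/90 or antihypertensive use),
    dyslipidemia (TC ≥5.2 mmol/L or lipid-lowering treatment), current
    smoking, obesity or inactivity (BMI ≥28 kg/m² or not exercising
    regularly ≥3×/week), and family history of myocardial infarction.

    A factor whose inputs are missing counts as not met; its name is
    returned in the missing-data list so callers can report it.
    """
    count = 0
    missing: list[str] = []

    if r.on_antihypertensive:
        count += 1
    elif r.sbp is None and r.dbp is None:
        missing.append("hypertension")
    elif (r.sbp is not None and r.sbp >= 140) or (r.dbp is not None and r.dbp >= 90):
        count += 1

    if r.on_lipid_lowering:
        count += 1
    elif r.total_cholesterol is None:
        missing.append("dyslipidemia")
    elif r.total_cholesterol >= 5.2:
        count += 1

    if r.current_smoker:
        count += 1

    # obesity and inactivity form one combined factor
    if (r.bmi is not None and r.bmi >= 28) or not r.regular_exercise:
        count += 1
    elif r.bmi is None:
        missing.append("obesity_or_inactivity")

    if r.family_history_mi:
        count += 1

    return count, missing


def is_eligible_dm(r: ClinicalRecord) -> tuple[bool, list[str]]:
    """Apply the study's inclusion/exclusion rules for the diabetic arm.

    Eligible iff the T2DM diagnostic rule holds, at least one other
    cardiovascular risk factor is present, and none of the exclusion
    criteria (known/suspected CHD, abnormal resting ECG, prior MI/CABG/
    stent, insufficient diagnostic data) apply. Returns the verdict and
    the list of failed rules; never raises.
    """
    reasons: list[str] = []
    try:
        if not meets_t2dm_criteria(r):
            reasons.append("t2dm_criteria_not_met")
    except InsufficientData:
        reasons.append("insufficient_diagnostic_data")
    n_factors, _missing = count_risk_factors(r)
    if n_factors < 1:
        reasons.append("no_risk_factor")
    if r.prior_chd_or_symptoms:
        reasons.append("prior_chd_or_symptoms")
    if r.abnormal_ecg:
        reasons.append("abnormal_ecg")
    if r.prior_mi_cabg_stent:
        reasons.append("prior_mi_cabg_stent")
    return (not reasons, reasons)


def stratify_risk(
    ukpds_fatal_risk_pct: float,
    bounds: RiskTierBounds = DEFAULT_TIER_BOUNDS,
) -> RiskTier:
    """Assign the 10-year fatal-CHD risk tier from the risk percent."""
    if not 0 <= ukpds_fatal_risk_pct <= 100:
        raise ValueError(
            f"risk percent must be in [0, 100], got {ukpds_fatal_risk_pct}"
        )
    if ukpds_fatal_risk_pct < bounds.lower:
        return RiskTier.LOW
    if ukpds_fatal_risk_pct <= bounds.upper:
        return RiskTier.MODERATE
    return RiskTier.HIGH


def stratify_record(
    r: ClinicalRecord,
    bounds: RiskTierBounds = DEFAULT_TIER_BOUNDS,
    risk_fn: Callable[[ClinicalRecord], float] | None = None,
) -> RiskTier:
    """Tier a clinical record, optionally through a user-supplied risk engine.

    ``risk_fn`` replaces the precomputed ``ukpds_fatal_risk_pct`` column
    when given (hook for plugging in an actual risk-engine implementation).
    """
    risk = risk_fn(r) if risk_fn is not None else r.ukpds_fatal_risk_pct
    if risk is None:
        raise InsufficientData(
            f"patient {r.patient_id!r}: no UKPDS fatal risk percent available"
        )
    return stratify_risk(risk, bounds)
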