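"""Synthetic cohort generation.

Generates a control group plus three diabetic CHD-risk tiers with
segment-level lesions and clinical covariates whose group-wise marginals
(per-segment lesion prevalence, stenosis-severity mix, plaque-composition
mix, covariate locations) emulate the published screening cohort. Lesions
are drawn independently per applicable segment (a Bernoulli per segment,
optionally modulated by a patient-level frailty to induce within-patient
clustering); severity is a three-component mixture (mild / moderate /
severe) with uniform stenosis percent inside each stratum; composition is
a calcified / non-calcified / mixed mixture.

The generator is first-class, tested code: every emitted patient passes
the coronary-model validation, and every diabetic patient satisfies the
study's eligibility rules by construction (treated diabetes and at least
one cardiovascular risk factor, no exclusion flags).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .clinical import ClinicalRecord, RiskTierBounds, DEFAULT_TIER_BOUNDS, stratify_risk
from .cohort import CohortMember, CohortTable
from .scoring import grade_lesion
from .segments import (
    CoronarySegment,
    Dominance,
    PatientCCTA,
    PlaqueComposition,
    SegmentLesion,
    applicable_segments,
    validate_patient,
)

__all__ = [
    "CovariateProfile",
    "GroupProfile",
    "SimulationConfig",
    "generate_patient",
    "generate_cohort",
    "recover_profile",
    "default_profiles",
    "default_config",
    "reference_segment_counts",
]

#: Stenosis-percent range sampled uniformly within each severity stratum.
SEVERITY_RANGES = {
    "mild": (10.0, 49.0),
    "moderate": (50.0, 70.0),
    "severe": (71.0, 95.0),
}


def reference_segment_counts() -> dict[str, dict[str, dict[str, int]]]:
    """Published per-group stenotic-segment counts (packaged transcription).

    Keyed block → row → group → count; the ``segment`` block drives the
    default per-segment lesion probabilities.
    """
    out: dict[str, dict[str, dict[str, int]]] = {}
    path = resources.files("coroscore.data").joinpath("reference_segment_counts.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            block = out.setdefault(row["block"], {})
            entry = block.setdefault(row["row"], {})
            for g in ("control", "low", "moderate", "high"):
                entry[g] = int(row[g])
    return out


@dataclass(frozen=True)
class CovariateProfile:
    """Clinical covariate distributions for one group (means ± SD unless noted)."""

    age: tuple[float, float]
    sbp: tuple[float, float]
    total_cholesterol: tuple[float, float]
    hdl: tuple[float, float]
    triglycerides: tuple[float, float]
    fbg: tuple[float, float]
    hba1c: tuple[float, float]
    smoking_prob: float
    male_prob: float
    dm_duration_median: Optional[float] = None


@dataclass(frozen=True)
class GroupProfile:
    """Generative profile for one study group."""

    label: str
    n_patients: int
    is_dm: bool
    risk_range: tuple[float, float]  # UKPDS fatal-risk percent, uniform
    segment_probs: Mapping[str, float]  # per-segment lesion probability
    severity_mix: tuple[float, float, float]  # mild, moderate, severe
    composition_mix: tuple[float, float, float]  # calcified, non-calc, mixed
    covariates: CovariateProfile
    dominance_probs: tuple[float, float, float] = (0.85, 0.08, 0.07)
    frailty_sd: float = 0.0  # lognormal sigma of patient-level lesion frailty

    def validate(self, tier_bounds: RiskTierBounds = DEFAULT_TIER_BOUNDS) -> list[str]:
        problems: list[str] = []
        if self.n_patients < 1:
            problems.append(f"{self.label}: n_patients must be >= 1")
        for name, mix in (
            ("severity_mix", self.severity_mix),
            ("composition_mix", self.composition_mix),
            ("dominance_probs", self.dominance_probs),
        ):
            if any(p < 0 or p > 1 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                problems.append(f"{self.label}: {name} must be probabilities summing to 1")
        for seg, p in self.segment_probs.items():
            if not 0 <= p <= 1:
                problems.append(f"{self.label}: segment prob for {seg} out of [0,1]")
        lo, hi = self.risk_range
        if not 0 <= lo <= hi <= 100:
            problems.append(f"{self.label}: risk_range must be ordered within [0,100]")
        if self.is_dm:
            tiers = {stratify_risk(lo, tier_bounds), stratify_risk(hi, tier_bounds)}
            if len(tiers) != 1:
                problems.append(
                    f"{self.label}: risk_range {self.risk_range} spans tier boundaries"
                )
        return problems


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    profiles: tuple[GroupProfile, ...]

    def validate(self) -> list[str]:
        problems: list[str] = []
        for prof in self.profiles:
            problems.extend(prof.validate())
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            problems.append("duplicate group labels")
        return problems


_COVARIATES = {
    "control": CovariateProfile(
        age=(65, 13), sbp=(139, 19), total_cholesterol=(4.5, 1.0),
        hdl=(1.2, 0.2), triglycerides=(1.4, 0.6), fbg=(5.4, 0.5),
        hba1c=(5.5, 0.4), smoking_prob=0.23, male_prob=0.51,
    ),
    "low": CovariateProfile(
        age=(51, 5), sbp=(128, 16), total_cholesterol=(4.0, 1.0),
        hdl=(1.1, 0.2), triglycerides=(1.3, 0.6), fbg=(6.8, 1.5),
        hba1c=(8.1, 1.8), smoking_prob=0.20, male_prob=0.48,
        dm_duration_median=3.0,
    ),
    "moderate": CovariateProfile(
        age=(58, 6), sbp=(134, 17), total_cholesterol=(4.7, 1.1),
        hdl=(1.2, 0.3), triglycerides=(1.5, 0.6), fbg=(7.5, 1.5),
        hba1c=(9.1, 2.2), smoking_prob=0.38, male_prob=0.54,
        dm_duration_median=8.0,
    ),
    "high": CovariateProfile(
        age=(63, 8), sbp=(143, 17), total_cholesterol=(4.7, 1.1),
        hdl=(1.1, 0.2), triglycerides=(1.7, 0.6), fbg=(7.7, 1.8),
        hba1c=(9.6, 2.0), smoking_prob=0.30, male_prob=0.66,
        dm_duration_median=15.0,
    ),
}

# Obstructive fractions in the published severity block are ~13 / 22 / 46 /
# 47% per group; mixes split the obstructive mass between moderate and severe.
_SEVERITY = {
    "control": (0.87, 0.10, 0.03),
    "low": (0.78, 0.16, 0.06),
    "moderate": (0.54, 0.32, 0.14),
    "high": (0.53, 0.31, 0.16),
}

# Calcified fractions ~13 / 3 / 9 / 11%; the remainder splits 24:76 into
# non-calcified : mixed (the published non-calcified share of DM plaques).
def _composition(calc: float) -> tuple[float, float, float]:
    rest = 1.0 - calc
    return (calc, round(rest * 0.24, 6), round(rest - rest * 0.24, 6))


_CALCIFIED = {"control": 0.13, "low": 0.03, "moderate": 0.09, "high": 0.11}

_RISK_RANGES = {
    "control": (0.5, 7.4),
    "low": (1.0, 7.4),
    "moderate": (7.5, 15.0),
    "high": (15.5, 40.0),
}

_DEFAULT_N = {"control": 74, "low": 40, "moderate": 48, "high": 53}


def default_profiles(
    n_patients: Mapping[str, int] | None = None,
    frailty_sd: float = 0.0,
) -> tuple[GroupProfile, ...]:
    """Default study-condition profiles for the four groups.

    Per-segment lesion probabilities are the published per-group segment
    counts divided by the group size, so expected lesion burden per
    patient matches the published marginal totals.
    """
    counts = reference_segment_counts()["segment"]
    sizes = dict(_DEFAULT_N)
    if n_patients:
        sizes.update(n_patients)
    profiles = []
    for label in ("control", "low", "moderate", "high"):
        seg_probs = {
            seg: min(1.0, counts[seg][label] / _DEFAULT_N[label])
            for seg in counts
        }
        profiles.append(
            GroupProfile(
                label=label,
                n_patients=sizes[label],
                is_dm=label != "control",
                risk_range=_RISK_RANGES[label],
                segment_probs=seg_probs,
                severity_mix=_SEVERITY[label],
                composition_mix=_composition(_CALCIFIED[label]),
                covariates=_COVARIATES[label],
                frailty_sd=frailty_sd,
            )
        )
    return tuple(profiles)


def default_config(seed: int = 0, n_patients: Mapping[str, int] | None = None) -> SimulationConfig:
    return SimulationConfig(seed=seed, profiles=default_profiles(n_patients))


def _pos_normal(rng: np.random.Generator, mean: float, sd: float, lo: float = 0.1) -> float:
    return float(max(lo, rng.normal(mean, sd)))


_DOMINANCES = (Dominance.RIGHT, Dominance.LEFT, Dominance.BALANCED)
_COMPOSITIONS = (
    PlaqueComposition.CALCIFIED,
    PlaqueComposition.NON_CALCIFIED,
    PlaqueComposition.MIXED,
)
_STRATA = ("mild", "moderate", "severe")


def generate_patient(
    profile: GroupProfile,
    rng: np.random.Generator,
    patient_id: str | None = None,
) -> tuple[ClinicalRecord, PatientCCTA]:
    """Draw one patient (clinical record + CCTA annotation) from a profile."""
    pid = patient_id or f"{profile.label}-{rng.integers(0, 10**9):09d}"
    cov = profile.covariates

    dominance = _DOMINANCES[rng.choice(3, p=profile.dominance_probs)]
    frailty = (
        float(np.exp(rng.normal(0.0, profile.frailty_sd)))
        if profile.frailty_sd > 0
        else 1.0
    )
    lesions = []
    for seg in sorted(applicable_segments(dominance), key=lambda s: s.value):
        p_seg = min(1.0, profile.segment_probs.get(seg.value, 0.0) * frailty)
        if rng.random() < p_seg:
            stratum = _STRATA[rng.choice(3, p=profile.severity_mix)]
            lo, hi = SEVERITY_RANGES[stratum]
            pct = float(rng.uniform(lo, hi))
            comp = _COMPOSITIONS[rng.choice(3, p=profile.composition_mix)]
            lesions.append(SegmentLesion(seg, pct, comp))
    ccta = PatientCCTA(pid, dominance, tuple(lesions))

    smoker = bool(rng.random() < cov.smoking_prob)
    on_antihyper = bool(rng.random() < (0.5 if profile.is_dm else 0.2))
    on_lipid = bool(rng.random() < (0.15 if profile.is_dm else 0.1))
    bmi = _pos_normal(rng, 25.5, 3.0, lo=15)
    exercises = bool(rng.random() < 0.75)
    fam_hist = bool(rng.random() < (0.21 if profile.is_dm else 0.10))
    sbp = _pos_normal(rng, *cov.sbp, lo=80)
    hypertensive = on_antihyper or sbp >= 140
    if profile.is_dm and not (
        hypertensive or smoker or fam_hist or bmi >= 28 or not exercises
        or _COVARIATES[profile.label].total_cholesterol[0] >= 5.2
    ):
        # study inclusion requires >= 1 cardiovascular risk factor;
        # hypertension is by far the most prevalent one in this population
        on_antihyper = True

    duration = None
    if profile.is_dm and cov.dm_duration_median is not None:
        duration = float(max(0.5, rng.gamma(2.0, cov.dm_duration_median / 2.0)))

    record = ClinicalRecord(
        patient_id=pid,
        age=_pos_normal(rng, *cov.age, lo=30),
        sex="male" if rng.random() < cov.male_prob else "female",
        dm_status=profile.is_dm,
        dm_duration=duration,
        hba1c=min(18.0, _pos_normal(rng, *cov.hba1c, lo=4.0)),
        fbg=_pos_normal(rng, *cov.fbg, lo=3.0),
        on_hypoglycemic_treatment=profile.is_dm,
        sbp=sbp,
        dbp=_pos_normal(rng, 80, 10, lo=50),
        on_antihypertensive=on_antihyper,
        total_cholesterol=_pos_normal(rng, *cov.total_cholesterol, lo=2.0),
        hdl=_pos_normal(rng, *cov.hdl, lo=0.4),
        triglycerides=_pos_normal(rng, *cov.triglycerides, lo=0.3),
        on_lipid_lowering=on_lipid,
        current_smoker=smoker,
        bmi=bmi,
        regular_exercise=exercises,
        family_history_mi=fam_hist,
        ukpds_fatal_risk_pct=float(rng.uniform(*profile.risk_range)),
    )
    return record, ccta


def generate_cohort(cfg: SimulationConfig) -> CohortTable:
    """Generate the full multi-group cohort deterministically from the seed."""
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid simulation config: " + "; ".join(problems))
    rng = np.random.default_rng(cfg.seed)
    members = []
    for prof in cfg.profiles:
        for i in range(prof.n_patients):
            pid = f"{prof.label}-{i + 1:04d}"
            record, ccta = generate_patient(prof, rng, patient_id=pid)
            members.append(CohortMember(record=record, ccta=ccta, group=prof.label))
    return CohortTable(members)


def recover_profile(cohort: CohortTable) -> dict[str, dict]:
    """Empirical per-group lesion marginals (parameter-recovery harness).

    For each group: per-segment lesion frequency with the number of
    patients for whom the segment was anatomically applicable as the
    denominator, the severity-grade mix over lesions, and the composition
    mix. Groups with no lesions are flagged instead of estimated.
    """
    out: dict[str, dict] = {}
    for group, patients in cohort.patients_by_group().items():
        n = len(patients)
        seg_hits = {seg: 0 for seg in CoronarySegment}
        seg_n = {seg: 0 for seg in CoronarySegment}
        sev = {1: 0, 2: 0, 3: 0}
        comp = {c: 0 for c in _COMPOSITIONS}
        total = 0
        for p in patients:
            app = applicable_segments(p.dominance)
            for seg in app:
                seg_n[seg] += 1
            for lesion in p.lesions:
                seg_hits[lesion.segment] += 1
                sev[grade_lesion(lesion.stenosis_pct)] += 1
                comp[lesion.composition] += 1
                total += 1
        entry: dict = {"n_patients": n, "n_lesions": total}
        if total == 0:
            entry["flag"] = "no lesions in group; mixes not estimable"
        else:
            entry["severity_mix"] = tuple(sev[g] / total for g in (1, 2, 3))
            entry["composition_mix"] = tuple(comp[c] / total for c in _COMPOSITIONS)
        entry["segment_freq"] = {
            seg.value: (seg_hits[seg] / seg_n[seg] if seg_n[seg] else float("nan"))
            for seg in CoronarySegment
        }
        entry["segment_denominator"] = {seg.value: seg_n[seg] for seg in CoronarySegment}
        out[group] = entry
    return out
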