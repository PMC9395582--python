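"""Per-patient CCTA plaque-burden scores.

Five scores are computed from the segment-level lesion annotations:

* **SIS** (segment involvement score) — number of segments with any plaque,
  0–18, irrespective of stenosis degree.
* **SSS** (segment stenosis score) — per-segment severity grades (1 mild,
  2 moderate/obstructive, 3 severe) summed over the tree.
* **SC** (stenosis coefficient) — SSS / SIS, defined as 0 when SIS is 0.
* **SPP** (severe proximal plaque) — any >70% stenosis in the left main or
  a proximal LAD / LCx / RCA segment.
* **CT-LeSc** (CT-adapted Leaman score) — per-lesion product of the
  dominance-aware localization weight, a composition factor (1.0 calcified,
  1.5 non-calcified or mixed) and a stenosis factor (1.0 obstructive,
  0.615 non-obstructive), summed over all lesions.

Obstructive stenosis (OS) is a ≥50% luminal diameter reduction; severe is
strictly >70%. Grade boundaries are configurable through
:class:`GradeBoundaries` but default to those definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

from .segments import (
    PROXIMAL_SEGMENTS,
    CoronarySegment,
    Dominance,
    PatientCCTA,
    PlaqueComposition,
    SegmentLesion,
    require_valid,
    segment_weight,
)

__all__ = [
    "GradeBoundaries",
    "ScorePanel",
    "grade_lesion",
    "is_obstructive",
    "compute_sis",
    "compute_sss",
    "compute_sc",
    "compute_spp",
    "lesion_ct_lesc",
    "patient_ct_lesc",
    "score_patient",
    "COMPOSITION_FACTOR",
    "NON_OBSTRUCTIVE_FACTOR",
]

#: CT-LeSc multiplication factor by plaque composition.
COMPOSITION_FACTOR = {
    PlaqueComposition.CALCIFIED: 1.0,
    PlaqueComposition.NON_CALCIFIED: 1.5,
    PlaqueComposition.MIXED: 1.5,
}

#: CT-LeSc multiplication factor for a non-obstructive (<50%) lesion.
NON_OBSTRUCTIVE_FACTOR = 0.615

RoundingMode = Literal["full_precision", "paper_2dp"]


@dataclass(frozen=True)
class GradeBoundaries:
    """Stenosis-percent cut points for severity grading.

    ``obstructive_pct`` is the inclusive lower bound of grade 2 (and of the
    obstructive-stenosis flag); ``severe_pct`` is the exclusive lower bound
    of grade 3 (a lesion exactly at it is grade 2, not severe).
    """

    obstructive_pct: float = 50.0
    severe_pct: float = 70.0

    def __post_init__(self) -> None:
        if not 0 < self.obstructive_pct <= self.severe_pct <= 100:
            raise ValueError(
                "require 0 < obstructive_pct <= severe_pct <= 100"
            )


DEFAULT_BOUNDARIES = GradeBoundaries()


@dataclass(frozen=True)
class ScorePanel:
    """The full per-patient score panel."""

    patient_id: str
    sis: int
    sss: int
    sc: float
    spp_positive: bool
    ct_lesc: float
    has_obstructive: bool
    partial_lesc: dict[CoronarySegment, float] = field(default_factory=dict)


def _check_pct(stenosis_pct: float) -> None:
    if not 0.0 <= stenosis_pct <= 100.0:
        raise ValueError(
            f"stenosis percent must be in [0, 100], got {stenosis_pct}"
        )


def grade_lesion(
    stenosis_pct: float, boundaries: GradeBoundaries = DEFAULT_BOUNDARIES
) -> int:
    """Severity grade (1–3) of a present plaque.

    Grade 0 means "no plaque" and is never returned for a recorded lesion:
    1 below the obstructive cut, 2 from obstructive up to and including the
    severe cut, 3 strictly above it.
    """
    _check_pct(stenosis_pct)
    if stenosis_pct > boundaries.severe_pct:
        return 3
    if stenosis_pct >= boundaries.obstructive_pct:
        return 2
    return 1


def is_obstructive(
    stenosis_pct: float, boundaries: GradeBoundaries = DEFAULT_BOUNDARIES
) -> bool:
    """True iff the lumen reduction meets the obstructive (≥50%) cut."""
    _check_pct(stenosis_pct)
    return stenosis_pct >= boundaries.obstructive_pct


def compute_sis(p: PatientCCTA) -> int:
    """Count of distinct segments exhibiting plaque (0–18)."""
    require_valid(p)
    return len({lesion.segment for lesion in p.lesions})


def compute_sss(
    p: PatientCCTA, boundaries: GradeBoundaries = DEFAULT_BOUNDARIES
) -> int:
    """Sum of per-segment severity grades."""
    require_valid(p)
    return sum(grade_lesion(l.stenosis_pct, boundaries) for l in p.lesions)


def compute_sc(sis: int, sss: int) -> float:
    """Stenosis coefficient SSS/SIS; 0 when SIS is 0."""
    if sis == 0:
        if sss != 0:
            raise ValueError("SSS must be 0 when SIS is 0")
        return 0.0
    if not sis <= sss <= 3 * sis:
        raise ValueError(f"inconsistent scores: SIS={sis}, SSS={sss}")
    return sss / sis


def compute_spp(
    p: PatientCCTA, boundaries: GradeBoundaries = DEFAULT_BOUNDARIES
) -> bool:
    """Severe proximal plaque: any >70% lesion on LM or a proximal segment."""
    require_valid(p)
    return any(
        l.segment in PROXIMAL_SEGMENTS and l.stenosis_pct > boundaries.severe_pct
        for l in p.lesions
    )


def lesion_ct_lesc(
    lesion: SegmentLesion,
    dominance: Dominance,
    boundaries: GradeBoundaries = DEFAULT_BOUNDARIES,
) -> float:
    """Partial CT-LeSc of one lesion: weight × composition × stenosis factor."""
    weight = segment_weight(lesion.segment, dominance)
    comp = COMPOSITION_FACTOR[lesion.composition]
    sten = 1.0 if is_obstructive(lesion.stenosis_pct, boundaries) else NON_OBSTRUCTIVE_FACTOR
    return weight * comp * sten


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def patient_ct_lesc(
    p: PatientCCTA,
    rounding_mode: RoundingMode = "full_precision",
    boundaries: GradeBoundaries = DEFAULT_BOUNDARIES,
) -> float:
    """Patient-level CT-LeSc: sum of per-lesion partials.

    Under ``paper_2dp`` each partial is rounded half-up to two decimals
    before summing, the convention used when the score is reported per
    lesion to two decimals; ``full_precision`` keeps exact arithmetic.
    """
    require_valid(p)
    partials = (lesion_ct_lesc(l, p.dominance, boundaries) for l in p.lesions)
    if rounding_mode == "paper_2dp":
        return _round_half_up(sum(_round_half_up(v) for v in partials))
    if rounding_mode == "full_precision":
        return sum(partials)
    raise ValueError(f"unknown rounding mode {rounding_mode!r}")


def score_patient(
    p: PatientCCTA,
    rounding_mode: RoundingMode = "full_precision",
    boundaries: GradeBoundaries = DEFAULT_BOUNDARIES,
) -> ScorePanel:
    """Compute the full score panel for one patient."""
    require_valid(p)
    sis = compute_sis(p)
    sss = compute_sss(p, boundaries)
    partials = {
        l.segment: lesion_ct_lesc(l, p.dominance, boundaries) for l in p.lesions
    }
    if rounding_mode == "paper_2dp":
        partials = {seg: _round_half_up(v) for seg, v in partials.items()}
        total = _round_half_up(sum(partials.values()))
    else:
        total = sum(partials.values())
    return ScorePanel(
        patient_id=p.patient_id,
        sis=sis,
        sss=sss,
        sc=compute_sc(sis, sss),
        spp_positive=compute_spp(p, boundaries),
        ct_lesc=total,
        has_obstructive=any(
            is_obstructive(l.stenosis_pct, boundaries) for l in p.lesions
        ),
        partial_lesc=partials,
    )
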