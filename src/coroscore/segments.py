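"""The 18-segment SCCT coronary model and CT-adapted Leaman localization weights.

The coronary tree is represented purely as a set of 18 labelled segments
(the SCCT reporting model); no topology or image geometry is carried. Each
segment has a localization weight that depends on coronary dominance —
which artery supplies the posterior descending territory — because the
myocardial mass at risk behind a given segment changes with dominance.
Some segments do not exist under a given dominance pattern (e.g. a
posterior descending artery from the left coronary in a right-dominant
heart); those (segment, dominance) cells are *not applicable* and any
lesion annotated there is treated as corrupt input, never as weight zero.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "CoronarySegment",
    "Dominance",
    "PlaqueComposition",
    "SegmentLesion",
    "PatientCCTA",
    "NotApplicableSegment",
    "segment_weight",
    "applicable_segments",
    "load_weight_table",
    "validate_patient",
    "PROXIMAL_SEGMENTS",
]


class Dominance(str, enum.Enum):
    """Coronary dominance pattern."""

    RIGHT = "right"
    LEFT = "left"
    BALANCED = "balanced"


class PlaqueComposition(str, enum.Enum):
    """Plaque tissue class as read on CCTA."""

    CALCIFIED = "calcified"
    NON_CALCIFIED = "non_calcified"
    MIXED = "mixed"


class CoronarySegment(str, enum.Enum):
    """The 18 SCCT coronary segments.

    Enum values are canonical snake-case tokens; :attr:`display_name` gives
    the printable name. Readers accept either form.
    """

    RCA_PROXIMAL = "rca_proximal"
    RCA_MID = "rca_mid"
    RCA_DISTAL = "rca_distal"
    PDA = "pda"
    LEFT_MAIN = "left_main"
    LAD_PROXIMAL = "lad_proximal"
    LAD_MID = "lad_mid"
    LAD_DISTAL = "lad_distal"
    FIRST_DIAGONAL = "first_diagonal"
    SECOND_DIAGONAL = "second_diagonal"
    LCX_PROXIMAL = "lcx_proximal"
    FIRST_OBTUSE_MARGINAL = "first_obtuse_marginal"
    LCX_DISTAL = "lcx_distal"
    SECOND_OBTUSE_MARGINAL = "second_obtuse_marginal"
    PDA_FROM_LCA = "pda_from_lca"
    PL_BRANCH_FROM_LCA = "pl_branch_from_lca"
    PL_BRANCH_FROM_RCA = "pl_branch_from_rca"
    INTERMEDIATE_BRANCH = "intermediate_branch"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def parse(cls, name: str) -> "CoronarySegment":
        """Resolve a canonical token or printable name to a segment.

        Raises ``KeyError`` listing accepted names for unknown input.
        """
        key = name.strip()
        try:
            return cls(key.lower())
        except ValueError:
            pass
        try:
            return _BY_DISPLAY[key.lower()]
        except KeyError:
            accepted = sorted(
                {s.value for s in cls} | {s.display_name for s in cls}
            )
            raise KeyError(
                f"unknown coronary segment {name!r}; accepted names: "
                + ", ".join(accepted)
            ) from None


_DISPLAY_NAMES = {
    CoronarySegment.RCA_PROXIMAL: "RCA proximal",
    CoronarySegment.RCA_MID: "RCA mid",
    CoronarySegment.RCA_DISTAL: "RCA distal",
    CoronarySegment.PDA: "PDA",
    CoronarySegment.LEFT_MAIN: "Left main",
    CoronarySegment.LAD_PROXIMAL: "LAD proximal",
    CoronarySegment.LAD_MID: "LAD mid",
    CoronarySegment.LAD_DISTAL: "LAD distal",
    CoronarySegment.FIRST_DIAGONAL: "1st diagonal",
    CoronarySegment.SECOND_DIAGONAL: "2nd diagonal",
    CoronarySegment.LCX_PROXIMAL: "LCx proximal",
    CoronarySegment.FIRST_OBTUSE_MARGINAL: "1st obtuse marginal",
    CoronarySegment.LCX_DISTAL: "LCx distal",
    CoronarySegment.SECOND_OBTUSE_MARGINAL: "2nd obtuse marginal",
    CoronarySegment.PDA_FROM_LCA: "PDA from LCA",
    CoronarySegment.PL_BRANCH_FROM_LCA: "PL branch from LCA",
    CoronarySegment.PL_BRANCH_FROM_RCA: "PL branch from RCA",
    CoronarySegment.INTERMEDIATE_BRANCH: "Intermediate branch",
}
_BY_DISPLAY = {v.lower(): k for k, v in _DISPLAY_NAMES.items()}

#: Segments whose severe (>70%) disease defines a positive severe-proximal-
#: plaque (SPP) flag: left main plus the proximal LAD, LCx and RCA.
PROXIMAL_SEGMENTS = frozenset(
    {
        CoronarySegment.LEFT_MAIN,
        CoronarySegment.LAD_PROXIMAL,
        CoronarySegment.LCX_PROXIMAL,
        CoronarySegment.RCA_PROXIMAL,
    }
)


class NotApplicableSegment(ValueError):
    """A segment that does not exist under the given dominance pattern."""

    def __init__(self, segment: CoronarySegment, dominance: Dominance):
        self.segment = segment
        self.dominance = dominance
        super().__init__(
            f"segment {segment.display_name!r} is not applicable under "
            f"{dominance.value} dominance"
        )


def load_weight_table() -> dict[tuple[CoronarySegment, Dominance], float | None]:
    """Read the packaged localization-weight table.

    Returns a complete mapping over all 18 × 3 (segment, dominance) cells;
    not-applicable cells map to ``None``.
    """
    table: dict[tuple[CoronarySegment, Dominance], float | None] = {}
    path = resources.files("coroscore.data").joinpath("ct_lesc_weights.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            seg = CoronarySegment(row["segment"])
            for dom in Dominance:
                cell = row[dom.value].strip()
                table[(seg, dom)] = None if cell == "na" else float(cell)
    if len(table) != 54:
        raise RuntimeError("weight table must contain all 54 cells")
    return table


_WEIGHTS = load_weight_table()


def segment_weight(segment: CoronarySegment, dominance: Dominance) -> float:
    """Localization weight of ``segment`` under ``dominance``.

    Raises :class:`NotApplicableSegment` for anatomically absent cells.
    """
    w = _WEIGHTS[(segment, dominance)]
    if w is None:
        raise NotApplicableSegment(segment, dominance)
    return w


def applicable_segments(dominance: Dominance) -> frozenset[CoronarySegment]:
    """Segments that exist under ``dominance`` (non-"na" weight cells)."""
    return frozenset(
        seg for seg in CoronarySegment if _WEIGHTS[(seg, dominance)] is not None
    )


@dataclass(frozen=True)
class SegmentLesion:
    """One plaque annotation on one coronary segment.

    ``stenosis_pct`` is the maximal luminal diameter reduction in percent.
    A lesion record implies plaque is present (the >1 mm² cross-section
    criterion is assumed satisfied upstream by the reader).
    """

    segment: CoronarySegment
    stenosis_pct: float
    composition: PlaqueComposition

    def __post_init__(self) -> None:
        if not 0.0 <= self.stenosis_pct <= 100.0:
            raise ValueError(
                f"stenosis_pct must be in [0, 100], got {self.stenosis_pct}"
            )


@dataclass(frozen=True)
class PatientCCTA:
    """All lesion annotations for one patient — the scoring unit."""

    patient_id: str
    dominance: Dominance
    lesions: tuple[SegmentLesion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))


def validate_patient(p: PatientCCTA) -> list[str]:
    """Check patient-level invariants; return human-readable violations.

    Validation never raises: an empty list means the patient is valid.
    Checked rules: at most one lesion per segment, and no lesion on a
    segment that is not applicable for the patient's dominance.
    """
    violations: list[str] = []
    seen: set[CoronarySegment] = set()
    for lesion in p.lesions:
        if lesion.segment in seen:
            violations.append(
                f"duplicate lesion on segment {lesion.segment.display_name!r}"
            )
        seen.add(lesion.segment)
        if _WEIGHTS[(lesion.segment, p.dominance)] is None:
            violations.append(
                f"lesion on segment {lesion.segment.display_name!r} which is "
                f"not applicable under {p.dominance.value} dominance"
            )
    return violations


def require_valid(p: PatientCCTA) -> None:
    """Raise ``ValueError`` listing all violations if ``p`` is invalid."""
    violations = validate_patient(p)
    if violations:
        raise ValueError(
            f"invalid patient {p.patient_id!r}: " + "; ".join(violations)
        )
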