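"""Cohort container pairing clinical records with CCTA annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .clinical import ClinicalRecord
from .segments import PatientCCTA

__all__ = ["CohortMember", "CohortTable"]


@dataclass(frozen=True)
class CohortMember:
    record: ClinicalRecord
    ccta: PatientCCTA
    group: str


@dataclass
class CohortTable:
    """Collection of (clinical record, CCTA) pairs with group labels.

    Groups partition the cohort; every member carries exactly one label.
    """

    members: list[CohortMember] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[CohortMember]:
        return iter(self.members)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.group, None)
        return list(seen)

    def patients_by_group(self) -> dict[str, list[PatientCCTA]]:
        out: dict[str, list[PatientCCTA]] = {}
        for m in self.members:
            out.setdefault(m.group, []).append(m.ccta)
        return out

    def records_by_group(self) -> dict[str, list[ClinicalRecord]]:
        out: dict[str, list[ClinicalRecord]] = {}
        for m in self.members:
            out.setdefault(m.group, []).append(m.record)
        return out
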