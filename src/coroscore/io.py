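"""Readers and writers for the lesion, clinical, score and report tables.

All interchange is comma-separated UTF-8 text with a mandatory header row
and decimal points. Stenosis must be given in percent (0–100); values
that look like fractions (in (0, 1)) are rejected rather than silently
rescaled, to surface unit bugs at the boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .clinical import ClinicalRecord, RiskTierBounds
from .cohort import CohortMember, CohortTable
from .scoring import GradeBoundaries, RoundingMode, ScorePanel
from .segments import (
    CoronarySegment,
    Dominance,
    PatientCCTA,
    PlaqueComposition,
    SegmentLesion,
)
from .stats import DichotomizationThresholds

logger = logging.getLogger("coroscore")

__all__ = [
    "RunConfig",
    "read_lesion_table",
    "write_lesion_table",
    "read_clinical_table",
    "write_clinical_table",
    "write_score_table",
    "worked_example_path",
    "load_worked_example",
]

LESION_COLUMNS = ["patient_id", "dominance", "segment", "stenosis_pct", "composition"]

#: worst-first composition order used when collapsing duplicate rows
_COMPOSITION_SEVERITY = {
    PlaqueComposition.MIXED: 2,
    PlaqueComposition.NON_CALCIFIED: 1,
    PlaqueComposition.CALCIFIED: 0,
}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with the study's published defaults."""

    boundaries: GradeBoundaries = GradeBoundaries()
    thresholds: DichotomizationThresholds = DichotomizationThresholds()
    tier_bounds: RiskTierBounds = RiskTierBounds()
    rounding_mode: RoundingMode = "full_precision"
    percentile_method: str = "linear"
    significance_level: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        if "grade_boundaries" in raw:
            kwargs["boundaries"] = GradeBoundaries(**raw["grade_boundaries"])
        if "thresholds" in raw:
            kwargs["thresholds"] = DichotomizationThresholds(**raw["thresholds"])
        if "tier_bounds" in raw:
            kwargs["tier_bounds"] = RiskTierBounds(**raw["tier_bounds"])
        for key in ("rounding_mode", "percentile_method", "significance_level", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _parse_composition(token: str, line: int) -> PlaqueComposition:
    t = token.strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return PlaqueComposition(t)
    except ValueError:
        raise ValueError(
            f"line {line}: unknown plaque composition {token!r}; accepted: "
            "calcified, non_calcified, mixed"
        ) from None


def _parse_stenosis(token: str, line: int) -> float:
    try:
        pct = float(token)
    except ValueError:
        raise ValueError(f"line {line}: stenosis_pct {token!r} is not a number") from None
    if 0.0 < pct < 1.0:
        raise ValueError(
            f"line {line}: stenosis_pct {pct} looks like a fraction; "
            "give percent in [0, 100] (fractions are rejected, not rescaled)"
        )
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"line {line}: stenosis_pct {pct} out of [0, 100]")
    return pct


def read_lesion_table(path: str | Path) -> list[PatientCCTA]:
    """Read a lesion CSV into one :class:`PatientCCTA` per patient id.

    Duplicate segment rows for one patient are collapsed to the maximal
    stenosis and the worst composition (mixed > non-calcified > calcified)
    with a warning; conflicting dominance entries for one patient raise.
    Malformed rows raise with their line number.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion table missing columns: {missing}")

    dominance: dict[str, Dominance] = {}
    lesions: dict[str, dict[CoronarySegment, SegmentLesion]] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        pid = str(row["patient_id"]).strip()
        try:
            dom = Dominance(str(row["dominance"]).strip().lower())
        except ValueError:
            raise ValueError(
                f"line {line}: unknown dominance {row['dominance']!r}; "
                "accepted: right, left, balanced"
            ) from None
        try:
            seg = CoronarySegment.parse(str(row["segment"]))
        except KeyError as exc:
            raise ValueError(f"line {line}: {exc.args[0]}") from None
        pct = _parse_stenosis(str(row["stenosis_pct"]), line)
        comp = _parse_composition(str(row["composition"]), line)

        if pid in dominance and dominance[pid] is not dom:
            raise ValueError(
                f"patient {pid!r} has conflicting dominance entries "
                f"({dominance[pid].value} vs {dom.value})"
            )
        if pid not in dominance:
            dominance[pid] = dom
            order.append(pid)
        bucket = lesions.setdefault(pid, {})
        new = SegmentLesion(seg, pct, comp)
        if seg in bucket:
            old = bucket[seg]
            merged = SegmentLesion(
                seg,
                max(old.stenosis_pct, new.stenosis_pct),
                max(
                    old.composition, new.composition,
                    key=_COMPOSITION_SEVERITY.__getitem__,
                ),
            )
            warnings.warn(
                f"patient {pid!r}: multiple lesion rows on "
                f"{seg.display_name!r} collapsed to maximal stenosis "
                f"{merged.stenosis_pct} and composition {merged.composition.value}",
                stacklevel=2,
            )
            bucket[seg] = merged
        else:
            bucket[seg] = new

    return [
        PatientCCTA(pid, dominance[pid], tuple(lesions.get(pid, {}).values()))
        for pid in order
    ]


def write_lesion_table(patients: Iterable[PatientCCTA], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "dominance": p.dominance.value,
            "segment": l.segment.value,
            "stenosis_pct": l.stenosis_pct,
            "composition": l.composition.value,
        }
        for p in patients
        for l in p.lesions
    ]
    pd.DataFrame(rows, columns=LESION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


_BOOL_FIELDS = {
    f.name
    for f in dataclasses.fields(ClinicalRecord)
    if f.type in ("bool", bool)
}
_OPTIONAL_FLOAT_FIELDS = {
    f.name
    for f in dataclasses.fields(ClinicalRecord)
    if "float" in str(f.type) and f.name not in ("age",)
}


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical covariate CSV (one row per patient)."""
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"patient_id": str(row["patient_id"]), "age": float(row["age"]),
                        "sex": str(row["sex"]).strip().lower()}
        for name in _BOOL_FIELDS:
            if name in df.columns and not pd.isna(row[name]):
                v = row[name]
                kwargs[name] = bool(v) if not isinstance(v, str) else v.strip().lower() in ("1", "true", "yes")
        for name in _OPTIONAL_FLOAT_FIELDS:
            if name in df.columns and not pd.isna(row[name]):
                kwargs[name] = float(row[name])
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False, float_format="%.17g")


def write_cohort(cohort: CohortTable, lesion_path: str | Path, clinical_path: str | Path) -> None:
    """Write a cohort as a lesion table and a clinical table (+group column)."""
    write_lesion_table([m.ccta for m in cohort], lesion_path)
    df = pd.DataFrame(
        [{**dataclasses.asdict(m.record), "group": m.group} for m in cohort]
    )
    df.to_csv(clinical_path, index=False, float_format="%.17g")


def read_cohort(lesion_path: str | Path, clinical_path: str | Path) -> CohortTable:
    """Read a cohort back from the two tables written by :func:`write_cohort`."""
    patients = {p.patient_id: p for p in read_lesion_table(lesion_path)}
    df = pd.read_csv(clinical_path)
    groups = {str(r["patient_id"]): str(r["group"]) for _, r in df.iterrows()}
    records = read_clinical_table(clinical_path)
    members = []
    for rec in records:
        ccta = patients.get(
            rec.patient_id,
            PatientCCTA(rec.patient_id, Dominance.RIGHT, ()),
        )
        members.append(CohortMember(rec, ccta, groups[rec.patient_id]))
    return CohortTable(members)


def write_score_table(panels: Iterable[ScorePanel], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "sis": p.sis,
            "sss": p.sss,
            "sc": p.sc,
            "spp": p.spp_positive,
            "ct_lesc": p.ct_lesc,
            "has_obstructive": p.has_obstructive,
        }
        for p in panels
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "sis", "sss", "sc", "spp", "ct_lesc", "has_obstructive"],
    ).to_csv(path, index=False)


def worked_example_path() -> Path:
    """Path to the packaged six-lesion worked-example lesion table."""
    with resources.as_file(
        resources.files("coroscore.data").joinpath("worked_example_lesions.csv")
    ) as p:
        return Path(p)


def load_worked_example() -> PatientCCTA:
    """The packaged worked-example patient (right dominance, six mild lesions)."""
    (patient,) = read_lesion_table(worked_example_path())
    return patient
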