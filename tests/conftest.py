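import csv
from importlib import resources

import numpy as np
import pytest

from coroscore import (
    CoronarySegment,
    Dominance,
    PatientCCTA,
    PlaqueComposition,
    SegmentLesion,
    applicable_segments,
    load_worked_example,
)


@pytest.fixture(scope="session")
def worked_example() -> PatientCCTA:
    """The packaged six-lesion worked-example patient (right dominance)."""
    return load_worked_example()


def read_raw_weight_table() -> dict[tuple[str, str], float | None]:
    """Independent read of the packaged weight CSV (no coroscore parsing)."""
    table: dict[tuple[str, str], float | None] = {}
    path = resources.files("coroscore.data").joinpath("ct_lesc_weights.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            for dom in ("right", "left", "balanced"):
                cell = row[dom].strip()
                table[(row["segment"], dom)] = None if cell == "na" else float(cell)
    return table


def oracle_ct_lesc(patient: PatientCCTA) -> float:
    """Brute-force CT-LeSc recomputation straight from the packaged table.

    Independent of coroscore.scoring: applies the three factor definitions
    (localization weight, calcified 1.0 vs other 1.5, obstructive 1.0 vs
    0.615) lesion by lesion.
    """
    weights = read_raw_weight_table()
    total = 0.0
    for lesion in patient.lesions:
        w = weights[(lesion.segment.value, patient.dominance.value)]
        assert w is not None
        comp = 1.0 if lesion.composition.value == "calcified" else 1.5
        sten = 1.0 if lesion.stenosis_pct >= 50.0 else 0.615
        total += w * comp * sten
    return total


def random_patient(rng: np.random.Generator, lesion_prob: float = 0.35) -> PatientCCTA:
    """Random valid patient: lesions drawn only on applicable segments."""
    dominance = [Dominance.RIGHT, Dominance.LEFT, Dominance.BALANCED][
        rng.integers(0, 3)
    ]
    comps = list(PlaqueComposition)
    lesions = []
    for seg in sorted(applicable_segments(dominance), key=lambda s: s.value):
        if rng.random() < lesion_prob:
            lesions.append(
                SegmentLesion(
                    seg,
                    float(rng.uniform(0, 100)),
                    comps[rng.integers(0, 3)],
                )
            )
    return PatientCCTA("rnd", dominance, tuple(lesions))
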