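"""Cohort-level screening analysis as a Model / Results pair.

:class:`CCTAScreeningAnalysis` is built from a cohort (clinical records
paired with CCTA lesion annotations, plus group labels); ``fit()`` scores
every patient, stratifies the diabetic arm into UKPDS risk tiers, runs the
group-comparison battery (Kruskal–Wallis with Bonferroni post-hoc on the
continuous scores, χ² on the severe-proximal-plaque ratio, group-indicator
logistic odds ratios on the dichotomized findings) and returns a
:class:`ScreeningResults` carrying the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .clinical import stratify_record
from .cohort import CohortTable
from .io import RunConfig, read_cohort
from .scoring import ScorePanel, score_patient
from .stats import (
    ComparisonResult,
    OddsResult,
    compare_categorical,
    compare_multi,
    compare_two,
    dichotomize_panel,
    logistic_or,
    summarize_variable,
    tabulate_lesions,
)

__all__ = ["CCTAScreeningAnalysis", "ScreeningResults"]

CONTINUOUS_SCORES = ("sis", "sss", "sc", "ct_lesc")
OUTCOMES = ("sis_gt", "sss_gt", "ct_lesc_gt", "obstructive")


@dataclass
class ScreeningResults:
    """Fitted screening-analysis results."""

    score_table: pd.DataFrame
    group_order: tuple[str, ...]
    reference_group: str
    descriptives: dict[str, dict[str, dict]]
    omnibus: dict[str, ComparisonResult]
    posthoc: dict[str, list[ComparisonResult]]
    spp_test: ComparisonResult
    odds_ratios: dict[str, list[OddsResult]]
    lesion_table: pd.DataFrame
    config: RunConfig

    def posthoc_frame(self) -> pd.DataFrame:
        rows = []
        for score, comps in self.posthoc.items():
            for c in comps:
                rows.append(
                    {
                        "score": score,
                        "groups": " vs ".join(c.groups),
                        "test": c.test,
                        "statistic": c.statistic,
                        "p_adjusted": c.p_value,
                    }
                )
        return pd.DataFrame(rows)

    def odds_frame(self) -> pd.DataFrame:
        rows = []
        for outcome, ors in self.odds_ratios.items():
            for r in ors:
                rows.append(
                    {
                        "outcome": outcome,
                        "group": r.group,
                        "odds_ratio": r.odds_ratio,
                        "ci_lower": r.ci_lower,
                        "ci_upper": r.ci_upper,
                        "p_value": r.p_value,
                        "separated": r.separated,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted comparison battery."""
        alpha = self.config.significance_level
        lines = ["CCTA plaque-burden screening analysis", "=" * 42]
        counts = self.score_table["group"].value_counts()
        lines.append(
            "Groups: "
            + ", ".join(f"{g} (n={counts.get(g, 0)})" for g in self.group_order)
        )
        lines.append(f"Reference group: {self.reference_group}")
        lines.append("")
        lines.append("Score medians (Q1, Q3) by group and omnibus Kruskal-Wallis:")
        for score in CONTINUOUS_SCORES:
            cells = []
            for g in self.group_order:
                d = self.descriptives[score][g]
                cells.append(f"{g} {d['median']:.2f} ({d['q1']:.2f}, {d['q3']:.2f})")
            omni = self.omnibus[score]
            star = "*" if omni.p_value < alpha else ""
            lines.append(
                f"  {score.upper():8s} " + " | ".join(cells)
                + f"  H={omni.statistic:.3f} p={omni.p_value:.4g}{star}"
            )
        d = self.descriptives["spp"]
        cells = [
            f"{g} {d[g]['count']}/{d[g]['n']} ({d[g]['percent']:.1f}%)"
            for g in self.group_order
        ]
        star = "*" if self.spp_test.p_value < alpha else ""
        lines.append(
            "  SPP+     " + " | ".join(cells)
            + f"  chi2={self.spp_test.statistic:.3f} p={self.spp_test.p_value:.4g}{star}"
        )
        lines.append("")
        lines.append(
            f"Odds ratios vs {self.reference_group} (binary logistic, Wald 95% CI):"
        )
        for outcome, ors in self.odds_ratios.items():
            for r in ors:
                if r.separated:
                    lines.append(
                        f"  {outcome:12s} {r.group:10s} separated (infinite MLE)"
                    )
                else:
                    star = "*" if r.p_value < alpha else ""
                    lines.append(
                        f"  {outcome:12s} {r.group:10s} OR={r.odds_ratio:.3f} "
                        f"({r.ci_lower:.3f}-{r.ci_upper:.3f}) p={r.p_value:.4g}{star}"
                    )
        return "\n".join(lines)


class CCTAScreeningAnalysis:
    """Screening-cohort comparison model.

    Parameters
    ----------
    cohort
        Clinical + CCTA cohort with group labels. Members whose label is
        empty are assigned ``control`` if non-diabetic, otherwise their
        UKPDS risk tier.
    config
        Pipeline configuration (grade boundaries, dichotomization
        thresholds, tier bounds, rounding and percentile rules).
    reference_group
        Reference level for the logistic odds ratios.
    """

    def __init__(
        self,
        cohort: CohortTable,
        config: RunConfig | None = None,
        reference_group: str = "control",
    ):
        self.cohort = cohort
        self.config = config or RunConfig()
        self.reference_group = reference_group

    @classmethod
    def from_cohort(cls, cohort: CohortTable, **kwargs) -> "CCTAScreeningAnalysis":
        return cls(cohort, **kwargs)

    @classmethod
    def from_tables(
        cls,
        lesion_path: str | Path,
        clinical_path: str | Path,
        **kwargs,
    ) -> "CCTAScreeningAnalysis":
        return cls(read_cohort(lesion_path, clinical_path), **kwargs)

    def _group_of(self, member) -> str:
        if member.group:
            return member.group
        if not member.record.dm_status:
            return "control"
        return stratify_record(member.record, self.config.tier_bounds).value

    def fit(self) -> ScreeningResults:
        cfg = self.config
        rows = []
        panels: dict[str, ScorePanel] = {}
        groups: dict[str, str] = {}
        for m in self.cohort:
            panel = score_patient(
                m.ccta, rounding_mode=cfg.rounding_mode, boundaries=cfg.boundaries
            )
            g = self._group_of(m)
            panels[m.ccta.patient_id] = panel
            groups[m.ccta.patient_id] = g
            flags = dichotomize_panel(panel, cfg.thresholds)
            rows.append(
                {
                    "patient_id": m.ccta.patient_id,
                    "group": g,
                    "sis": panel.sis,
                    "sss": panel.sss,
                    "sc": panel.sc,
                    "spp": panel.spp_positive,
                    "ct_lesc": panel.ct_lesc,
                    "has_obstructive": panel.has_obstructive,
                    **flags,
                }
            )
        table = pd.DataFrame(rows)
        order = tuple(
            g for g in ("control", "low", "moderate", "high") if g in set(table["group"])
        ) or tuple(dict.fromkeys(table["group"]))
        extra = tuple(g for g in dict.fromkeys(table["group"]) if g not in order)
        order = order + extra
        if len(order) < 2:
            raise ValueError("cohort comparison requires at least two groups")

        descriptives: dict[str, dict[str, dict]] = {}
        omnibus: dict[str, ComparisonResult] = {}
        posthoc: dict[str, list[ComparisonResult]] = {}
        by_group = {g: table[table["group"] == g] for g in order}
        for score in CONTINUOUS_SCORES:
            descriptives[score] = {
                g: summarize_variable(
                    by_group[g][score].to_numpy(), "nonnormal",
                    percentile_method=cfg.percentile_method,
                )
                for g in order
            }
            comps = compare_multi(
                {g: by_group[g][score].to_numpy() for g in order}, posthoc=True
            )
            omnibus[score] = comps[0]
            posthoc[score] = comps[1:]
        descriptives["spp"] = {
            g: summarize_variable(by_group[g]["spp"].to_numpy(), "categorical")
            for g in order
        }
        spp_counts = [
            [int(by_group[g]["spp"].sum()), int((~by_group[g]["spp"]).sum())]
            for g in order
        ]
        spp_test = compare_categorical(list(map(list, zip(*spp_counts))))

        odds: dict[str, list[OddsResult]] = {}
        for outcome in OUTCOMES:
            y = table[outcome].to_numpy()
            if y.min() == y.max():
                odds[outcome] = []
                continue
            odds[outcome] = logistic_or(
                y, table["group"].to_numpy(), reference=self.reference_group
            )

        lesion_table = tabulate_lesions(
            {
                g: [m.ccta for m in self.cohort if groups[m.ccta.patient_id] == g]
                for g in order
            }
        )
        return ScreeningResults(
            score_table=table,
            group_order=order,
            reference_group=self.reference_group,
            descriptives=descriptives,
            omnibus=omnibus,
            posthoc=posthoc,
            spp_test=spp_test,
            odds_ratios=odds,
            lesion_table=lesion_table,
            config=cfg,
        )
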