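"""Cohort comparison statistics.

Implements the statistical battery used to compare plaque-burden scores
across the control group and the diabetic risk tiers: descriptive
summaries, two-group Mann–Whitney U (exact by full enumeration at small
n, normal approximation with tie correction otherwise), Kruskal–Wallis
with Bonferroni-adjusted pairwise post-hoc tests, Pearson χ² for
categorical tables, score dichotomization (SIS > 3, SSS > 5,
CT-LeSc > 8.7, obstructive stenosis) and group-indicator binary logistic
regression odds ratios with Wald confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

from .scoring import ScorePanel
from .segments import (
    CoronarySegment,
    PatientCCTA,
    PlaqueComposition,
)
from .scoring import is_obstructive

__all__ = [
    "ComparisonResult",
    "OddsResult",
    "DichotomizationThresholds",
    "summarize_variable",
    "compare_two",
    "compare_multi",
    "compare_categorical",
    "dichotomize_panel",
    "logistic_or",
    "tabulate_lesions",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis-test result."""

    test: str
    statistic: float
    p_value: float
    adjusted: bool = False
    groups: tuple[str, ...] = ()
    note: str = ""
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class OddsResult:
    """Odds ratio from a binary logistic fit with Wald 95% CI."""

    group: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    separated: bool = False


@dataclass(frozen=True)
class DichotomizationThresholds:
    """Strict cut points turning the score panel into binary outcomes."""

    sis: float = 3.0
    sss: float = 5.0
    ct_lesc: float = 8.7

    def __post_init__(self) -> None:
        if min(self.sis, self.sss, self.ct_lesc) <= 0:
            raise ValueError("dichotomization thresholds must be positive")


DEFAULT_THRESHOLDS = DichotomizationThresholds()


def summarize_variable(
    values: Sequence,
    kind: str,
    percentile_method: str = "linear",
) -> dict:
    """Descriptive summary of one variable.

    ``kind``: ``normal`` → mean ± SD (ddof 1); ``nonnormal`` → median with
    25th/75th percentiles; ``categorical`` → count and percent of truthy
    values. The percentile rule defaults to linear interpolation between
    closest ranks and is selectable via any numpy quantile method.
    """
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty variable")
    if kind == "normal":
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return {"kind": kind, "n": arr.size, "mean": float(np.mean(arr)), "sd": sd}
    if kind == "nonnormal":
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method=percentile_method)
        return {
            "kind": kind,
            "n": arr.size,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    if kind == "categorical":
        n_pos = int(np.count_nonzero(arr))
        return {
            "kind": kind,
            "n": arr.size,
            "count": n_pos,
            "percent": 100.0 * n_pos / arr.size,
        }
    raise ValueError(f"unknown summary kind {kind!r}")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by full enumeration with midranks.

    Enumerates every assignment of the pooled midranks to the first group
    and computes P(|U − n1·n2/2| ≥ |U_obs − n1·n2/2|). Valid with ties
    because midranks keep the null distribution symmetric about n1·n2/2.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    dev_obs = abs(u_obs - center)
    total = 0
    extreme = 0
    idx = range(n1 + n2)
    for combo in itertools.combinations(idx, n1):
        u = float(np.sum(ranks[list(combo)])) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def compare_two(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 10,
    groups: tuple[str, str] = ("group1", "group2"),
    use_continuity: bool = True,
) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    Exact p by full enumeration (tie-safe, midranks) when the combined
    sample size is at most ``exact_max_n``; otherwise the tie-corrected
    normal approximation. The continuity correction (on by default) keeps
    the approximation within a few percent of the exact p at small n;
    turn it off to recover the exact algebraic k=2 Kruskal–Wallis
    equivalence H = z².
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= exact_max_n:
        u, p = _exact_mwu(x, y)
        return ComparisonResult(
            test="mann-whitney-exact", statistic=u, p_value=p, groups=groups
        )
    if np.all(x[0] == np.concatenate([x, y])):
        # all pooled values identical: no evidence against the null
        u = x.size * y.size / 2.0
        return ComparisonResult(
            test="mann-whitney", statistic=u, p_value=1.0, groups=groups
        )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic",
        use_continuity=use_continuity,
    )
    return ComparisonResult(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=groups,
    )


def compare_multi(
    groups: Mapping[str, Sequence[float]],
    posthoc: bool = True,
    exact_max_n: int = 10,
) -> list[ComparisonResult]:
    """Kruskal–Wallis omnibus test with optional Bonferroni post-hoc.

    The post-hoc stage runs all k·(k−1)/2 pairwise Mann–Whitney tests and
    multiplies each raw p by that number (capped at 1).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, s in zip(labels, samples):
        if s.size == 0:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        omnibus = ComparisonResult(
            test="kruskal-wallis", statistic=0.0, p_value=1.0,
            groups=tuple(labels), note="all values identical",
        )
    else:
        h, p = sps.kruskal(*samples)
        omnibus = ComparisonResult(
            test="kruskal-wallis", statistic=float(h), p_value=float(p),
            groups=tuple(labels),
        )
    results = [omnibus]
    if posthoc:
        pairs = list(itertools.combinations(range(len(labels)), 2))
        m = len(pairs)
        for i, j in pairs:
            raw = compare_two(
                samples[i], samples[j], exact_max_n=exact_max_n,
                groups=(labels[i], labels[j]),
            )
            results.append(
                ComparisonResult(
                    test=raw.test + "+bonferroni",
                    statistic=raw.statistic,
                    p_value=min(1.0, m * raw.p_value),
                    adjusted=True,
                    groups=(labels[i], labels[j]),
                    note=f"raw_p={raw.p_value:.6g}; m={m}",
                )
            )
    return results


def compare_categorical(table: Sequence[Sequence[float]]) -> ComparisonResult:
    """Pearson χ² test of independence, no continuity correction.

    Emits a warning (rather than switching tests) when any expected cell
    count falls below 5.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("contingency table must be 2-D with non-negative counts")
    if tab.sum() == 0:
        raise ValueError("contingency table has zero total")
    # drop all-zero rows/columns so df reflects observed categories
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if min(tab.shape) < 2:
        return ComparisonResult(
            test="chi-square", statistic=0.0, p_value=1.0,
            note="degenerate table (single non-empty row or column)",
        )
    chi2, p, dof, expected = sps.chi2_contingency(tab, correction=False)
    note = ""
    if np.any(expected < 5):
        note = "expected count < 5 in some cells"
        warnings.warn(
            "chi-square approximation dubious: expected count < 5",
            stacklevel=2,
        )
    return ComparisonResult(
        test="chi-square", statistic=float(chi2), p_value=float(p), note=note,
        df=int(dof),
    )


def dichotomize_panel(
    panel: ScorePanel,
    thresholds: DichotomizationThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, bool]:
    """Binary CCTA findings used as logistic outcomes (strict thresholds)."""
    return {
        "sis_gt": panel.sis > thresholds.sis,
        "sss_gt": panel.sss > thresholds.sss,
        "ct_lesc_gt": panel.ct_lesc > thresholds.ct_lesc,
        "obstructive": panel.has_obstructive,
    }


def logistic_or(
    outcome: Sequence[bool],
    group: Sequence[str],
    reference: str,
) -> list[OddsResult]:
    """Group-indicator binary logistic regression.

    Fits outcome ~ C(group) with the given reference level by maximum
    likelihood and returns, per non-reference group, the exponentiated
    coefficient (odds ratio), its Wald 95% CI and p-value. Complete or
    quasi-complete separation (a group with all-positive or all-negative
    outcomes) is detected up front and flagged instead of reporting a
    meaningless CI.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=object)
    if y.size != g.size or y.size == 0:
        raise ValueError("outcome and group must be equal-length and non-empty")
    levels = [reference] + sorted({str(v) for v in g} - {reference})
    if reference not in set(map(str, g)):
        raise ValueError(f"reference group {reference!r} not present")
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if y.min() == y.max():
        raise ValueError("outcome does not vary")

    separated = {
        lvl: (y[g == lvl].min() == y[g == lvl].max())
        for lvl in levels
    }
    X = np.column_stack(
        [np.ones(y.size)] + [(g == lvl).astype(float) for lvl in levels[1:]]
    )
    results: list[OddsResult] = []
    if separated[reference] or any(separated[l] for l in levels[1:]):
        # MLE is infinite for the affected contrasts; report flags only
        for lvl in levels[1:]:
            flagged = separated[reference] or separated[lvl]
            if not flagged:
                sub = (g == reference) | (g == lvl)
                two = logistic_or(y[sub] > 0.5, g[sub], reference)
                results.append(two[0])
            else:
                results.append(
                    OddsResult(
                        group=lvl, odds_ratio=float("nan"),
                        ci_lower=float("nan"), ci_upper=float("nan"),
                        p_value=float("nan"), separated=True,
                    )
                )
        return results

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    conf = fit.conf_int(alpha=0.05)
    for k, lvl in enumerate(levels[1:], start=1):
        results.append(
            OddsResult(
                group=lvl,
                odds_ratio=float(np.exp(fit.params[k])),
                ci_lower=float(np.exp(conf[k, 0])),
                ci_upper=float(np.exp(conf[k, 1])),
                p_value=float(fit.pvalues[k]),
            )
        )
    return results


def tabulate_lesions(
    patients_by_group: Mapping[str, Iterable[PatientCCTA]],
) -> pd.DataFrame:
    """Per-group stenotic-segment counts with severity and composition margins.

    Returns a tidy frame with one row per (block, row, group) count, the
    same shape as a published segment-distribution table: a ``segment``
    block (counts per segment id), a ``severity`` block (obstructive vs
    non-obstructive) and a ``composition`` block (calcified vs
    non-calcified-or-mixed). Within each group the severity and
    composition blocks each sum to the group's total segment count.
    """
    rows = []
    for gname, patients in patients_by_group.items():
        seg_counts = {seg: 0 for seg in CoronarySegment}
        n_obs = n_nonobs = n_calc = n_noncalc_mixed = 0
        for p in patients:
            for lesion in p.lesions:
                seg_counts[lesion.segment] += 1
                if is_obstructive(lesion.stenosis_pct):
                    n_obs += 1
                else:
                    n_nonobs += 1
                if lesion.composition is PlaqueComposition.CALCIFIED:
                    n_calc += 1
                else:
                    n_noncalc_mixed += 1
        for seg, c in seg_counts.items():
            rows.append(("segment", seg.value, gname, c))
        rows.append(("severity", "obstructive", gname, n_obs))
        rows.append(("severity", "non_obstructive", gname, n_nonobs))
        rows.append(("composition", "non_calcified_or_mixed", gname, n_noncalc_mixed))
        rows.append(("composition", "calcified", gname, n_calc))
    return pd.DataFrame(rows, columns=["block", "row", "group", "count"])
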