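"""Morphometry summaries and cohort statistics.

Covers the abnormal-section-length readout (percent of section length
occupied by dysplastic/abnormal intervals), the per-xenograft threshold
classification (at least 12% of section length abnormal, averaged over the
xenograft's sections), and two-sample Mann-Whitney U comparison of cohort
metrics with the conventional significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError
from .geometry import merge_intervals

#: fraction of section length (percent) at or above which a xenograft is
#: categorized as abnormal regeneration
DEFAULT_THRESHOLD_PERCENT = 12.0

VALID_LABELS = ("normal", "abnormal", "roi")

#: p-value cut-points for significance stars
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class RegionAnnotation:
    """Labeled 1-D intervals along a section's axis (micrometres)."""

    section_id: str
    section_length_um: float
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.section_length_um <= 0:
            raise ValidationError("section_length_um: must be positive")
        for a, b, label in self.intervals:
            if label not in VALID_LABELS:
                raise ValidationError(f"intervals: unknown label {label!r}")
            if not (0 <= a < b <= self.section_length_um):
                raise ValidationError(f"intervals: ({a}, {b}) outside [0, {self.section_length_um}]")


@dataclass
class MwuResult:
    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # exact / normal_approx_tie_corrected
    degenerate: bool = False

    @property
    def stars(self) -> str:
        for cut, mark in STAR_LEVELS:
            if self.p_two_sided < cut:
                return mark
        return "NS"


@dataclass
class CohortComparison:
    metric: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    test: MwuResult

    def summary(self) -> str:
        t = self.test
        return (
            f"{self.metric}: {self.group_a} (n={t.n1}, median={self.median_a:.4g}) vs "
            f"{self.group_b} (n={t.n2}, median={self.median_b:.4g}); "
            f"Mann-Whitney U={t.u_statistic:.4g}, p={t.p_two_sided:.4g} [{t.stars}] ({t.method})"
        )


def abnormal_fraction(annotation: RegionAnnotation) -> float:
    """Percent of section length covered by abnormal intervals.

    Overlapping abnormal intervals are merged before summing, so the result
    is invariant under re-ordering and splitting of intervals.
    """
    abnormal = [(a, b) for a, b, label in annotation.intervals if label == "abnormal"]
    merged = merge_intervals(abnormal)
    total = sum(b - a for a, b in merged)
    return 100.0 * total / annotation.section_length_um


def classify_xenograft(
    per_section_fractions: list[float],
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
    summary: str = "mean",
) -> tuple[bool, float]:
    """Categorize a xenograft from its per-section abnormal fractions.

    The summary value (mean by default; ``max`` and ``median`` available)
    is compared against the threshold; the boundary counts as above
    ("at least" semantics).  Returns (above, summary_value).
    """
    if len(per_section_fractions) == 0:
        raise ValidationError("per_section_fractions: need at least one section value")
    funcs = {"mean": np.mean, "max": np.max, "median": np.median}
    if summary not in funcs:
        raise ValidationError(f"summary: {summary!r} not one of {sorted(funcs)}")
    value = float(funcs[summary](per_section_fractions))
    return value >= threshold_percent, value


def mann_whitney_u(a, b, alternative: str = "two-sided") -> MwuResult:
    """Mann-Whitney U test with the method chosen by sample size and ties.

    Exact p by full enumeration of the null distribution when both samples
    have at most 8 observations and the pooled data are tie-free; otherwise
    the normal approximation with tie correction and continuity correction.
    Identical constant samples are degenerate and reported with p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("a/b: both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return MwuResult(
            u_statistic=a.size * b.size / 2.0,
            n1=int(a.size),
            n2=int(b.size),
            p_two_sided=1.0,
            method="normal_approx_tie_corrected",
            degenerate=True,
        )
    if a.size <= 8 and b.size <= 8 and not has_ties:
        res = mannwhitneyu(a, b, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = mannwhitneyu(a, b, alternative=alternative, method="asymptotic", use_continuity=True)
        method = "normal_approx_tie_corrected"
    return MwuResult(
        u_statistic=float(res.statistic),
        n1=int(a.size),
        n2=int(b.size),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=method,
    )


def make_cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a tidy cohort table with columns
    (cohort, xenograft_id, section_id, metric, value); duplicate
    (xenograft, section, metric) keys are rejected."""
    df = pd.DataFrame(rows, columns=["cohort", "xenograft_id", "section_id", "metric", "value"])
    if df.duplicated(subset=["xenograft_id", "section_id", "metric"]).any():
        raise ValidationError("rows: duplicate (xenograft_id, section_id, metric) entries")
    return df


def cohort_compare(
    table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    aggregate_per_xenograft: bool = False,
) -> CohortComparison:
    """Compare one metric between two cohorts with Mann-Whitney U.

    By default the per-section/region values are pooled into cohort dot
    plots; ``aggregate_per_xenograft=True`` first averages within each
    xenograft (the variant that avoids pseudo-replication).
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValidationError(f"metric: no rows for metric {metric!r}")
    if aggregate_per_xenograft:
        sub = sub.groupby(["cohort", "xenograft_id"], as_index=False)["value"].mean()
    va = sub.loc[sub["cohort"] == group_a, "value"].to_numpy(dtype=float)
    vb = sub.loc[sub["cohort"] == group_b, "value"].to_numpy(dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValidationError(f"cohort: group {'' if va.size else group_a}{'' if vb.size else group_b} has no values for {metric!r}")
    test = mann_whitney_u(va, vb)
    return CohortComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        median_a=float(np.median(va)),
        median_b=float(np.median(vb)),
        test=test,
    )
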