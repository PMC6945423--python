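"""Two-group and k-group tests computed from summary statistics.

The clinical tables report only per-stratum n, mean and SD, so every test
here is the summary-statistic form of its full-data counterpart: Welch and
pooled-variance t, one-way ANOVA from level summaries, and a binormal AUC
for single-study discrimination. A full-data test run on any raw sample
whose moments match the summaries reproduces these results exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .study_io import GroupRow, StudySummary


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df1: float
    df2: float | None
    p_value: float
    method: str


def qpcr_relative_expression(cq_target: float, cq_reference: float) -> float:
    """Relative expression of a target normalized to a reference gene.

    Uses the 2^-dCq rule: one extra amplification cycle for the target
    relative to the reference halves the inferred abundance.
    """
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return 2.0 ** (-(cq_target - cq_reference))


def _check_pair(a: GroupRow, b: GroupRow) -> None:
    if a.n < 2 or b.n < 2:
        raise InsufficientDataError("each group needs n >= 2")


def welch_t(a: GroupRow, b: GroupRow) -> TestResult:
    """Unequal-variance two-sample t test from group summaries.

    Degrees of freedom by the Welch-Satterthwaite expression; two-sided p.
    """
    _check_pair(a, b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=t, df1=df, df2=None, p_value=p, method="welch_t")


def pooled_t(a: GroupRow, b: GroupRow) -> TestResult:
    """Student's pooled-variance two-sample t from group summaries."""
    _check_pair(a, b)
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=t, df1=float(df), df2=None, p_value=p,
                      method="pooled_t")


def anova_oneway_from_summary(rows: Sequence[GroupRow]) -> TestResult:
    """One-way fixed-effects ANOVA from per-level n/mean/SD.

    F = MSB/MSW with df1 = k-1, df2 = N-k; identical to a full-data ANOVA
    on any raw sample matching the level moments.
    """
    if len(rows) < 2:
        raise ValueError("ANOVA needs at least two levels")
    levels = [(r.variable, r.level) for r in rows]
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate levels within the variable")
    for r in rows:
        if r.n < 2:
            raise InsufficientDataError(f"level {r.level}: n >= 2 required")
    k = len(rows)
    N = sum(r.n for r in rows)
    grand = sum(r.n * r.mean for r in rows) / N
    ssb = sum(r.n * (r.mean - grand) ** 2 for r in rows)
    ssw = sum((r.n - 1) * r.sd**2 for r in rows)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    f = msb / msw
    p = stats.f.sf(f, k - 1, N - k)
    return TestResult(statistic=f, df1=float(k - 1), df2=float(N - k),
                      p_value=p, method="anova")


def binormal_auc(s: StudySummary) -> float:
    """Single-study AUC under a binormal model for the two arms.

    If case and control values are normal with the summarized means and SDs,
    the probability that a random case exceeds a random control is
    Phi(dmean / sqrt(sd_case^2 + sd_control^2)). Equals 0.5 at no
    separation and is monotone in the mean difference.
    """
    if s.sd_case <= 0 or s.sd_control <= 0:
        raise ValueError("SDs must be strictly positive")
    z = (s.mean_case - s.mean_control) / math.hypot(s.sd_case, s.sd_control)
    return float(stats.norm.cdf(z))
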