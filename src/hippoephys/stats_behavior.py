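"""Behavioral scores and summary-statistic group comparisons.

Group comparisons follow the conventions of the source analyses: unpaired
pooled-variance Student's t (df = n1 + n2 - 2; the pooled form, not
Welch, matching the reported degrees of freedom), Mann-Whitney U with
both orientations reported (published U values do not fix an
orientation), and the two-sample Kolmogorov-Smirnov D. t tests can be
recomputed directly from printed mean/SD/n summaries.

Behavioral scores: the spatial-novelty discrimination ratio
t_novel / (t_novel + t_other) with chance at 0.5, the T-maze alternation
score (fraction of alternating choice runs, chance 0.5), and the analytic
chance level for an m-option task (e.g. 33.3% for the goal arm of a
three-arm water Y-maze).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n >= 2 for variance-based tests")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class TestResult:
    statistic: str  # 't', 'U', 'D'
    value: float
    df: float | None
    p: float
    extra: dict | None = None


def t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Pooled-variance two-sample t from printed mean/SD/n summaries."""
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestResult("t", 0.0, a.n + b.n - 2, 1.0)
        return TestResult("t", float("inf"), a.n + b.n - 2, 0.0)
    t, p = sstats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TestResult("t", float(t), a.n + b.n - 2, float(p))


def mann_whitney(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Mann-Whitney U, both orientations reported.

    The p-value is exact (full enumeration) for n1*n2 <= 400 without
    ties, otherwise by the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(np.concatenate((x, y)) == x[0]):
        # fully tied samples carry no ordering information
        u = len(x) * len(y) / 2.0
        return TestResult("U", u, None, 1.0, extra={"U_x": u, "U_y": u})
    ties = len(np.unique(np.concatenate((x, y)))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_y = len(x) * len(y) - u_x
    return TestResult(
        "U", u_x, None, float(res.pvalue), extra={"U_x": u_x, "U_y": u_y}
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov D with asymptotic p."""
    res = sstats.ks_2samp(x, y, method="asymp")
    return TestResult("D", float(res.statistic), None, float(res.pvalue))


def discrimination_ratio(t_novel_s: float, t_other_s: float) -> float:
    """Time in the novel arm over total time in novel + other arms.

    Chance (no discrimination) is 0.5.
    """
    if t_novel_s < 0 or t_other_s < 0:
        raise ValueError("times must be non-negative")
    total = t_novel_s + t_other_s
    if total == 0:
        raise ValueError("no time spent in either arm")
    return t_novel_s / total


def alternation_score(forced_arms, chosen_arms) -> float:
    """Fraction of choice runs that alternate from the forced arm.

    Scores 1 when the chosen arm differs from the forced arm, 0 when the
    animal returns to it. Chance is 0.5.
    """
    forced = np.asarray(forced_arms)
    chosen = np.asarray(chosen_arms)
    if len(forced) == 0 or len(forced) != len(chosen):
        raise ValueError("need equal-length non-empty forced/choice sequences")
    return float(np.mean(forced != chosen))


def chance_level_percent(n_options: int) -> float:
    """Analytic chance percentage for an n-way choice (3-arm maze: 33.3%)."""
    if n_options < 2:
        raise ValueError("need at least 2 options")
    return 100.0 / n_options


def percent_change(baseline_mean: float, comparison_mean: float) -> float:
    """Percent reduction of comparison relative to baseline."""
    if baseline_mean == 0:
        raise ValueError("baseline mean must be non-zero")
    return 100.0 * (baseline_mean - comparison_mean) / baseline_mean
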