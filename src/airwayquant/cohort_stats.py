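"""Nonparametric cohort statistics: normality, Kruskal-Wallis, Dunn, t-test.

The unit of analysis is the subject: per-image measurements are reduced to a
subject-level median upstream, and the tests here compare those subject-level
values between diagnostic groups (e.g. healthy control, asthma, COPD).

* D'Agostino-Pearson omnibus K^2 assesses normality (skewness and kurtosis
  Z-statistics combined, chi-squared with 2 df).
* The Kruskal-Wallis H test (tie-corrected, chi-squared approximation with
  k - 1 df) is the omnibus comparison across >= 2 groups.
* Dunn's post test compares mean ranks pairwise on the pooled ranking, with
  a Bonferroni family correction over all pairs by default.
* Student's pooled-variance two-sided t-test covers two-group comparisons.

Summaries are medians with interquartile ranges; quartiles use the
linear-interpolation rule so tabulated outputs are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "dagostino_pearson",
    "kruskal_wallis",
    "dunn_posthoc",
    "two_group_t",
    "summarize",
]


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its p-value and optional pairwise table."""

    name: str
    statistic: float
    pvalue: float
    df: float | None = None
    pairwise: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or math.isnan(self.pvalue)):
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")


def _clean(values, name="values") -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def dagostino_pearson(values) -> TestResult:
    """D'Agostino-Pearson omnibus normality test (K^2, chi-squared 2 df).

    Requires n >= 8; the transformed-moment Z approximations behind the
    statistic are unreliable below that.
    """
    arr = _clean(values)
    if arr.size < 8:
        raise ValueError(
            f"D'Agostino-Pearson needs n >= 8 (moment approximations), got n={arr.size}"
        )
    if arr.std(ddof=0) == 0:
        raise ValueError("normality test undefined for a zero-variance sample")
    k2, p = stats.normaltest(arr)
    return TestResult(name="dagostino_pearson", statistic=float(k2), pvalue=float(p), df=2.0)


def _rank_groups(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], int]:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)  # average ranks for ties
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + g.size])
        start += g.size
    return pooled, out, pooled.size


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across k groups.

    H = 12 / (N (N+1)) * sum_j n_j (rbar_j - rbar)^2, corrected by
    1 - sum(t^3 - t) / (N^3 - N) over tie groups; p from chi-squared with
    k - 1 df.
    """
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    total = sum(a.size for a in arrays)
    if total < 3:
        raise ValueError("Kruskal-Wallis needs at least three observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("Kruskal-Wallis undefined: all observations identical")
    h, p = stats.kruskal(*arrays)
    return TestResult(
        name="kruskal_wallis", statistic=float(h), pvalue=float(p), df=float(len(arrays) - 1)
    )


def dunn_posthoc(
    groups,
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise rank comparison after a Kruskal-Wallis omnibus test.

    For groups i, j with mean pooled ranks rbar_i, rbar_j,

        z_ij = (rbar_i - rbar_j)
               / sqrt( (N (N+1) / 12 - T) (1/n_i + 1/n_j) ),

    where ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for ties.  Two-sided
    normal p-values are multiplied by the number of comparisons
    (``adjust="bonferroni"``, capped at 1) or left raw (``adjust="none"``).
    """
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("Dunn's test needs at least two groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels/groups length mismatch")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    pooled, ranked, n_total = _rank_groups(arrays)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = [r.mean() for r in ranked]
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se == 0:
            raise ValueError("Dunn's test undefined: zero rank variance (all values tied)")
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m) if adjust == "bonferroni" else p_raw
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_rank_a": mean_ranks[i],
                "mean_rank_b": mean_ranks[j],
                "z": z,
                "pvalue_raw": p_raw,
                "pvalue_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows)


def two_group_t(values_a, values_b) -> TestResult:
    """Pooled-variance two-sided Student's t-test, df = n_a + n_b - 2."""
    a, b = _clean(values_a, "values_a"), _clean(values_b, "values_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least two observations per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise ValueError("t-test undefined: zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        name="student_t", statistic=float(t), pvalue=float(p), df=float(a.size + b.size - 2)
    )


def summarize(values) -> tuple[float, tuple[float, float]]:
    """Median and (Q1, Q3) with linear-interpolation quartiles."""
    arr = _clean(values)
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(med), (float(q1), float(q3))
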