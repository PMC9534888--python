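"""Two-group comparison statistics for cohort result tables.

Continuous metrics are summarized as mean ± SD and median [IQR] with a
normal-approximation 95% CI, annotated with a Shapiro–Wilk normality check,
and compared with a two-sample rank test.  The rank test uses exact
enumeration of the rank-sum null distribution (with midranks for ties) for
small samples, switching to the tie-corrected normal approximation for
combined n > 20.  Proportions (e.g. patients off-center by more than 20 mm)
are compared with the uncorrected Pearson chi-square on the 2x2 table, and
agreement between two continuous measurements with the Pearson correlation.

A signed-rank test for *paired* data is also exposed
(:func:`signed_rank_test`); the between-group default is the unpaired
rank-sum test, since the two positioning groups contain different patients.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize",
    "rank_test",
    "signed_rank_test",
    "chi2_2x2",
    "pearson_r2",
    "normality_check",
    "compare_groups",
]

_EXACT_MAX_N = 20


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float
    normality_p: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "iqr": [self.q1, self.q3],
            "ci95": [self.ci_low, self.ci_high],
            "normality_p": self.normality_p,
        }


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    group_a: str
    group_b: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    test_name: str
    test_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "groups": [self.group_a, self.group_b],
            self.group_a: self.summary_a.to_dict(),
            self.group_b: self.summary_b.to_dict(),
            "test": self.test_name,
            "statistic": self.test_statistic,
            "p_value": self.p_value,
        }


def summarize(values: Sequence[float], with_normality: bool = False) -> GroupSummary:
    """Mean ± SD, median [IQR] and normal-approximation 95% CI.

    Quartiles use linear interpolation; the CI is mean ± 1.96·SD/√n.
    Requires n ≥ 2.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError(f"need at least 2 values to summarize, got {n}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    half = 1.96 * sd / math.sqrt(n)
    norm_p: Optional[float] = None
    if with_normality and 3 <= n <= 5000 and sd > 0:
        norm_p = normality_check(arr)
    return GroupSummary(n, mean, sd, med, q1, q3, mean - half, mean + half, norm_p)


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided p by full enumeration of rank assignments.

    Enumerates all C(n, n_a) ways the first group's ranks could fall and
    counts assignments whose rank sum deviates from the null mean at least
    as much as observed.  Midranks make this valid under ties.
    """
    n = ranks.size
    expected = n_a * (n + 1) / 2.0
    dev = abs(w_obs - expected) - 1e-9
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - expected) >= dev:
            count += 1
    return count / total


def rank_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sample rank-sum (Mann–Whitney/Wilcoxon) test, two-sided.

    Returns ``(W, p)`` where W is the rank sum of the first group.  With
    ``method='auto'`` the null distribution is enumerated exactly for
    combined n ≤ 20 (midranks under ties; identical samples give p = 1) and
    approximated normally with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n_a].sum())

    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "asymptotic"
    if method == "exact":
        return w, _exact_ranksum_p(ranks, n_a, w)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    expected = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return w, 1.0
    z = (w - expected) / math.sqrt(var)
    return w, float(2.0 * sps.norm.sf(abs(z)))


def signed_rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test for *paired* samples (two-sided).

    Provided for completeness; between-group comparisons of independent
    cohorts should use :func:`rank_test`.
    """
    res = sps.wilcoxon(np.asarray(values_a, float), np.asarray(values_b, float))
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Table layout ``[[a, b], [c, d]]`` (rows = groups, columns = outcome).
    chi2 = n(ad - bc)^2 / (r1 r2 c1 c2), p from chi-square with 1 df.
    Raises if any margin is zero (statistic undefined).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, r^2, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def normality_check(values: Sequence[float]) -> float:
    """Shapiro–Wilk p-value (annotation only; 3 ≤ n ≤ 5000)."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {arr.size}")
    if arr.std() == 0:
        raise ValueError("normality test undefined for a constant vector")
    return float(sps.shapiro(arr).pvalue)


def compare_groups(
    df,
    metrics: Sequence[str],
    group_col: str = "group",
    group_a: Optional[str] = None,
    group_b: Optional[str] = None,
) -> list[GroupComparison]:
    """Rank-test every metric column between two groups of a results table.

    ``df`` is a pandas DataFrame with one row per patient.  Rows with NaN
    in a metric are dropped for that metric.  Groups with fewer than two
    valid values are reported with NaN statistics ("insufficient n").
    """
    labels = list(dict.fromkeys(df[group_col]))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, found {labels}")
        group_a, group_b = labels
    out: list[GroupComparison] = []
    for metric in metrics:
        va = df.loc[df[group_col] == group_a, metric].dropna().to_numpy(dtype=float)
        vb = df.loc[df[group_col] == group_b, metric].dropna().to_numpy(dtype=float)
        if va.size < 2 or vb.size < 2:
            nan_sum = GroupSummary(
                n=int(min(va.size, vb.size)),
                mean=float("nan"), sd=float("nan"), median=float("nan"),
                q1=float("nan"), q3=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"),
            )
            out.append(
                GroupComparison(
                    metric_name=metric,
                    group_a=group_a, group_b=group_b,
                    summary_a=summarize(va, with_normality=True) if va.size >= 2 else nan_sum,
                    summary_b=summarize(vb, with_normality=True) if vb.size >= 2 else nan_sum,
                    test_name="insufficient n",
                    test_statistic=float("nan"),
                    p_value=float("nan"),
                )
            )
            continue
        w, p = rank_test(va, vb)
        out.append(
            GroupComparison(
                metric_name=metric,
                group_a=group_a, group_b=group_b,
                summary_a=summarize(va, with_normality=True),
                summary_b=summarize(vb, with_normality=True),
                test_name="rank-sum (exact)" if va.size + vb.size <= _EXACT_MAX_N else "rank-sum (normal approx.)",
                test_statistic=w,
                p_value=p,
            )
        )
    return out
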