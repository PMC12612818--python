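"""Condition-comparison statistics: Kruskal–Wallis, unpaired t, fold change.

Thin, edge-case-hardened wrappers over scipy.stats, returning a uniform
:class:`ComparisonResult`.  Degenerate inputs that a plotting-oriented
workflow routinely produces (all values identical, zero variance) are given
their limiting values instead of errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    df: float
    group_sizes: tuple[int, ...]
    group_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")


def kruskal_wallis(*groups: Sequence[float],
                   labels: Sequence[str] = ()) -> ComparisonResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p on k - 1 df.

    All values identical across groups is a well-defined no-signal case:
    H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValueError("need at least 3 values in total")
    k = len(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return ComparisonResult(test_name="kruskal_wallis", statistic=float(h),
                            p_value=float(p), df=float(k - 1),
                            group_sizes=tuple(len(a) for a in arrays),
                            group_labels=tuple(labels))


def unpaired_t(group_a: Sequence[float], group_b: Sequence[float],
               welch: bool = False,
               labels: Sequence[str] = ()) -> ComparisonResult:
    """Two-sided unpaired t-test; Student's pooled-variance form by default.

    Zero pooled variance is handled by its limits: equal means give t = 0,
    p = 1; unequal means give |t| -> inf, p -> 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("unpaired_t needs n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        equal = a.mean() == b.mean()
        t = 0.0 if equal else math.copysign(math.inf, a.mean() - b.mean())
        p = 1.0 if equal else 0.0
        df = len(a) + len(b) - 2.0
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return ComparisonResult(test_name="welch_t" if welch else "student_t",
                            statistic=t, p_value=p, df=df,
                            group_sizes=(len(a), len(b)),
                            group_labels=tuple(labels))


def fold_change(mean_a: float, mean_b: float) -> float:
    """mean_a / mean_b; the denominator must be strictly positive."""
    if mean_b <= 0:
        raise ValueError("fold_change denominator must be > 0")
    return float(mean_a) / float(mean_b)
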