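"""ROUT outlier trimming for univariate samples.

Robust regression and OUTlier removal (Motulsky & Brown), specialized to
the constant model, which is what trimming a metric distribution amounts
to:

1. Fit the location c robustly by minimizing the Lorentzian merit
   sum(log(1 + (r_i/RSDR)^2)), initialized at the median, alternating with
   re-estimation of the scale.
2. RSDR (robust standard deviation of residuals) = 68.27th percentile of
   |residuals| times n/(n - K), with K = 1 fitted parameter.
3. Rank |residuals| ascending; among the ~30% most extreme points, scan
   from the least extreme upward and flag point i (and everything more
   extreme) when its two-tailed t probability of r_i/RSDR on n - K df
   falls below alpha_i = Q(n - i + 1)/n — the Benjamini–Hochberg schedule
   at maximum desired false-discovery rate Q.

Trimming is two-sided: a residual is a residual regardless of sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class RoutResult:
    kept: np.ndarray
    outliers: np.ndarray
    outlier_indices: np.ndarray   # indices into the input sample
    q: float
    robust_center: float
    rsdr: float
    n: int


def _rsdr(residuals: np.ndarray, n_params: int = 1) -> float:
    n = len(residuals)
    if n <= n_params:
        return 0.0
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / (n - n_params)


def robust_location(values: np.ndarray, max_iter: int = 50,
                    tol: float = 1e-10) -> tuple[float, float]:
    """Constant-model robust fit: (center, RSDR) minimizing the Lorentzian merit."""
    values = np.asarray(values, dtype=float)
    c = float(np.median(values))
    s = _rsdr(values - c)
    if s == 0:
        return c, 0.0
    span = np.ptp(values)
    for _ in range(max_iter):
        res = optimize.minimize_scalar(
            lambda m: np.log1p(((values - m) / s) ** 2).sum(),
            bounds=(values.min() - span, values.max() + span), method="bounded",
            options={"xatol": tol * max(1.0, abs(c))})
        c_new = float(res.x)
        s_new = _rsdr(values - c_new)
        if s_new == 0:
            return c_new, 0.0
        if abs(c_new - c) <= tol * max(1.0, abs(c)) and abs(s_new - s) <= tol * s:
            c, s = c_new, s_new
            break
        c, s = c_new, s_new
    return c, s


def rout_trim(sample, q: float = 0.01) -> RoutResult:
    """Partition a univariate sample into kept values and flagged outliers.

    Samples with fewer than 10 values are returned unchanged with a warning
    (too few points for meaningful FDR-controlled detection).  Q is the
    maximum desired false-discovery rate; the method's recommended default
    is 0.01.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    values = np.asarray(sample, dtype=float)
    if values.ndim != 1:
        raise ValueError("sample must be one-dimensional")
    n = len(values)
    if n < 10:
        warnings.warn(f"n = {n} < 10: sample returned untrimmed", stacklevel=2)
        center = float(np.median(values)) if n else float("nan")
        return RoutResult(kept=values.copy(), outliers=np.array([]),
                          outlier_indices=np.array([], dtype=int),
                          q=q, robust_center=center, rsdr=0.0, n=n)

    center, rsdr = robust_location(values)
    resid = values - center
    order = np.argsort(np.abs(resid), kind="stable")  # ascending |residual|
    abs_sorted = np.abs(resid)[order]

    first_candidate = int(np.floor(0.7 * n))  # 0-based rank of first candidate
    flagged_from: int | None = None
    for i0 in range(first_candidate, n):
        rank = i0 + 1
        alpha = q * (n - rank + 1) / n
        if rsdr > 0:
            t = abs_sorted[i0] / rsdr
            p = 2.0 * stats.t.sf(t, df=n - 1)
        else:
            p = 0.0 if abs_sorted[i0] > 0 else 1.0
        if p < alpha:
            flagged_from = i0
            break

    if flagged_from is None:
        out_idx = np.array([], dtype=int)
    else:
        out_idx = np.sort(order[flagged_from:])
    mask = np.zeros(n, dtype=bool)
    mask[out_idx] = True
    return RoutResult(kept=values[~mask], outliers=values[mask],
                      outlier_indices=out_idx, q=q,
                      robust_center=center, rsdr=rsdr, n=n)
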