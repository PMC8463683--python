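"""Group-level nonparametric and correlation tests.

These are deliberately self-contained (exact Wilcoxon null by subset-sum
dynamic programming, t-based correlation p) so that statistic-only entry
points -- recomputing a p-value from a printed (V, n) or (r, n) pair -- are
supported, which library interfaces working from raw samples do not allow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestResult", "wilcoxon_signed_rank", "pearson_correlation_test"]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: int | None = None
    tails: int = 2
    flags: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _signed_rank_statistic(values: np.ndarray) -> tuple[float, int, bool, bool]:
    v = np.asarray(values, dtype=float)
    has_zeros = bool(np.any(v == 0))
    v = v[v != 0]
    n = v.size
    absv = np.abs(v)
    has_ties = bool(np.unique(absv).size < n)
    ranks = stats.rankdata(absv)
    vstat = float(ranks[v > 0].sum())
    return vstat, n, has_zeros, has_ties


def _exact_null_counts(n: int) -> np.ndarray:
    """Counts of signed-rank sums 0..n(n+1)/2 over all 2^n sign patterns."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r]
    return counts


def wilcoxon_signed_rank(
    values=None,
    V: float | None = None,
    n: int | None = None,
    method: str = "exact",
    tails: int = 2,
) -> TestResult:
    """One-sample Wilcoxon signed-rank test.

    Entry either with raw ``values`` (differences from the null location) or
    with a precomputed statistic ``(V, n)``.  ``method='exact'`` enumerates
    the full null distribution of V by dynamic programming over ranks 1..n
    and doubles the smaller tail (capped at 1); ``method='normal-cc'`` uses
    the continuity-corrected Gaussian approximation.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    flags = ""
    if values is not None:
        vstat, n, has_zeros, has_ties = _signed_rank_statistic(values)
        if method == "exact" and (has_zeros or has_ties):
            raise ValueError(
                "exact method requires no zeros and no tied absolute values; "
                "use method='normal-cc'"
            )
    else:
        if V is None or n is None:
            raise ValueError("provide either values or both V and n")
        vstat = float(V)
    if n is None or n < 1:
        raise ValueError("need n >= 1 nonzero values")
    total = n * (n + 1) / 2
    if not 0 <= vstat <= total:
        raise ValueError(f"V must lie in [0, {total}]")

    if method == "exact":
        counts = _exact_null_counts(n)
        denom = 2.0**n
        upper = counts[int(round(vstat)) :].sum() / denom
        lower = counts[: int(round(vstat)) + 1].sum() / denom
        if tails == 2:
            p = min(1.0, 2.0 * min(upper, lower))
        else:
            p = min(upper, lower)
        tag = "wilcoxon-exact"
    elif method == "normal-cc":
        mu = total / 2.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        # continuity correction shrinks |V - mu| by 0.5
        z = (vstat - mu - 0.5 * np.sign(vstat - mu)) / sd
        p = (2.0 if tails == 2 else 1.0) * stats.norm.sf(abs(z))
        p = min(1.0, p)
        tag = "wilcoxon-normal-cc"
    else:
        raise ValueError("method must be 'exact' or 'normal-cc'")
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=vstat,
        p_value=float(p),
        method=tag,
        n=int(n),
        tails=tails,
        flags=flags,
    )


def pearson_correlation_test(
    x=None, y=None, r: float | None = None, n: int | None = None
) -> TestResult:
    """Two-sided Pearson correlation test via the t transform.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` with n-2 degrees of freedom.  Accepts
    raw samples or a printed (r, n) pair.
    """
    flags = ""
    if r is None:
        if x is None or y is None:
            raise ValueError("provide either (x, y) or (r, n)")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        n = x.size
        if n < 3:
            raise ValueError("need n >= 3")
        r = float(np.corrcoef(x, y)[0, 1])
    if n is None or n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return TestResult(
            name="pearson_correlation",
            statistic=float(r),
            p_value=0.0,
            method="pearson-t",
            df=n - 2,
            n=int(n),
            flags="degenerate |r| = 1",
        )
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TestResult(
        name="pearson_correlation",
        statistic=float(r),
        p_value=float(min(1.0, p)),
        method="pearson-t",
        df=n - 2,
        n=int(n),
        flags=flags,
    )
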