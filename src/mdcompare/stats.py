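"""Exact small-sample statistics for replicate-level comparisons.

Molecular-dynamics studies commonly summarise each simulated state by a
handful of independent replicate values (here five binding-free-energy
means per state) and compare states with a one-tailed Mann-Whitney U
test.  At n1 = n2 = 5 the normal approximation is unreliable, so the
test is computed exactly: the null distribution of U is obtained by the
count-of-partitions recursion over all C(n1+n2, n1) equally likely rank
assignments, giving p-values such as 1/252 for complete separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "TestResult",
    "ReplicateSummary",
    "mann_whitney_exact",
    "replicate_summary",
    "state_delta",
    "exact_u_distribution",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-tailed Mann-Whitney U test."""

    U: float
    p_one_tailed: float
    alternative: str  # "less" | "greater" (direction of y relative to x)
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int

    @property
    def p_rounded(self) -> float:
        """p rounded to 3 decimals, the convention of printed tables."""
        return round(self.p_one_tailed, 3)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample standard deviation of replicate-level values."""

    values: tuple[float, ...]
    mean: float
    sd: float
    rounded_mean: float

    @property
    def n(self) -> int:
        return len(self.values)


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value in 0..n1*n2.

    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u): either the largest
    rank belongs to sample 1 (contributing n2 wins) or to sample 2.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null PMF of the Mann-Whitney U statistic (length n1*n2+1)."""
    counts = np.array(_u_counts(n1, n2), dtype=float)
    return counts / math.comb(n1 + n2, n1)


def _count_wins(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """U = number of (i, j) pairs where y_j beats x_i under the alternative.

    Ties count one half.
    """
    diff = y[:, None] - x[None, :]
    if alternative == "greater":
        wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    else:
        wins = (diff < 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins)


def mann_whitney_exact(x, y, alternative: str = "greater") -> TestResult:
    """One-tailed Mann-Whitney U test of sample ``y`` against sample ``x``.

    Parameters
    ----------
    x, y
        The two samples of replicate values.
    alternative
        "greater": y tends to exceed x; "less": y tends to fall below x.
        The p-value is the null probability of a U at least as favourable
        to the alternative as observed.

    The exact null distribution (count recursion, no approximation) is
    used whenever the samples are tie-free and n1 + n2 <= 40; ties fall
    back to the tie-corrected normal approximation on midranks, flagged
    in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_exact requires two non-empty samples")
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    u = _count_wins(x, y, alternative)

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= 40:
        pmf = exact_u_distribution(n1, n2)
        p = float(pmf[int(round(u)):].sum())
        method = "exact"
    else:
        # Tie-corrected normal approximation on midranks.
        mu = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            from scipy.stats import norm

            z = (u - mu - 0.5) / math.sqrt(sigma2)  # continuity corrected
            p = float(norm.sf(z))
        method = "normal_approx"
    return TestResult(U=u, p_one_tailed=p, alternative=alternative,
                      method=method, n1=n1, n2=n2)


def replicate_summary(values) -> ReplicateSummary:
    """Mean +/- sample sd (n-1 denominator) of replicate values.

    ``rounded_mean`` keeps one decimal, matching the convention used when
    tabulating per-state means in kJ/mol.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("replicate_summary requires n >= 2 (sd undefined)")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return ReplicateSummary(values=tuple(float(a) for a in v), mean=mean,
                            sd=sd, rounded_mean=round(mean, 1))


def state_delta(summary_a: ReplicateSummary, summary_b: ReplicateSummary,
                convention: str = "rounded") -> float:
    """Difference of state means, ``b - a``.

    convention "rounded" differences the one-decimal rounded means (this
    reproduces printed table deltas, which are computed from the printed
    means); "raw" differences the raw means.
    """
    if convention == "rounded":
        return round(summary_b.rounded_mean - summary_a.rounded_mean, 1)
    if convention == "raw":
        return summary_b.mean - summary_a.mean
    raise ValueError(f"unknown convention {convention!r}")
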