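"""Small-sample tests computable from printed summary statistics.

Growth-phenotype papers typically print only ``mean +/- s.e. (n)`` per group,
so the two-sample t-test here takes exactly those summaries.  The
Mann-Whitney U test is exact: for the small strain collections involved
(n_a + n_b <= 25) the full permutation distribution of U is enumerated, with
ties handled by mid-ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "t_test_summary",
    "one_sample_t",
    "mann_whitney_exact",
    "mann_whitney_normal",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard error of the mean, and replicate count for one group."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if self.n < 2:
            raise ValueError("need at least 2 replicates")

    @property
    def sd(self) -> float:
        """Sample standard deviation implied by the SE (se * sqrt(n))."""
        return self.se * math.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str


def t_test_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: Literal["welch", "pooled"] = "welch",
    tails: int = 2,
) -> TestResult:
    """Two-sample t-test from per-group mean/SE/n summaries.

    Welch: t = (mean_a - mean_b)/sqrt(se_a^2 + se_b^2), Satterthwaite df.
    Pooled: classical equal-variance t with df = n_a + n_b - 2.
    ``tails=1`` tests the alternative in the direction of the observed
    difference.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    va, vb = a.se**2, b.se**2
    if va == 0 and vb == 0:
        if a.mean == b.mean:
            raise ZeroDivisionError("t undefined: zero variance and equal means")
        t = math.inf if a.mean > b.mean else -math.inf
        df = float(a.n + b.n - 2)
        return TestResult(t, df, 0.0, f"{variant} t-test, {tails}-tailed")
    if variant == "welch":
        t = (a.mean - b.mean) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    elif variant == "pooled":
        # se = sd/sqrt(n) => sample variance = n*se^2
        sa2, sb2 = a.n * va, b.n * vb
        sp2 = ((a.n - 1) * sa2 + (b.n - 1) * sb2) / (a.n + b.n - 2)
        t = (a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = float(a.n + b.n - 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = tails * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), min(float(p), 1.0),
                      f"{variant} t-test, {tails}-tailed")


def one_sample_t(values: Sequence[float], mu0: float, tails: int = 2) -> TestResult:
    """One-sample t-test of the mean of ``values`` against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    sd = float(x.std(ddof=1))
    diff = float(x.mean()) - mu0
    if sd == 0:
        if diff == 0:
            raise ZeroDivisionError("t undefined: zero variance and mean == mu0")
        return TestResult(math.copysign(math.inf, diff), float(x.size - 1), 0.0,
                          f"one-sample t-test, {tails}-tailed")
    t = diff / (sd / math.sqrt(x.size))
    df = x.size - 1
    p = tails * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), min(float(p), 1.0),
                      f"one-sample t-test, {tails}-tailed")


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_exact(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Literal["less", "greater", "two-sided"] = "two-sided",
) -> TestResult:
    """Exact Mann-Whitney U test by full enumeration of group assignments.

    All C(n_a+n_b, n_a) ways of splitting the pooled mid-ranks into the two
    groups are enumerated, so the p-value is exact even under ties.
    ``alternative='less'`` tests that ``a`` tends to be smaller than ``b``
    (small U for group a).

    Raises when n_a + n_b > 25; use :func:`mann_whitney_normal` there.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    na, nb = xa.size, xb.size
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    if na + nb > 25:
        raise ValueError(
            "exact enumeration limited to n_a+n_b <= 25; "
            "use mann_whitney_normal for larger samples"
        )
    pooled = np.concatenate([xa, xb])
    ranks = sps.rankdata(pooled)  # mid-ranks under ties
    u_obs = _u_statistic(ranks[:na], na)

    n = na + nb
    mean_u = na * nb / 2.0
    count_le = 0
    count_ge = 0
    count_extreme = 0
    total = 0
    obs_dev = abs(u_obs - mean_u)
    for idx in combinations(range(n), na):
        u = _u_statistic(ranks[list(idx)], na)
        total += 1
        if u <= u_obs + 1e-12:
            count_le += 1
        if u >= u_obs - 1e-12:
            count_ge += 1
        if abs(u - mean_u) >= obs_dev - 1e-12:
            count_extreme += 1
    if alternative == "less":
        p = count_le / total
    elif alternative == "greater":
        p = count_ge / total
    elif alternative == "two-sided":
        p = count_extreme / total
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(u_obs, None, min(p, 1.0),
                      f"exact Mann-Whitney U, {alternative}")


def mann_whitney_normal(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Literal["less", "greater", "two-sided"] = "two-sided",
) -> TestResult:
    """Normal-approximation Mann-Whitney U for samples too large to enumerate."""
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return TestResult(float(res.statistic), None, float(res.pvalue),
                      f"Mann-Whitney U (normal approximation), {alternative}")
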