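"""Two-group comparisons as used throughout the figures.

Groups are summarized as mean +- SEM and compared with a two-sided Welch
(unequal-variance) t test or a Mann-Whitney U test.  The U test uses the
exact null distribution — full enumeration over group assignments of the
pooled mid-ranks, so ties are handled exactly — whenever n_a + n_b <= 12,
and the tie-corrected normal approximation with continuity correction
otherwise.  Significance is flagged at p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError

__all__ = ["StatResult", "compare_groups", "mann_whitney_exact"]

EXACT_LIMIT = 12


@dataclass
class StatResult:
    test: str                 # "t" | "mann-whitney"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    significant: bool
    method_detail: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p_value: must lie in [0, 1]")


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size >= 2 else math.nan
    return mean, sem


def mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by full enumeration (ties handled).

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first group
    computed from pooled mid-ranks, and p = min(1, 2 x min tail probability)
    over all C(n_a + n_b, n_a) equally likely group assignments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks under ties
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)

    idx = range(n_a + n_b)
    us = np.array([
        ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
        for comb in combinations(idx, n_a)
    ])
    total = us.size
    tol = 1e-9
    p_low = np.count_nonzero(us <= u_obs + tol) / total
    p_high = np.count_nonzero(us >= u_obs - tol) / total
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))


def compare_groups(a, b, test: str = "t") -> StatResult:
    """Two-sided two-sample comparison: Welch t or Mann-Whitney U."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mean_a, sem_a = _mean_sem(a)
    mean_b, sem_b = _mean_sem(b)

    if test == "t":
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("t test: both groups need n >= 2")
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            raise ValidationError("t test: degenerate (zero-variance) pooled data")
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        detail = "Welch two-sided"
    elif test in ("mw", "mann-whitney"):
        if a.size < 1 or b.size < 1:
            raise InsufficientDataError("Mann-Whitney: both groups need n >= 1")
        if a.size + b.size <= EXACT_LIMIT:
            stat, p = mann_whitney_exact(a, b)
            detail = "exact enumeration (ties handled)"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = res.statistic, res.pvalue
            detail = "normal approximation, tie-corrected"
        test = "mann-whitney"
    else:
        raise ValidationError(f"test: unknown test {test!r} (use 't' or 'mann-whitney')")

    return StatResult(
        test=test, statistic=float(stat), p_value=float(p),
        n_a=a.size, n_b=b.size,
        mean_a=mean_a, sem_a=sem_a, mean_b=mean_b, sem_b=sem_b,
        significant=bool(p < 0.05), method_detail=detail,
    )
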