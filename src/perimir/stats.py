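"""Nonparametric statistical toolkit: Kruskal-Wallis, Mann-Whitney U, Spearman.

All group contrasts in the pipeline go through these wrappers so that every
report carries the same result structure (statistic, p, method label, group
sizes, whether an exact computation was used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney", "kruskal_wallis", "rank_correlation"]

# exact null enumeration is used only for small tie-free samples
_EXACT_MW_MAX_N = 12
_EXACT_SPEARMAN_MAX_N = 7


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = field(default_factory=tuple)
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    The p-value is exact (full enumeration of the null distribution of U)
    when the pooled sample has no ties and at most 12 observations; otherwise
    the tie-corrected normal approximation is used.  The two-sided exact p is
    2 x min(tail), capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = (x.size + y.size) <= _EXACT_MW_MAX_N and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney-u",
        n=(x.size, y.size),
        exact=exact,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p at df = k - 1."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need >= 3 observations in total")
    if np.all(pooled == pooled[0]):
        # degenerate: no rank variation at all
        return TestResult(0.0, 1.0, "kruskal-wallis",
                          tuple(g.size for g in groups), exact=False)
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal-wallis",
                      tuple(g.size for g in groups), exact=False)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all orderings of one rank vector."""
    n = len(rx)
    rx = rx - rx.mean()
    denom = np.sqrt((rx ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    count = 0
    total = 0
    ryc = ry - ry.mean()
    for perm in permutations(range(n)):
        rho = float(np.dot(rx, ryc[list(perm)])) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_correlation(x, y) -> dict:
    """Spearman rank correlation.

    Uses average ranks for ties.  p is computed by exhaustive permutation for
    n <= 7, otherwise by the t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has undefined rank correlation")
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    exact = n <= _EXACT_SPEARMAN_MAX_N
    if exact:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = float(p_t)
    return {
        "r": rho,
        "p": min(float(p), 1.0),
        "method": "spearman",
        "n": int(n),
        "exact": exact,
    }
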