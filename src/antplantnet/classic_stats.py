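"""Auxiliary univariate statistics: Spearman correlation, chi-square goodness
of fit, one-way ANOVA, and Sorensen floristic similarity."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    n: int
    name: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "n": self.n,
        }


def spearman(x: Sequence[float], y: Sequence[float], exact: bool = False) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    Two-sided p-value via the t approximation; ``exact=True`` switches to a
    full permutation p-value (only for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rs, p = stats.spearmanr(x, y)
    n = x.size
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rs) - 1e-12
            total += 1
        p = count / total
    return TestResult(statistic=float(rs), df=n - 2, p_value=float(p), n=n, name="spearman")


def chisq_gof(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> TestResult:
    """Chi-square goodness of fit; uniform expectation when none is given."""
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        exp = np.full_like(obs, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        exp = exp * obs.sum() / exp.sum()
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    chi2, p = stats.chisquare(obs, exp)
    return TestResult(
        statistic=float(chi2), df=obs.size - 1, p_value=float(p), n=int(obs.sum()),
        name="chisq_gof",
    )


def anova_oneway(groups: Iterable[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test across groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    n = sum(a.size for a in arrs)
    if n - len(arrs) < 1:
        raise ValueError("not enough residual degrees of freedom")
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:
        raise ValueError("all values identical")
    f, p = stats.f_oneway(*arrs)
    return TestResult(
        statistic=float(f),
        df=(len(arrs) - 1, n - len(arrs)),
        p_value=float(p),
        n=n,
        name="anova_oneway",
    )


def sorensen(list_a: Iterable[str], list_b: Iterable[str]) -> float:
    """Sorensen similarity QS = 2|A∩B| / (|A| + |B|) of two species sets."""
    a, b = set(list_a), set(list_b)
    if not a or not b:
        raise ValueError("both species sets must be non-empty")
    return 2.0 * len(a & b) / (len(a) + len(b))
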