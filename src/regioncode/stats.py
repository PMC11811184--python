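"""Shared statistical primitives.

These wrap scipy/statsmodels with the exact conventions used throughout the
analysis: a strict-upper-tail binomial excess test against a 5% chance level,
an uncorrected Pearson chi-square on 2x2 proportion tables, Benjamini-Hochberg
FDR control, and paired/two-sample t-tests reported with Cohen's d and a
confidence interval of the mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "binomial_excess_test",
    "chi2_proportions",
    "bh_fdr",
    "group_comparison",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    df: float | None = None
    n: int | None = None
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def binomial_excess_test(
    k: int, n: int, p0: float = 0.05, *, inclusive: bool = False
) -> TestResult:
    """Upper-tail binomial test for an excess of selected units.

    Tests whether observing ``k`` selections out of ``n`` exceeds the chance
    level ``p0``. The default is the strict tail P(X > k); ``inclusive=True``
    gives P(X >= k). The strict tail is the convention that reproduces the
    published selection statistics this package mirrors.

    Parameters
    ----------
    k
        Number of selected units.
    n
        Total number of units.
    p0
        Chance selection probability, 0 < p0 < 1 (default 0.05).
    inclusive
        If True use P(X >= k) instead of the strict P(X > k).
    """
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"require 0 < p0 < 1, got {p0}")
    # scipy's sf is incomplete-beta based and accurate far below 1e-15,
    # where naive 1 - cdf would round to zero.
    p = float(sps.binom.sf(k - 1 if inclusive else k, n, p0))
    return TestResult(statistic=float(k), p_value=p, n=n,
                      extra={"p0": p0, "proportion": k / n if n else math.nan})


def chi2_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> TestResult:
    """Pearson chi-square test comparing two proportions k1/n1 vs k2/n2.

    Uses the 2x2 table [[k1, n1-k1], [k2, n2-k2]] with df=1 and no continuity
    correction. Groups may overlap (e.g. a subpopulation against the whole
    population); the test is computed on the table as given.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = sps.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero; test undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), df=float(dof),
                      n=n1 + n2)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _cohens_d(a: np.ndarray, b: np.ndarray, paired: bool) -> float:
    if paired:
        d = a - b
        sd = d.std(ddof=1)
        return float(d.mean() / sd) if sd > 0 else math.nan
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / math.sqrt(pooled)) if pooled > 0 else math.nan


def group_comparison(
    a,
    b,
    *,
    paired: bool = False,
    tails: str = "two-sided",
    alpha: float = 0.05,
) -> TestResult:
    """Paired or two-sample t-test with Cohen's d and CI of the mean difference.

    ``tails`` is one of ``two-sided``, ``greater`` (a > b) or ``less``.
    Degenerate inputs with zero variance everywhere return statistic 0 and a
    missing (NaN) p-value rather than an infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length samples")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 observations per group")

    if paired:
        diff = a - b
        if diff.std(ddof=1) == 0:
            p = math.nan if diff.mean() != 0 else 1.0
            return TestResult(statistic=0.0, p_value=p, df=float(len(diff) - 1),
                              n=len(diff), effect_size=math.nan)
        res = sps.ttest_rel(a, b, alternative=tails)
        n = len(diff)
        se = diff.std(ddof=1) / math.sqrt(n)
        tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
        ci = (float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se))
        df = n - 1
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = math.nan if a.mean() != b.mean() else 1.0
            return TestResult(statistic=0.0, p_value=p, n=len(a) + len(b),
                              effect_size=math.nan)
        res = sps.ttest_ind(a, b, alternative=tails)
        na, nb = len(a), len(b)
        df = na + nb - 2
        pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        se = math.sqrt(pooled * (1 / na + 1 / nb))
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        delta = a.mean() - b.mean()
        ci = (float(delta - tcrit * se), float(delta + tcrit * se))

    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        n=len(a) + len(b),
        effect_size=_cohens_d(a, b, paired),
        ci=ci,
    )
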