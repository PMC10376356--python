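"""Contingency-table statistics for cohort outcome comparisons.

2x2 odds ratios are computed as the cross-product ratio ad/bc with a Woolf
(log-scale) confidence interval, SE = sqrt(1/a + 1/b + 1/c + 1/d); tables
with a zero cell fall back to the Haldane–Anscombe +0.5 correction and say
so in the result.  Chi-square and Fisher tests are delegated to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "ChiSquareResult",
    "odds_ratio_woolf",
    "chi_square",
    "two_proportion_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows exposure groups, columns outcome (event, no event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        arr = self.to_array()
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("every margin needs at least one observation")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_lower: float
    ci_upper: float
    alpha: float
    continuity_corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "test": "odds_ratio_woolf",
            "or": self.or_value,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "alpha": self.alpha,
            "continuity_corrected": self.continuity_corrected,
        }


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    yates_correction: bool
    fisher_fallback: bool = False
    min_expected: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "test": "fisher_exact" if self.fisher_fallback else "chi_square",
            "statistic": self.statistic,
            "p": self.p_value,
            "dof": self.dof,
            "yates_correction": self.yates_correction,
            "fisher_fallback": self.fisher_fallback,
            "min_expected": self.min_expected,
        }


def odds_ratio_woolf(t: ContingencyTable2x2, alpha: float = 0.05) -> OddsRatioResult:
    """Cross-product odds ratio ad/bc with the Woolf log-scale CI.

    CI = exp(ln OR ± z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)).  Zero
    cells trigger the Haldane–Anscombe +0.5 correction on all four cells,
    flagged in the result.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    log_or = math.log(or_value)
    return OddsRatioResult(
        or_value=or_value,
        ci_lower=math.exp(log_or - z * se),
        ci_upper=math.exp(log_or + z * se),
        alpha=alpha,
        continuity_corrected=corrected,
    )


def chi_square(
    table,
    yates_correction: bool = False,
    fisher_when_sparse: bool = True,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x k count table.

    Yates continuity correction is off by default.  When any expected count
    falls below 5 and the table is 2x2, the Fisher exact test is reported
    instead (flagged); for larger sparse tables the chi-square is still
    returned with the flagged minimum expected count.
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    stat, p, dof, expected = sps.chi2_contingency(arr, correction=yates_correction)
    min_exp = float(expected.min())
    if fisher_when_sparse and min_exp < 5.0 and arr.shape == (2, 2):
        _, p_fisher = sps.fisher_exact(arr)
        return ChiSquareResult(
            statistic=float(stat), p_value=float(p_fisher), dof=int(dof),
            yates_correction=yates_correction, fisher_fallback=True, min_expected=min_exp,
        )
    return ChiSquareResult(
        statistic=float(stat), p_value=float(p), dof=int(dof),
        yates_correction=yates_correction, fisher_fallback=False, min_expected=min_exp,
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int, yates_correction: bool = False) -> ChiSquareResult:
    """Compare two attainment proportions k1/n1 vs k2/n2 (unpaired chi-square)."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n for both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return chi_square(table, yates_correction=yates_correction, fisher_when_sparse=False)
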