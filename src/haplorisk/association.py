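"""Case-control odds-ratio association for haplotypes and genotypes.

A haplotype row with ``a`` carrier chromosomes among ``n_case`` case
chromosomes and ``b`` among ``n_control`` control chromosomes defines the
2x2 table ``[[a, b], [n_case - a, n_control - b]]``.  The same machinery
applies to genotype rows counted over individuals.  Conventions:

* odds ratio: sample cross-product ratio ``a * d / (b * c)``;
* 95% CI: Woolf's log method, ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``;
* p-value: Pearson chi-square with 1 df and *no* continuity correction;
* multiplicity: Bonferroni over the number of categories tested.

Zero cells yield OR 0 or +inf with a flag and an undefined CI by default; the
Haldane-Anscombe +0.5 correction is available behind ``haldane=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CountTable

__all__ = [
    "OddsRatioCI",
    "AssociationResult",
    "odds_ratio_2x2",
    "chi2_p_2x2",
    "bonferroni",
    "associate_table",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class OddsRatioCI:
    odds_ratio: float
    ci_low: float
    ci_high: float
    zero_cell: bool = False

    def __iter__(self):
        return iter((self.odds_ratio, self.ci_low, self.ci_high))


def _cells(a: int, b: int, n_case: int, n_control: int) -> tuple[int, int, int, int]:
    if n_case <= 0 or n_control <= 0:
        raise ValueError("cohort totals must be positive")
    if not (0 <= a <= n_case) or not (0 <= b <= n_control):
        raise ValueError("cell counts must lie within the cohort totals")
    return a, b, n_case - a, n_control - b


def odds_ratio_2x2(
    a: int, b: int, n_case: int, n_control: int, haldane: bool = False
) -> OddsRatioCI:
    """Sample odds ratio with Woolf 95% confidence interval.

    ``a`` and ``b`` are exposed (carrier) counts among ``n_case`` and
    ``n_control``.  With a zero cell the OR is reported as 0 or ``inf`` with
    ``zero_cell=True`` and an undefined (NaN) interval, unless ``haldane``
    adds 0.5 to every cell first.
    """
    a, b, c, d = _cells(a, b, n_case, n_control)
    if haldane and 0 in (a, b, c, d):
        fa, fb, fc, fd = (x + 0.5 for x in (a, b, c, d))
        zero = True
    elif 0 in (a, b, c, d):
        if (a == 0 or d == 0) and (b == 0 or c == 0):
            or_ = math.nan  # 0/0: no information
        elif a == 0 or d == 0:
            or_ = 0.0
        else:
            or_ = math.inf
        return OddsRatioCI(or_, math.nan, math.nan, zero_cell=True)
    else:
        fa, fb, fc, fd = a, b, c, d
        zero = False
    or_ = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    log_or = math.log(or_)
    return OddsRatioCI(
        or_, math.exp(log_or - _Z95 * se), math.exp(log_or + _Z95 * se), zero_cell=zero
    )


def chi2_p_2x2(a: int, b: int, n_case: int, n_control: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) and its upper-tail p."""
    a, b, c, d = _cells(a, b, n_case, n_control)
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; chi2 set to 0", stacklevel=2)
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value, ``min(1, m * p)``."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p)


@dataclass
class AssociationResult:
    """One row of a case-control association table."""

    label: str
    case_count: int
    control_count: int
    case_pct: float
    control_pct: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    p_corrected: float
    significant: bool
    zero_cell: bool = False


def associate_table(
    table: CountTable,
    m: int | None = None,
    alpha: float = 0.05,
    haldane: bool = False,
) -> list[AssociationResult]:
    """Run the 2x2 association over every row of a (filtered) count table.

    ``m`` is the Bonferroni multiplicity; it defaults to the number of rows.
    Results are sorted by descending odds ratio, the layout used for
    published association tables; ``significant`` marks rows whose corrected
    p-value stays below ``alpha``.
    """
    if m is None:
        m = len(table.rows)
    results = []
    for r in table.rows:
        orci = odds_ratio_2x2(
            r.case_count, r.control_count, table.case_total, table.control_total,
            haldane=haldane,
        )
        chi2, p = chi2_p_2x2(
            r.case_count, r.control_count, table.case_total, table.control_total
        )
        pc = bonferroni(p, m)
        results.append(
            AssociationResult(
                label=r.label,
                case_count=r.case_count,
                control_count=r.control_count,
                case_pct=100.0 * r.case_count / table.case_total,
                control_pct=100.0 * r.control_count / table.control_total,
                odds_ratio=orci.odds_ratio,
                ci_low=orci.ci_low,
                ci_high=orci.ci_high,
                chi2=chi2,
                p=p,
                p_corrected=pc,
                significant=pc < alpha,
                zero_cell=orci.zero_cell,
            )
        )
    results.sort(key=lambda x: x.odds_ratio, reverse=True)
    return results
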