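"""Sequential relative predispositional effect (RPE) procedure.

When one haplotype is strongly over-represented in patients, other haplotypes
are mechanically under-represented (a displacement effect), so a naive
case-control comparison cannot tell true protection from crowding-out.  The
RPE procedure addresses this by working in rounds:

1. For every remaining haplotype compute the count expected in cases if cases
   followed the control distribution, ``E_i = control_i * (case_total /
   control_total)`` at the *current* (post-removal) totals.
2. Form the overall chi-square ``sum (O_i - E_i)^2 / E_i`` over the remaining
   categories with ``df = #categories - 1``; if it is no longer significant
   (default P >= 0.001), stop.
3. Otherwise select the haplotype with the largest contribution, record its
   unpooled two-proportion z statistic on the current totals, remove its
   chromosomes from both cases and controls, and repeat.

Cohort totals may exceed the sum of the displayed rows (chromosomes carrying
rare, unlisted haplotypes).  That remainder is carried as an explicit residual
category: it keeps the expected counts summing to the case total and
contributes to the overall chi-square, but is never itself selected for
removal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .cohort import HaplotypeCountTable

__all__ = [
    "RPERound",
    "RPETrace",
    "expected_counts",
    "unpooled_z",
    "run_rpe",
    "RESIDUAL_LABEL",
]

RESIDUAL_LABEL = "(other)"


def expected_counts(
    table: HaplotypeCountTable,
    case_total: int | None = None,
    control_total: int | None = None,
) -> dict[str, float]:
    """Expected case counts under the no-differential-predisposition null.

    ``E_i = control_count_i * (case_total / control_total)``.  Totals default
    to the table's cohort totals; pass the current totals when running inside
    a removal round.
    """
    case_total = table.case_total if case_total is None else case_total
    control_total = table.control_total if control_total is None else control_total
    if control_total <= 0:
        raise ValueError("control total must be positive")
    ratio = case_total / control_total
    return {r.label: r.control_count * ratio for r in table.rows}


def unpooled_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z statistic with unpooled variance, and two-sided p.

    ``z = (p1 - p2) / sqrt(p1 (1-p1)/n1 + p2 (1-p2)/n2)``.  When both
    proportions are degenerate (0 or 1) the statistic is undefined and NaN is
    returned with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0.0:
        if p1 == p2:
            return 0.0, 1.0
        warnings.warn("degenerate proportions; z undefined", stacklevel=2)
        return math.nan, math.nan
    z = (p1 - p2) / math.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


@dataclass
class RPERound:
    """One removal round of the sequential procedure."""

    index: int
    label: str
    observed: int
    expected: float
    contribution: float
    z: float
    p_z: float
    overall_chi2: float
    overall_p: float
    df: int
    remaining_case_total: int
    remaining_control_total: int


@dataclass
class RPETrace:
    """Ordered rounds plus the reason the procedure stopped."""

    rounds: list[RPERound]
    stop_reason: str  # "overall_not_significant" | "exhausted" | "max_rounds"
    final_chi2: float
    final_p: float
    final_df: int

    @property
    def removed_labels(self) -> list[str]:
        return [r.label for r in self.rounds]


def run_rpe(
    table: HaplotypeCountTable,
    alpha_overall: float = 0.001,
    max_rounds: int | None = None,
    include_residual: bool = True,
) -> RPETrace:
    """Run the sequential RPE procedure on a haplotype count table.

    ``alpha_overall`` is the stopping threshold on the overall chi-square
    p-value across the remaining categories.  ``include_residual`` carries the
    undisplayed-rare-chromosome remainder as a non-selectable category (see
    module docstring); disable it only for tables whose rows exhaust the
    totals.
    """
    if len(table.rows) < 2:
        raise ValueError("need at least 2 haplotypes")
    if not (0.0 < alpha_overall < 1.0):
        raise ValueError("alpha_overall must be in (0, 1)")

    counts: dict[str, tuple[int, int]] = {
        r.label: (r.case_count, r.control_count) for r in table.rows
    }
    if include_residual and (table.residual_case or table.residual_control):
        counts[RESIDUAL_LABEL] = (table.residual_case, table.residual_control)
    case_total, control_total = table.case_total, table.control_total

    rounds: list[RPERound] = []
    stop_reason = "exhausted"
    chi2_overall = p_overall = math.nan
    df = 0
    while True:
        selectable = [lab for lab in counts if lab != RESIDUAL_LABEL]
        if len(selectable) < 1 or control_total <= 0:
            stop_reason = "exhausted"
            break
        ratio = case_total / control_total
        contribs: dict[str, tuple[float, float]] = {}
        chi2_overall = 0.0
        for lab, (obs, ctrl) in counts.items():
            e = ctrl * ratio
            if e > 0:
                contrib = (obs - e) ** 2 / e
            else:
                contrib = math.inf if obs > 0 else 0.0
            contribs[lab] = (e, contrib)
            chi2_overall += contrib
        df = len(counts) - 1
        if df < 1 or not math.isfinite(chi2_overall):
            p_overall = 0.0 if not math.isfinite(chi2_overall) else 1.0
        else:
            p_overall = float(stats.chi2.sf(chi2_overall, df))
        if p_overall >= alpha_overall:
            stop_reason = "overall_not_significant"
            break
        if max_rounds is not None and len(rounds) >= max_rounds:
            stop_reason = "max_rounds"
            break
        label = max(selectable, key=lambda lab: contribs[lab][1])
        obs, ctrl = counts[label]
        expected, contribution = contribs[label]
        z, p_z = unpooled_z(obs, case_total, ctrl, control_total)
        rounds.append(
            RPERound(
                index=len(rounds) + 1,
                label=label,
                observed=obs,
                expected=expected,
                contribution=contribution,
                z=z,
                p_z=p_z,
                overall_chi2=chi2_overall,
                overall_p=p_overall,
                df=df,
                remaining_case_total=case_total,
                remaining_control_total=control_total,
            )
        )
        del counts[label]
        case_total -= obs
        control_total -= ctrl
        if len(counts) < 2:
            stop_reason = "exhausted"
            chi2_overall, p_overall, df = math.nan, math.nan, 0
            break
    return RPETrace(rounds, stop_reason, chi2_overall, p_overall, df)
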