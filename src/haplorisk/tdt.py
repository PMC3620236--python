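"""Stratified transmission analysis of the non-risk ("X/Y") parent.

To ask whether a second haplotype modifies the risk conferred by an index
risk haplotype R (here typically DRB1*03:01-DQB1*02:01), offspring are
stratified by carriage of R and, within each stratum, the transmissions of
the parent(s) carrying *neither* copy of R are tallied: each informative
(heterozygous, R-free) parent contributes one transmitted (T) and one
untransmitted (NT) haplotype, so ``sum T = sum NT = n_informative`` by
construction.

Per-haplotype testing is haplotype-vs-rest on the 2x2 table
``[[T, NT], [n - T, n - NT]]`` (Pearson chi-square, 1 df, no continuity
correction) with OR ``T (n - NT) / (NT (n - T))``; the paired McNemar
statistic ``(T - NT)^2 / (T + NT)`` is available behind a flag.  Strata are
compared with a Pearson chi-square on ``[[T+, NT+], [T-, NT-]]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .cohort import TrioFamily, normalize_label

__all__ = [
    "TransmissionTable",
    "TransmissionAccounting",
    "StratifiedTDTResult",
    "count_transmissions",
    "tdt_vs_rest",
    "mcnemar",
    "compare_strata",
    "stratified_tdt",
]


@dataclass
class TransmissionTable:
    """Per-haplotype transmitted/not-transmitted counts in one stratum."""

    stratum: str  # "risk_positive" | "risk_negative"
    counts: dict[str, list[int]] = field(default_factory=dict)  # label -> [T, NT]

    def add(self, transmitted: str, not_transmitted: str) -> None:
        self.counts.setdefault(transmitted, [0, 0])[0] += 1
        self.counts.setdefault(not_transmitted, [0, 0])[1] += 1

    @property
    def n_informative(self) -> int:
        return sum(t for t, _ in self.counts.values())

    def t_nt(self, label: str) -> tuple[int, int]:
        t, nt = self.counts.get(normalize_label(label), (0, 0))
        return t, nt

    @property
    def labels(self) -> list[str]:
        return sorted(self.counts)


@dataclass
class TransmissionAccounting:
    """Families and parents set aside while counting, for transparent reporting."""

    n_families_seen: int = 0
    n_offspring_used: int = 0
    n_both_parents_carry_risk: int = 0
    n_no_eligible_parent: int = 0
    n_homozygous_parents_skipped: int = 0
    n_ambiguous_parents_skipped: int = 0
    n_non_mendelian: int = 0


def _transmitted_options(
    fam: TrioFamily, child: tuple[str, str], parent: str
) -> set[str]:
    """Haplotypes the given parent may have transmitted, over all consistent
    phase assignments of the child."""
    idx = 0 if parent == "father" else 1
    return {assign[idx] for assign in fam.mendelian_assignments(child)}


def count_transmissions(
    families: Iterable[TrioFamily],
    risk: str,
    offspring_status: str = "affected",
) -> tuple[TransmissionTable, TransmissionTable, TransmissionAccounting]:
    """Tally X/Y-parent transmissions to offspring, stratified by risk carriage.

    For every offspring of the requested status, the stratum is determined by
    whether the offspring carries at least one copy of ``risk``.  Every parent
    carrying no copy of ``risk`` is informative (this lets both parents of a
    risk-negative offspring contribute); homozygous parents are skipped, as
    are parents whose transmitted haplotype cannot be resolved uniquely from
    phase (intercross-like matings).  Families in which both parents carry the
    risk haplotype have no eligible X/Y parent and are excluded from both
    strata.
    """
    risk = normalize_label(risk)
    pos = TransmissionTable("risk_positive")
    neg = TransmissionTable("risk_negative")
    acct = TransmissionAccounting()
    for fam in families:
        acct.n_families_seen += 1
        father_has_risk = risk in fam.father
        mother_has_risk = risk in fam.mother
        if father_has_risk and mother_has_risk:
            acct.n_both_parents_carry_risk += 1
            continue
        for child, status in fam.children:
            if status != offspring_status:
                continue
            if not fam.is_mendelian(child):
                acct.n_non_mendelian += 1
                continue
            acct.n_offspring_used += 1
            table = pos if risk in child else neg
            used_any = False
            for parent_name, pair, has_risk in (
                ("father", fam.father, father_has_risk),
                ("mother", fam.mother, mother_has_risk),
            ):
                if has_risk:
                    continue
                if pair[0] == pair[1]:
                    acct.n_homozygous_parents_skipped += 1
                    continue
                options = _transmitted_options(fam, child, parent_name)
                if len(options) != 1:
                    acct.n_ambiguous_parents_skipped += 1
                    continue
                transmitted = options.pop()
                not_transmitted = pair[1] if transmitted == pair[0] else pair[0]
                table.add(transmitted, not_transmitted)
                used_any = True
            if not used_any:
                acct.n_no_eligible_parent += 1
    return pos, neg, acct


def tdt_vs_rest(
    t: int, nt: int, n_informative: int, use_mcnemar: bool = False
) -> tuple[float, float, float]:
    """Haplotype-vs-rest transmission test: ``(OR, chi2, two-sided p)``.

    The 2x2 table is ``[[T, NT], [n - T, n - NT]]`` (this haplotype against
    all others, transmitted against not transmitted).  With ``use_mcnemar``
    the statistic is the paired ``(T - NT)^2 / (T + NT)`` instead, with the
    same vs-rest OR.
    """
    if n_informative <= 0:
        raise ValueError("n_informative must be positive")
    if t + nt > 2 * n_informative or t > n_informative or nt > n_informative:
        raise ValueError("transmission counts exceed the informative-parent total")
    rest_t, rest_nt = n_informative - t, n_informative - nt
    if nt == 0 or rest_t == 0:
        or_ = math.inf if t > 0 else math.nan
    elif t == 0 or rest_nt == 0:
        or_ = 0.0
    else:
        or_ = (t * rest_nt) / (nt * rest_t)
    if use_mcnemar:
        if t + nt == 0:
            return or_, 0.0, 1.0
        chi2 = (t - nt) ** 2 / (t + nt)
        return or_, chi2, float(stats.chi2.sf(chi2, 1))
    table = np.array([[t, nt], [rest_t, rest_nt]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return or_, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return or_, float(chi2), float(p)


def mcnemar(t: int, nt: int) -> tuple[float, float]:
    """Paired transmission test ``(T - NT)^2 / (T + NT)`` and its p-value."""
    if t + nt == 0:
        return 0.0, 1.0
    chi2 = (t - nt) ** 2 / (t + nt)
    return chi2, float(stats.chi2.sf(chi2, 1))


def compare_strata(
    t_pos: int, nt_pos: int, t_neg: int, nt_neg: int
) -> tuple[float, float]:
    """Pearson chi-square comparing T:NT between the two strata."""
    if min(t_pos, nt_pos, t_neg, nt_neg) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[t_pos, nt_pos], [t_neg, nt_neg]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin comparing strata; chi2 set to 0", stacklevel=2)
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class StratumResult:
    t: int
    nt: int
    or_vs_rest: float
    chi2: float
    p: float


@dataclass
class StratifiedTDTResult:
    """Per-haplotype result across both strata."""

    label: str
    positive: StratumResult
    negative: StratumResult
    between_chi2: float
    between_p: float


def stratified_tdt(
    families: Iterable[TrioFamily],
    risk: str,
    offspring_status: str = "affected",
    min_het_parents: int = 250,
    use_mcnemar: bool = False,
) -> tuple[list[StratifiedTDTResult], TransmissionTable, TransmissionTable, TransmissionAccounting]:
    """Full stratified transmission analysis for one risk haplotype.

    ``min_het_parents`` gates which haplotypes may index the stratification:
    the analysis refuses to run unless the risk haplotype is carried by at
    least that many heterozygous parents, the informativeness requirement for
    this design.  Set it to 0 to disable (e.g. on small simulated data).
    """
    families = list(families)
    risk = normalize_label(risk)
    n_het = sum(
        (risk in pair and pair[0] != pair[1])
        for fam in families
        for pair in (fam.father, fam.mother)
    )
    if n_het < min_het_parents:
        raise ValueError(
            f"risk haplotype {risk} carried by only {n_het} heterozygous parents "
            f"(< {min_het_parents} required)"
        )
    pos, neg, acct = count_transmissions(families, risk, offspring_status)
    results = []
    for label in sorted(set(pos.labels) | set(neg.labels)):
        strata = []
        for table in (pos, neg):
            t, nt = table.t_nt(label)
            if t + nt == 0:
                strata.append(StratumResult(0, 0, math.nan, 0.0, 1.0))
                continue
            or_, chi2, p = tdt_vs_rest(t, nt, table.n_informative, use_mcnemar)
            strata.append(StratumResult(t, nt, or_, chi2, p))
        bchi2, bp = compare_strata(
            strata[0].t, strata[0].nt, strata[1].t, strata[1].nt
        ) if (strata[0].t + strata[0].nt) and (strata[1].t + strata[1].nt) else (0.0, 1.0)
        results.append(StratifiedTDTResult(label, strata[0], strata[1], bchi2, bp))
    return results, pos, neg, acct
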