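"""Log-additivity interaction model for genotypic odds ratios.

If the two haplotypes of a genotype contribute risk independently, the
expected genotypic odds ratio is the product of the haplotypic ones,
``OR_g_exp = OR_ha * OR_hb`` — additivity on the log scale.  The deviation of
the observed genotypic OR from this expectation,

    alpha = log10(OR_g_obs) - log10(OR_ha * OR_hb),

probes interaction between the haplotypes: within an empirical neutral band
(default [0.01, 0.09], endpoints inclusive) the genotype behaves as a pure
gene-dosage combination of its haplotypes; above the band the pairing is
synergistically predisposing, below it the pairing lowers the combined risk.
The band is asymmetric about zero and does not contain it: small alphas
below 0.01 (including slightly positive ones) fall outside the neutral call,
so the sign is reported separately from the classification.

Two modes are provided: *reproduction* combines odds ratios rounded to one
decimal (the precision of published association tables, allowing exact
comparison against them) and *full* keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .association import AssociationResult
from .cohort import genotype_label, normalize_label

__all__ = [
    "AlphaRecord",
    "expected_genotypic_or",
    "alpha",
    "classify_alpha",
    "build_alpha_table",
    "NEUTRAL_BAND",
]

NEUTRAL_BAND = (0.01, 0.09)


def expected_genotypic_or(or_ha: float, or_hb: float) -> float:
    """Expected genotypic OR under haplotypic independence: the product."""
    if or_ha <= 0 or or_hb <= 0:
        raise ValueError("haplotypic odds ratios must be positive")
    return or_ha * or_hb


def alpha(or_g_obs: float, or_g_exp: float, log_base: float = 10.0) -> float:
    """Deviation of the observed genotypic OR from the expected one.

    ``alpha = log(or_g_obs) - log(or_g_exp)`` in base ``log_base`` (default
    10, the scale on which the neutral band is defined).
    """
    if or_g_obs <= 0 or or_g_exp <= 0:
        raise ValueError("odds ratios must be positive")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    return math.log(or_g_obs, log_base) - math.log(or_g_exp, log_base)


def classify_alpha(
    value: float, band: tuple[float, float] = NEUTRAL_BAND
) -> str:
    """Classify an alpha value against the neutral band (endpoints inclusive).

    Returns ``"neutral"`` inside the band, ``"positive_interaction"`` above
    it and ``"negative_interaction"`` below it.  Note that values in
    ``[0, 0.01)`` are below the band yet non-negative; callers should report
    the sign separately (see :class:`AlphaRecord`).
    """
    low, high = band
    if low >= high:
        raise ValueError("band low must be < high")
    if low <= value <= high:
        return "neutral"
    return "positive_interaction" if value > high else "negative_interaction"


def _character(or_h: float) -> str:
    return "predisposing" if or_h > 1.0 else "protective"


@dataclass
class AlphaRecord:
    """One genotype's observed vs expected odds ratio and its alpha."""

    genotype: str  # canonical "A/B" label
    character: tuple[str, str]  # per-haplotype predisposing/protective
    or_ha: float
    or_hb: float
    or_g_obs: float
    or_g_exp: float
    alpha: float
    classification: str
    sign: str  # "+", "-" or "0"
    below_band_positive: bool  # alpha in [0, band_low): outside band, yet positive


def build_alpha_table(
    hap_results: Sequence[AssociationResult],
    gen_results: Sequence[AssociationResult],
    pairs: Iterable[tuple[str, str]],
    mode: str = "reproduction",
    log_base: float = 10.0,
    band: tuple[float, float] = NEUTRAL_BAND,
) -> list[AlphaRecord]:
    """Combine haplotypic and genotypic association results into alpha records.

    ``pairs`` lists the genotypes to evaluate (normally the significantly
    associated ones).  In ``"reproduction"`` mode every odds ratio is rounded
    to one decimal before combination, matching the precision of published
    tables; ``"full"`` keeps full precision.  The expected genotypic OR is
    always computed from the haplotypic ORs, never taken from a table.
    """
    if mode not in ("reproduction", "full"):
        raise ValueError(f"mode must be 'reproduction' or 'full', got {mode!r}")
    hap_or = {r.label: r.odds_ratio for r in hap_results}
    gen_or = {r.label: r.odds_ratio for r in gen_results}
    rnd = (lambda x: round(x, 1)) if mode == "reproduction" else (lambda x: x)
    records = []
    for ha, hb in pairs:
        ha, hb = normalize_label(ha), normalize_label(hb)
        glabel = genotype_label(ha, hb)
        for h in (ha, hb):
            if h not in hap_or:
                raise KeyError(f"haplotype {h!r} missing from haplotypic results")
        if glabel not in gen_or:
            raise KeyError(f"genotype {glabel!r} missing from genotypic results")
        or_ha, or_hb = rnd(hap_or[ha]), rnd(hap_or[hb])
        or_g_obs = rnd(gen_or[glabel])
        or_g_exp = expected_genotypic_or(or_ha, or_hb)
        a = alpha(or_g_obs, or_g_exp, log_base=log_base)
        records.append(
            AlphaRecord(
                genotype=glabel,
                character=(_character(or_ha), _character(or_hb)),
                or_ha=or_ha,
                or_hb=or_hb,
                or_g_obs=or_g_obs,
                or_g_exp=or_g_exp,
                alpha=a,
                classification=classify_alpha(a, band),
                sign="+" if a > 0 else ("-" if a < 0 else "0"),
                below_band_positive=0.0 <= a < band[0],
            )
        )
    return records
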