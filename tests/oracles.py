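"""Independent oracles used to cross-check the package's statistics.

Everything here is computed from first principles (closed forms or exhaustive
enumeration) without calling the implementation under test.
"""

from __future__ import annotations

import itertools
import math

from scipy import stats


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Closed-form Pearson chi-square N(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def pooled_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-proportion z with pooled variance; its square is the Pearson chi2."""
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    var = p * (1 - p) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0
    return (p1 - p2) / math.sqrt(var)


def woolf_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Sample OR with the log-method 95% CI, straight from the formula."""
    or_ = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


class PopulationModel:
    """Exact population-level expectations of the generative cohort model.

    Genotypes are two independent haplotype draws; penetrance is
    ``baseline * rr(ha) * rr(hb) * 10**inter[(ha, hb)]``.  All quantities are
    obtained by enumerating every ordered haplotype pair, so they are exact
    up to floating point and independent of any sampling.
    """

    def __init__(self, freqs, rr=None, inter=None, baseline=0.01):
        self.labels = list(freqs)
        self.freqs = dict(freqs)
        self.rr = dict(rr or {})
        self.inter = {}
        for pair, val in (inter or {}).items():
            self.inter[frozenset(pair)] = val
        self.baseline = baseline

    def penetrance(self, ha, hb):
        risk = (
            self.baseline
            * self.rr.get(ha, 1.0)
            * self.rr.get(hb, 1.0)
            * 10.0 ** self.inter.get(frozenset((ha, hb)), 0.0)
        )
        return min(risk, 1.0)

    def _status_masses(self):
        case, ctrl = {}, {}
        for ha, hb in itertools.product(self.labels, repeat=2):
            f = self.freqs[ha] * self.freqs[hb]
            pen = self.penetrance(ha, hb)
            case[(ha, hb)] = f * pen
            ctrl[(ha, hb)] = f * (1 - pen)
        zc, zn = sum(case.values()), sum(ctrl.values())
        return (
            {g: m / zc for g, m in case.items()},
            {g: m / zn for g, m in ctrl.items()},
        )

    def haplotype_or(self, label):
        """Population chromosome-level odds ratio for carrying `label`."""
        case, ctrl = self._status_masses()
        pc = sum(m for (ha, hb), m in case.items() for h in (ha, hb) if h == label) / 2
        pn = sum(m for (ha, hb), m in ctrl.items() for h in (ha, hb) if h == label) / 2
        return (pc / (1 - pc)) / (pn / (1 - pn))

    def genotype_or(self, ha, hb):
        """Population individual-level odds ratio for the unordered genotype."""
        case, ctrl = self._status_masses()
        want = frozenset((ha, hb)) if ha != hb else frozenset((ha,))
        pc = sum(m for g, m in case.items() if frozenset(g) == want)
        pn = sum(m for g, m in ctrl.items() if frozenset(g) == want)
        return (pc / (1 - pc)) / (pn / (1 - pn))

    def population_alpha(self, ha, hb):
        """Plug-in alpha implied by the population ORs (log10 scale)."""
        org = self.genotype_or(ha, hb)
        exp = self.haplotype_or(ha) * self.haplotype_or(hb)
        return math.log10(org) - math.log10(exp)


def enumerate_transmissions(risk: str, other: str):
    """Exhaustive transmission bookkeeping for a 2-haplotype system.

    Enumerates every phased mating of haplotypes {risk, other} crossed with
    every transmission choice, applying the X/Y-parent rules by hand: child
    stratum is carriage of `risk`; a parent is informative when it carries no
    copy of `risk` and is heterozygous; families where both parents carry
    `risk` are excluded.  Returns {stratum: {label: [T, NT]}} with every
    outcome weighted equally (uniform mating and transmission probabilities).
    """
    haps = (risk, other)
    out = {
        "risk_positive": {h: [0, 0] for h in haps},
        "risk_negative": {h: [0, 0] for h in haps},
    }
    for father in itertools.product(haps, repeat=2):
        for mother in itertools.product(haps, repeat=2):
            if risk in father and risk in mother:
                continue
            for fi, mi in itertools.product((0, 1), repeat=2):
                child = (father[fi], mother[mi])
                stratum = "risk_positive" if risk in child else "risk_negative"
                for pair, ti in ((father, fi), (mother, mi)):
                    if risk in pair or pair[0] == pair[1]:
                        continue
                    out[stratum][pair[ti]][0] += 1
                    out[stratum][pair[1 - ti]][1] += 1
    return out
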