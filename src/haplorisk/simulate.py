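"""Seeded generator of haplotype pools, case-control cohorts and trio families.

The generative model mirrors the assumptions under which the association and
interaction statistics are derived:

* haplotypes are atomic labels with population frequencies ``f_h`` summing
  to 1; genotypes are two independent draws (random mating, Hardy-Weinberg
  at the haplotype level);
* disease probability for genotype ``(ha, hb)`` is multiplicative,
  ``baseline_risk * rr(ha) * rr(hb)``, optionally scaled by
  ``10 ** interaction_alpha[(ha, hb)]`` — so the interaction dial is
  parameterized directly on the scale of the alpha statistic it should
  induce — and clipped to [0, 1];
* case-control cohorts are rejection-sampled to the requested quotas;
* trio families are ascertained on an affected child: parents are drawn from
  the population, each transmits one of its two haplotypes uniformly, and
  the family is kept when the child is affected.  Parental affection is
  ignored.  An unaffected sibling can be drawn from the same parents.

All sampling flows through a single :class:`numpy.random.Generator` seeded
from the config; the same seed yields byte-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import (
    CountRow,
    GenotypeCountTable,
    HaplotypeCountTable,
    TrioFamily,
    genotype_label,
    normalize_label,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "sample_genotype",
    "disease_probability",
    "generate_cohort",
    "generate_trios",
]

_MAX_BATCHES = 1000
# refuse configs whose expected number of draws to fill a quota is absurd
_MAX_EXPECTED_DRAWS = 5e7


@dataclass
class SimulationConfig:
    """Population and study-design parameters for the simulator.

    ``interaction_alpha`` maps unordered haplotype pairs (canonical ``A/B``
    genotype labels or 2-tuples) to log10 multipliers applied on top of the
    multiplicative genotype risk.
    """

    haplotype_freqs: dict[str, float]
    baseline_risk: float = 0.005
    haplotype_rr: dict[str, float] = field(default_factory=dict)
    interaction_alpha: dict[str, float] = field(default_factory=dict)
    n_cases: int = 1000
    n_controls: int = 1000
    n_families: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.haplotype_freqs = {
            normalize_label(k): float(v) for k, v in self.haplotype_freqs.items()
        }
        if abs(sum(self.haplotype_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if any(v < 0 for v in self.haplotype_freqs.values()):
            raise ValueError("haplotype frequencies must be non-negative")
        if not (0.0 < self.baseline_risk < 1.0):
            raise ValueError("baseline_risk must be in (0, 1)")
        self.haplotype_rr = {
            normalize_label(k): float(v) for k, v in self.haplotype_rr.items()
        }
        if any(v <= 0 for v in self.haplotype_rr.values()):
            raise ValueError("relative risks must be positive")
        norm: dict[str, float] = {}
        for key, val in self.interaction_alpha.items():
            if isinstance(key, str):
                pair = key
            else:
                pair = genotype_label(*key)
            norm[genotype_label(*pair.split("/"))] = float(val)
        self.interaction_alpha = norm
        unknown = (set(self.haplotype_rr) - set(self.haplotype_freqs)) | {
            h
            for g in self.interaction_alpha
            for h in g.split("/")
            if h not in self.haplotype_freqs
        }
        if unknown:
            raise ValueError(f"risk parameters for unknown haplotypes: {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return list(self.haplotype_freqs)

    def rr(self, label: str) -> float:
        return self.haplotype_rr.get(label, 1.0)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "haplotype_freqs": self.haplotype_freqs,
            "baseline_risk": self.baseline_risk,
            "haplotype_rr": self.haplotype_rr,
            "interaction_alpha": self.interaction_alpha,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_families": self.n_families,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def sample_genotype(
    freqs: dict[str, float], rng: np.random.Generator
) -> tuple[str, str]:
    """Draw one genotype: two independent haplotypes (random mating)."""
    labels = list(freqs)
    p = np.asarray(list(freqs.values()), dtype=float)
    i, j = rng.choice(len(labels), size=2, p=p / p.sum())
    return labels[i], labels[j]


def disease_probability(pair: tuple[str, str], config: SimulationConfig) -> float:
    """Penetrance of a genotype under the multiplicative-plus-interaction model."""
    ha, hb = (normalize_label(h) for h in pair)
    for h in (ha, hb):
        if h not in config.haplotype_freqs:
            raise KeyError(f"unknown haplotype {h!r}")
    risk = config.baseline_risk * config.rr(ha) * config.rr(hb)
    ia = config.interaction_alpha.get(genotype_label(ha, hb))
    if ia is not None:
        risk *= 10.0 ** ia
    if risk > 1.0:
        warnings.warn(f"penetrance for {ha}/{hb} clipped from {risk:.3g} to 1", stacklevel=2)
        risk = 1.0
    return risk


# -- vectorized internals ---------------------------------------------------


class _Model:
    """Array form of the config for fast batch sampling."""

    def __init__(self, config: SimulationConfig):
        self.labels = config.labels
        self.freqs = np.asarray([config.haplotype_freqs[l] for l in self.labels])
        self.freqs = self.freqs / self.freqs.sum()
        self.rr = np.asarray([config.rr(l) for l in self.labels])
        k = len(self.labels)
        self.inter = np.zeros((k, k))
        index = {l: i for i, l in enumerate(self.labels)}
        for glabel, a in config.interaction_alpha.items():
            ha, hb = glabel.split("/")
            i, j = index[ha], index[hb]
            self.inter[i, j] = self.inter[j, i] = a
        self.baseline = config.baseline_risk

    def sample_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(len(self.labels), size=n, p=self.freqs)

    def penetrance(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        risk = self.baseline * self.rr[h1] * self.rr[h2] * 10.0 ** self.inter[h1, h2]
        return np.minimum(risk, 1.0)


@dataclass
class SimulatedCohort:
    """Phased case-control genotypes with derivable count tables."""

    labels: list[str]
    case_h1: np.ndarray
    case_h2: np.ndarray
    control_h1: np.ndarray
    control_h2: np.ndarray

    @property
    def n_cases(self) -> int:
        return len(self.case_h1)

    @property
    def n_controls(self) -> int:
        return len(self.control_h1)

    def genotypes(self, status: str) -> list[tuple[str, str]]:
        h1, h2 = (
            (self.case_h1, self.case_h2)
            if status == "case"
            else (self.control_h1, self.control_h2)
        )
        return [(self.labels[i], self.labels[j]) for i, j in zip(h1, h2)]

    def haplotype_counts(self) -> HaplotypeCountTable:
        """Chromosome counts per haplotype; totals are 2x the individual counts."""
        k = len(self.labels)
        case = np.bincount(self.case_h1, minlength=k) + np.bincount(
            self.case_h2, minlength=k
        )
        control = np.bincount(self.control_h1, minlength=k) + np.bincount(
            self.control_h2, minlength=k
        )
        rows = [
            CountRow(lab, int(case[i]), int(control[i]))
            for i, lab in enumerate(self.labels)
        ]
        return HaplotypeCountTable(rows, 2 * self.n_cases, 2 * self.n_controls)

    def genotype_counts(self) -> GenotypeCountTable:
        """Individual counts per unordered genotype (only observed genotypes)."""
        counts: dict[str, list[int]] = {}
        for col, (h1, h2) in enumerate(
            ((self.case_h1, self.case_h2), (self.control_h1, self.control_h2))
        ):
            lo = np.minimum(h1, h2)
            hi = np.maximum(h1, h2)
            pairs, n = np.unique(np.stack([lo, hi]), axis=1, return_counts=True)
            for (i, j), c in zip(pairs.T, n):
                lab = genotype_label(self.labels[i], self.labels[j])
                counts.setdefault(lab, [0, 0])[col] += int(c)
        rows = [CountRow(lab, c[0], c[1]) for lab, c in sorted(counts.items())]
        return GenotypeCountTable(rows, self.n_cases, self.n_controls)


def generate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Rejection-sample individuals until the case and control quotas fill.

    Raises if the quotas cannot be filled within an iteration cap (e.g. a
    baseline risk so extreme that one status never occurs).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    model = _Model(config)
    need_cases, need_controls = config.n_cases, config.n_controls
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_cases = got_controls = 0
    # batch size adapted to the expected yield of the rarer status
    p_affected = float(
        (model.freqs[:, None] * model.freqs[None, :]
         * model.penetrance(*np.meshgrid(np.arange(len(model.labels)),
                                         np.arange(len(model.labels)), indexing="ij"))).sum()
    )
    n_batches = 0
    while got_cases < need_cases or got_controls < need_controls:
        n_batches += 1
        if n_batches > _MAX_BATCHES:
            raise RuntimeError(
                "could not fill case/control quotas; baseline risk too extreme"
            )
        remaining_case = max(need_cases - got_cases, 0)
        remaining_control = max(need_controls - got_controls, 0)
        if (
            remaining_case / max(p_affected, 1e-300) > _MAX_EXPECTED_DRAWS
            or remaining_control / max(1.0 - p_affected, 1e-300) > _MAX_EXPECTED_DRAWS
        ):
            raise RuntimeError(
                "could not fill case/control quotas; baseline risk too extreme"
            )
        batch = int(
            min(
                2_000_000,
                max(
                    10_000,
                    1.5 * remaining_case / max(p_affected, 1e-9),
                    1.5 * remaining_control / max(1.0 - p_affected, 1e-9),
                ),
            )
        )
        h1 = model.sample_haplotypes(batch, rng)
        h2 = model.sample_haplotypes(batch, rng)
        affected = rng.random(batch) < model.penetrance(h1, h2)
        if remaining_case:
            idx = np.flatnonzero(affected)[:remaining_case]
            cases.append(np.stack([h1[idx], h2[idx]]))
            got_cases += len(idx)
        if remaining_control:
            idx = np.flatnonzero(~affected)[:remaining_control]
            controls.append(np.stack([h1[idx], h2[idx]]))
            got_controls += len(idx)
    case = np.concatenate(cases, axis=1) if cases else np.empty((2, 0), dtype=int)
    control = (
        np.concatenate(controls, axis=1) if controls else np.empty((2, 0), dtype=int)
    )
    return SimulatedCohort(
        model.labels, case[0], case[1], control[0], control[1]
    )


def generate_trios(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    include_sibling: bool = False,
) -> list[TrioFamily]:
    """Ascertain ``config.n_families`` trio families on an affected child.

    Parents are population draws; each child receives one uniformly chosen
    haplotype per parent.  With ``include_sibling`` an additional child is
    drawn from the same parents and kept whatever its status, labelled by its
    simulated affection status (the healthy-sibling negative control).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    model = _Model(config)
    if config.n_families <= 0:
        raise ValueError("config.n_families must be positive")
    fams: list[TrioFamily] = []
    # mean child penetrance equals the population mean penetrance
    mean_pen = float(
        (model.freqs[:, None] * model.freqs[None, :]
         * model.penetrance(*np.meshgrid(np.arange(len(model.labels)),
                                         np.arange(len(model.labels)), indexing="ij"))).sum()
    )
    n_batches = 0
    while len(fams) < config.n_families:
        n_batches += 1
        if n_batches > _MAX_BATCHES:
            raise RuntimeError("could not ascertain enough affected-child families")
        remaining = config.n_families - len(fams)
        if remaining / max(mean_pen, 1e-300) > _MAX_EXPECTED_DRAWS:
            raise RuntimeError("could not ascertain enough affected-child families")
        batch = int(min(2_000_000, max(1_000, 1.5 * remaining / max(mean_pen, 1e-9))))
        f1 = model.sample_haplotypes(batch, rng)
        f2 = model.sample_haplotypes(batch, rng)
        m1 = model.sample_haplotypes(batch, rng)
        m2 = model.sample_haplotypes(batch, rng)
        from_f = np.where(rng.random(batch) < 0.5, f1, f2)
        from_m = np.where(rng.random(batch) < 0.5, m1, m2)
        affected = rng.random(batch) < model.penetrance(from_f, from_m)
        idx = np.flatnonzero(affected)[:remaining]
        if include_sibling:
            sib_f = np.where(rng.random(batch) < 0.5, f1, f2)
            sib_m = np.where(rng.random(batch) < 0.5, m1, m2)
            sib_aff = rng.random(batch) < model.penetrance(sib_f, sib_m)
        lab = model.labels
        for i in idx:
            children = [((lab[from_f[i]], lab[from_m[i]]), "affected")]
            if include_sibling:
                children.append(
                    (
                        (lab[sib_f[i]], lab[sib_m[i]]),
                        "affected" if sib_aff[i] else "unaffected",
                    )
                )
            fams.append(
                TrioFamily(
                    family_id=f"fam{len(fams) + 1:05d}",
                    father=(lab[f1[i]], lab[f2[i]]),
                    mother=(lab[m1[i]], lab[m2[i]]),
                    children=children,
                )
            )
    return fams
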