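"""Data model and file I/O for haplotype/genotype count tables and trio families.

Haplotypes at the tightly linked DRB1 and DQB1 loci are treated as atomic
string labels (e.g. ``"*03:01-*02:01"``).  A *haplotype* count table counts
chromosomes in cases and controls; a *genotype* count table counts individuals
carrying an unordered pair of haplotypes.  Displayed rows need not exhaust the
cohort totals: chromosomes carrying haplotypes below the reporting threshold
are carried implicitly in ``case_total`` / ``control_total``.

Trio families (two parents plus offspring with phased haplotype pairs) are
validated for Mendelian consistency only; statistical phasing is out of scope
and input files must already be phased.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "normalize_label",
    "genotype_label",
    "split_genotype_label",
    "CountRow",
    "HaplotypeCountTable",
    "GenotypeCountTable",
    "TrioFamily",
    "TrioValidationReport",
    "read_count_table",
    "write_count_table",
    "read_grouping_map",
    "collapse_haplogroups",
    "filter_by_frequency",
    "read_trios",
    "write_trios",
    "validate_trios",
]

# Typographic glyphs that appear in published HLA tables, mapped to ASCII.
_GLYPHS = str.maketrans({"∶": ":", "–": "-", "—": "-", "−": "-"})


def normalize_label(label: str) -> str:
    """Normalize a haplotype label to ASCII (``*03:01-*02:01`` style).

    Published tables use the ratio colon ``∶`` and en/em dashes; these are
    mapped to ``:`` and ``-`` so labels compare equal across sources.
    """
    out = label.strip().translate(_GLYPHS)
    if not out:
        raise ValueError("empty haplotype label")
    return out


def genotype_label(hap_a: str, hap_b: str) -> str:
    """Canonical label for an unordered pair of haplotypes (``A/B`` == ``B/A``)."""
    a, b = sorted((normalize_label(hap_a), normalize_label(hap_b)))
    return f"{a}/{b}"


def split_genotype_label(label: str) -> tuple[str, str]:
    """Inverse of :func:`genotype_label`; returns the sorted haplotype pair."""
    parts = normalize_label(label).split("/")
    if len(parts) != 2:
        raise ValueError(f"not a genotype label (expected 'A/B'): {label!r}")
    a, b = sorted(parts)
    return a, b


@dataclass(frozen=True)
class CountRow:
    """One haplotype (chromosome counts) or genotype (individual counts) row."""

    label: str
    case_count: int
    control_count: int


def _validate_rows(rows: Sequence[CountRow], case_total: int, control_total: int) -> None:
    if not rows:
        raise ValueError("no rows")
    seen: set[str] = set()
    for r in rows:
        if r.label in seen:
            raise ValueError(f"duplicate label: {r.label!r}")
        seen.add(r.label)
        if r.case_count < 0 or r.control_count < 0:
            raise ValueError(f"negative count in row {r.label!r}")
    if case_total <= 0 or control_total <= 0:
        raise ValueError("totals must be positive")
    if sum(r.case_count for r in rows) > case_total:
        raise ValueError("row case counts exceed case_total")
    if sum(r.control_count for r in rows) > control_total:
        raise ValueError("row control counts exceed control_total")


@dataclass
class _CountTable:
    rows: list[CountRow]
    case_total: int
    control_total: int

    def __post_init__(self) -> None:
        self.rows = [
            CountRow(normalize_label(r.label), int(r.case_count), int(r.control_count))
            for r in self.rows
        ]
        _validate_rows(self.rows, self.case_total, self.control_total)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def row(self, label: str) -> CountRow:
        label = normalize_label(label)
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def displayed_case_sum(self) -> int:
        return sum(r.case_count for r in self.rows)

    @property
    def displayed_control_sum(self) -> int:
        return sum(r.control_count for r in self.rows)

    @property
    def residual_case(self) -> int:
        """Case chromosomes/individuals in the totals but not in any row."""
        return self.case_total - self.displayed_case_sum

    @property
    def residual_control(self) -> int:
        return self.control_total - self.displayed_control_sum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "case_count": [r.case_count for r in self.rows],
                "control_count": [r.control_count for r in self.rows],
            }
        )


class HaplotypeCountTable(_CountTable):
    """Per-haplotype case/control chromosome counts with cohort totals."""


class GenotypeCountTable(_CountTable):
    """Per-genotype case/control individual counts with cohort totals.

    Row labels are canonical ``A/B`` genotype labels (unordered pairs).
    """

    def __post_init__(self) -> None:
        self.rows = [
            CountRow(genotype_label(*split_genotype_label(r.label)), r.case_count, r.control_count)
            for r in self.rows
        ]
        super().__post_init__()


CountTable = Union[HaplotypeCountTable, GenotypeCountTable]


def read_count_table(path: str | Path, kind: str = "haplotype") -> CountTable:
    """Read a TSV count table.

    Format: a header line ``label<TAB>case_count<TAB>control_count``, one row
    per haplotype/genotype, and a ``#totals<TAB><case_total>
    <TAB><control_total>`` comment line carrying the cohort totals (which may
    exceed the displayed row sums).  Parse errors report the line number.
    """
    if kind not in ("haplotype", "genotype"):
        raise ValueError(f"kind must be 'haplotype' or 'genotype', got {kind!r}")
    path = Path(path)
    rows: list[CountRow] = []
    case_total = control_total = None
    with path.open(newline="") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.lstrip("#").split("\t")
                if fields and fields[0].strip() == "totals":
                    if len(fields) != 3:
                        raise ValueError(f"{path.name}:{lineno}: malformed #totals line")
                    case_total, control_total = int(fields[1]), int(fields[2])
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields[:3]] != ["label", "case_count", "control_count"]:
                    raise ValueError(
                        f"{path.name}:{lineno}: expected header "
                        f"'label\\tcase_count\\tcontrol_count'"
                    )
                header_seen = True
                continue
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected 3 columns, got {len(fields)}")
            try:
                case_n, control_n = int(fields[1]), int(fields[2])
                if case_n < 0 or control_n < 0:
                    raise ValueError("negative count")
                rows.append(CountRow(fields[0], case_n, control_n))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path.name}: no rows")
    if case_total is None or control_total is None:
        raise ValueError(f"{path.name}: missing '#totals' line")
    cls = HaplotypeCountTable if kind == "haplotype" else GenotypeCountTable
    return cls(rows, case_total, control_total)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table in the canonical TSV layout (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"#totals\t{table.case_total}\t{table.control_total}\n")
        fh.write("label\tcase_count\tcontrol_count\n")
        for r in table.rows:
            fh.write(f"{r.label}\t{r.case_count}\t{r.control_count}\n")


def read_grouping_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping fine haplotype labels to haplogroups."""
    mapping: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            mapping[normalize_label(fields[0])] = normalize_label(fields[1])
    return mapping


def collapse_haplogroups(table: CountTable, mapping: Mapping[str, str]) -> CountTable:
    """Pool rows whose labels map to the same haplogroup.

    The map is treated as a total function: labels absent from it keep their
    own name.  Counts are summed within each group; totals are unchanged, so
    count conservation is exact.  Group order follows first appearance.
    """
    mapping = {normalize_label(k): normalize_label(v) for k, v in mapping.items()}
    grouped: dict[str, list[int]] = {}
    order: list[str] = []
    for r in table.rows:
        group = mapping.get(r.label, r.label)
        if group not in grouped:
            grouped[group] = [0, 0]
            order.append(group)
        grouped[group][0] += r.case_count
        grouped[group][1] += r.control_count
    rows = [CountRow(g, grouped[g][0], grouped[g][1]) for g in order]
    return type(table)(rows, table.case_total, table.control_total)


def filter_by_frequency(table: CountTable, threshold: float = 0.01) -> CountTable:
    """Keep rows reaching ``threshold`` frequency in cases *or* controls.

    The either-group rule: a row survives when
    ``case_count/case_total >= threshold`` or
    ``control_count/control_total >= threshold``, so a category rare in
    patients but common in controls (a candidate protective haplotype) is
    retained.  Idempotent.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    rows = [
        r
        for r in table.rows
        if r.case_count / table.case_total >= threshold
        or r.control_count / table.control_total >= threshold
    ]
    if not rows:
        raise ValueError("no rows pass the frequency threshold")
    return type(table)(rows, table.case_total, table.control_total)


# --------------------------------------------------------------------------
# Trio families


@dataclass
class TrioFamily:
    """One nuclear family with phased parental and offspring haplotype pairs.

    ``children`` holds ``(haplotype pair, status)`` tuples with status one of
    ``"affected"``, ``"unaffected"`` or ``"unknown"``.
    """

    family_id: str
    father: tuple[str, str]
    mother: tuple[str, str]
    children: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.father = (normalize_label(self.father[0]), normalize_label(self.father[1]))
        self.mother = (normalize_label(self.mother[0]), normalize_label(self.mother[1]))
        self.children = [
            ((normalize_label(p[0]), normalize_label(p[1])), status)
            for p, status in self.children
        ]

    def is_intercross(self) -> bool:
        """Both parents heterozygous for the same two haplotypes (uninformative)."""
        return (
            self.father[0] != self.father[1]
            and set(self.father) == set(self.mother)
        )

    def mendelian_assignments(
        self, child: tuple[str, str]
    ) -> list[tuple[str, str]]:
        """All consistent (paternal haplotype, maternal haplotype) assignments."""
        c1, c2 = child
        options = set()
        for pf, pm in ((c1, c2), (c2, c1)):
            if pf in self.father and pm in self.mother:
                options.add((pf, pm))
        return sorted(options)

    def is_mendelian(self, child: tuple[str, str]) -> bool:
        return bool(self.mendelian_assignments(child))


_STATUS_CODE = {"1": "unaffected", "2": "affected", "0": "unknown"}
_CODE_STATUS = {v: k for k, v in _STATUS_CODE.items()}


def read_trios(path: str | Path) -> list[TrioFamily]:
    """Read a PED-like TSV of phased trios.

    Columns: ``family_id  member(F|M|C)  hap1  hap2  status(1|2|0)``.  Parent
    rows may carry any status code; offspring status is interpreted as
    1 = unaffected, 2 = affected, 0 = unknown.
    """
    path = Path(path)
    fathers: dict[str, tuple[str, str]] = {}
    mothers: dict[str, tuple[str, str]] = {}
    kids: dict[str, list[tuple[tuple[str, str], str]]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 5:
                raise ValueError(f"{path.name}:{lineno}: expected 5 columns")
            fam, member, h1, h2, status = (f.strip() for f in fields[:5])
            if fam not in order:
                order.append(fam)
            pair = (h1, h2)
            if member == "F":
                if fam in fathers:
                    raise ValueError(f"{path.name}:{lineno}: duplicate father in family {fam}")
                fathers[fam] = pair
            elif member == "M":
                if fam in mothers:
                    raise ValueError(f"{path.name}:{lineno}: duplicate mother in family {fam}")
                mothers[fam] = pair
            elif member == "C":
                if status not in _STATUS_CODE:
                    raise ValueError(f"{path.name}:{lineno}: bad status code {status!r}")
                kids.setdefault(fam, []).append((pair, _STATUS_CODE[status]))
            else:
                raise ValueError(f"{path.name}:{lineno}: member must be F, M or C")
    families = []
    for fam in order:
        if fam not in fathers or fam not in mothers:
            raise ValueError(f"family {fam}: missing parent record")
        families.append(TrioFamily(fam, fathers[fam], mothers[fam], kids.get(fam, [])))
    return families


def write_trios(families: Iterable[TrioFamily], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        for fam in families:
            fh.write(f"{fam.family_id}\tF\t{fam.father[0]}\t{fam.father[1]}\t0\n")
            fh.write(f"{fam.family_id}\tM\t{fam.mother[0]}\t{fam.mother[1]}\t0\n")
            for pair, status in fam.children:
                fh.write(
                    f"{fam.family_id}\tC\t{pair[0]}\t{pair[1]}\t{_CODE_STATUS[status]}\n"
                )


@dataclass
class TrioValidationReport:
    """Outcome of :func:`validate_trios`; flags, never imputes."""

    consistent: list[TrioFamily]
    mendelian_errors: list[tuple[str, tuple[str, str]]]
    intercrosses: list[str]

    @property
    def n_consistent(self) -> int:
        return len(self.consistent)

    def summary(self) -> str:
        return (
            f"{self.n_consistent} consistent families, "
            f"{len(self.mendelian_errors)} Mendelian inconsistencies, "
            f"{len(self.intercrosses)} intercross (uninformative) families"
        )


def validate_trios(families: Iterable[TrioFamily]) -> TrioValidationReport:
    """Check each family for Mendelian consistency and flag intercrosses.

    A child is Mendelian-consistent when one of its haplotypes matches a
    paternal and the other a maternal haplotype.  Families in which both
    parents are heterozygous for the same haplotypes are flagged as
    intercrosses (phase of transmissions cannot be resolved); they are
    reported but still listed among the consistent families if no Mendelian
    error is present, so callers decide whether to exclude them.
    """
    consistent: list[TrioFamily] = []
    errors: list[tuple[str, tuple[str, str]]] = []
    intercrosses: list[str] = []
    for fam in families:
        ok = True
        for pair, _status in fam.children:
            if not fam.is_mendelian(pair):
                errors.append((fam.family_id, pair))
                ok = False
        if fam.is_intercross():
            intercrosses.append(fam.family_id)
        if ok:
            consistent.append(fam)
    return TrioValidationReport(consistent, errors, intercrosses)
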