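"""HLA class I nomenclature, genotypes, model populations, and allele-frequency coverage.

Every person carries six HLA class I allele slots — two each at the A, B and C
loci — and each allele presents a different slice of an antigen's peptides.
This module provides the vocabulary for that genetics: four-digit alleles
(``A*02:01``), six-slot personal genotypes, cohorts of genotyped subjects
(model populations), HLA-restriction patterns used for trial preselection,
and the allele-frequency coverage statistic used to judge how representative
a cohort is of a global frequency catalog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "HlaAllele",
    "Genotype",
    "Subject",
    "ModelPopulation",
    "AlleleFrequencyCatalog",
    "HlaRestriction",
    "CoverageResult",
    "AlleleParseError",
    "parse_allele",
    "parse_restriction",
    "matches_restriction",
    "stratify_population",
    "allele_coverage",
]

CLASS_I_LOCI = ("A", "B", "C")

#: Slot order of a complete class I genotype.
GENOTYPE_SLOTS = ("A1", "A2", "B1", "B2", "C1", "C2")


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A class I HLA allele at group ("A*02") or protein ("A*02:01") resolution.

    Parameters
    ----------
    locus : str
        One of ``A``, ``B``, ``C``.
    group : str
        Allele-group field (first numeric field), zero-padded, length >= 2.
    protein : str, optional
        Protein-designation field (second numeric field).  ``None`` means a
        group-level allele such as ``A*24``, as used in trial restriction
        columns ("A24").
    """

    locus: str
    group: str
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if self.locus not in CLASS_I_LOCI:
            raise AlleleParseError(f"unknown HLA class I locus {self.locus!r}")
        if not (self.group.isdigit() and len(self.group) >= 2):
            raise AlleleParseError(f"bad allele group field {self.group!r}")
        if self.protein is not None and not (
            self.protein.isdigit() and len(self.protein) >= 2
        ):
            raise AlleleParseError(f"bad protein field {self.protein!r}")

    @property
    def is_four_digit(self) -> bool:
        return self.protein is not None

    @property
    def group_allele(self) -> "HlaAllele":
        """This allele truncated to group resolution (A*02:01 -> A*02)."""
        return HlaAllele(self.locus, self.group)

    def __str__(self) -> str:
        if self.protein is None:
            return f"{self.locus}*{self.group}"
        return f"{self.locus}*{self.group}:{self.protein}"


_ALLELE_RE = re.compile(r"^([ABC])\*?(\d+)(?::(\d+))?$")


def parse_allele(text: str) -> HlaAllele:
    """Parse an HLA allele string in any of the common spellings.

    Accepted dialects: ``A*02:01``, ``A02:01``, ``A*0201``, ``A0201``,
    group-level ``A02``/``A*02`` and single-digit ``A2`` (normalized to
    ``A02``).  Anything else is an error, never a guess.
    """
    if not isinstance(text, str) or not text.strip():
        raise AlleleParseError("empty allele string")
    token = text.strip().upper().replace("HLA-", "")
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"cannot parse HLA allele {text!r}")
    locus, first, second = m.group(1), m.group(2), m.group(3)
    if second is not None:
        return HlaAllele(locus, first.zfill(2), second.zfill(2))
    if len(first) <= 2:
        return HlaAllele(locus, first.zfill(2))  # group-level, e.g. "A2", "A24"
    if len(first) == 4:
        return HlaAllele(locus, first[:2], first[2:])  # concatenated "A0201"
    raise AlleleParseError(f"ambiguous numeric field in HLA allele {text!r}")


@dataclass(frozen=True)
class Genotype:
    """A complete six-slot class I genotype, ordered (A1, A2, B1, B2, C1, C2).

    Homozygous loci carry duplicate slots; all downstream epitope counting
    uses :attr:`distinct_alleles`, because a homozygous allele presents the
    same peptides once.
    """

    slots: tuple[HlaAllele, HlaAllele, HlaAllele, HlaAllele, HlaAllele, HlaAllele]

    def __post_init__(self) -> None:
        if len(self.slots) != 6:
            raise ValueError("a class I genotype has exactly six allele slots")
        expected = ("A", "A", "B", "B", "C", "C")
        got = tuple(a.locus for a in self.slots)
        if got != expected:
            raise ValueError(f"slot loci must be {expected}, got {got}")
        for a in self.slots:
            if not a.is_four_digit:
                raise ValueError(f"genotype slots must be four-digit alleles, got {a}")

    @property
    def distinct_alleles(self) -> frozenset[HlaAllele]:
        return frozenset(self.slots)

    @staticmethod
    def from_strings(alleles: Sequence[str]) -> "Genotype":
        if len(alleles) != 6:
            raise ValueError("expected six allele strings (A1,A2,B1,B2,C1,C2)")
        return Genotype(tuple(parse_allele(a) for a in alleles))  # type: ignore[arg-type]


@dataclass(frozen=True)
class Subject:
    subject_id: str
    genotype: Genotype
    group_label: Optional[str] = None


@dataclass(frozen=True)
class ModelPopulation:
    """An ordered cohort of fully genotyped subjects (an in silico trial cohort)."""

    subjects: tuple[Subject, ...]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("a model population must contain at least one subject")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def distinct_alleles(self) -> frozenset[HlaAllele]:
        out: set[HlaAllele] = set()
        for s in self.subjects:
            out.update(s.genotype.distinct_alleles)
        return frozenset(out)


@dataclass(frozen=True)
class AlleleFrequencyCatalog:
    """Allele -> population frequency map (fractions; the catalog total is
    reported as-is and treated as the 100% reference)."""

    entries: Mapping[HlaAllele, float]

    def __post_init__(self) -> None:
        for allele, freq in self.entries.items():
            if freq < 0:
                raise ValueError(f"negative frequency for {allele}")

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class HlaRestriction:
    """An enrollment restriction: a disjunction of allele patterns.

    A group-level pattern (``A*02``) matches any four-digit allele in that
    group; a four-digit pattern matches exactly.  The empty restriction
    matches every genotype (no preselection).
    """

    patterns: tuple[HlaAllele, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.patterns

    def __str__(self) -> str:
        return " or ".join(str(p) for p in self.patterns) if self.patterns else "no"


_NO_RESTRICTION_TOKENS = {"", "no", "none", "all", "nan"}


def parse_restriction(text: Optional[str]) -> HlaRestriction:
    """Parse a restriction cell such as ``"A02"``, ``"A1 or A2"``, ``"A02|A24:02"``.

    Empty cells and the tokens "no"/"none"/"all" mean no preselection.
    """
    if text is None or str(text).strip().lower() in _NO_RESTRICTION_TOKENS:
        return HlaRestriction()
    parts = re.split(r"\s*(?:\bor\b|[|,;/])\s*", str(text).strip(), flags=re.IGNORECASE)
    patterns = tuple(parse_allele(p) for p in parts if p.strip())
    return HlaRestriction(patterns)


def _allele_matches_pattern(allele: HlaAllele, pattern: HlaAllele) -> bool:
    if allele.locus != pattern.locus or allele.group != pattern.group:
        return False
    if pattern.protein is None:
        return True
    return allele.protein == pattern.protein


def matches_restriction(genotype: Genotype, restriction: HlaRestriction) -> bool:
    """True iff any genotype allele matches any restriction pattern
    (vacuously true for the empty restriction)."""
    if restriction.is_empty:
        return True
    return any(
        _allele_matches_pattern(a, p)
        for a in genotype.distinct_alleles
        for p in restriction.patterns
    )


def stratify_population(
    population: ModelPopulation, restriction: HlaRestriction
) -> Optional[ModelPopulation]:
    """Retain the subjects matching an enrollment restriction, in order.

    Returns ``None`` when no subject matches (callers decide whether an
    empty stratum is an error; an in silico trial on it has no denominator).
    """
    kept = tuple(
        s for s in population.subjects if matches_restriction(s.genotype, restriction)
    )
    if not kept:
        return None
    return ModelPopulation(kept)


@dataclass(frozen=True)
class CoverageResult:
    """Summed catalog frequency of a population's distinct allele set."""

    coverage: float
    n_alleles: int
    missing: tuple[HlaAllele, ...]  # population alleles absent from the catalog

    def __float__(self) -> float:
        return self.coverage


def allele_coverage(
    population: ModelPopulation, catalog: AlleleFrequencyCatalog
) -> CoverageResult:
    """Fraction of global allele frequency covered by the population's alleles.

    Sums catalog frequencies over the distinct four-digit alleles occurring
    anywhere in the population; alleles absent from the catalog contribute 0
    and are reported in :attr:`CoverageResult.missing`.
    """
    if len(catalog) == 0:
        raise ValueError("allele-frequency catalog is empty")
    alleles = population.distinct_alleles
    covered = 0.0
    missing = []
    for a in sorted(alleles):
        if a in catalog.entries:
            covered += catalog.entries[a]
        else:
            missing.append(a)
    return CoverageResult(coverage=covered, n_alleles=len(alleles), missing=tuple(missing))
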