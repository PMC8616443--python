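"""Overlapping k-mer scanning and the peptide–HLA binding contract.

Antigens are scanned into every overlapping 9-mer window (the class I epitope
length); a :class:`BindingTable` maps (peptide, allele) pairs to predicted
percentile ranks — lower rank means stronger predicted binding, and rank <= 2
is the conventional strong-binder cutoff.  The quantity the trial layer is
built on is, per subject, the number of DISTINCT autologous alleles a peptide
is predicted to bind: promiscuous epitopes (binding >= 3 of a person's own
six alleles) are the model's predictor of real T-cell responses.

Binding predictions are pluggable: precomputed tables (e.g. exported from an
external predictor) are first-class, and a simple position-specific scoring
matrix scorer with an empirical percentile-rank transform is provided as the
built-in default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .hla import Genotype, HlaAllele, HlaRestriction, Subject

__all__ = [
    "AMINO_ACIDS",
    "Antigen",
    "Vaccine",
    "PeptideWindow",
    "BindingRecord",
    "BindingTable",
    "ScoringMatrix",
    "EpitopeHit",
    "SubjectEpitopeProfile",
    "scan_peptides",
    "matrix_percentile_rank",
    "predict_binding_table",
    "count_binding_alleles",
    "build_subject_profile",
]

#: The 20 standard residues, in the fixed column order of scoring matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_K = 9
DEFAULT_RANK_THRESHOLD = 2.0


@dataclass(frozen=True)
class Antigen:
    """A protein antigen targeted by a vaccine."""

    antigen_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq:
            raise ValueError(f"antigen {self.antigen_id!r} has an empty sequence")
        bad = set(seq) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(
                f"antigen {self.antigen_id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Vaccine:
    """One or more antigens plus the trial's HLA enrollment restriction."""

    vaccine_id: str
    antigens: tuple[Antigen, ...]
    restriction: HlaRestriction = HlaRestriction()

    def __post_init__(self) -> None:
        if not self.antigens:
            raise ValueError(f"vaccine {self.vaccine_id!r} has no antigens")
        ids = [a.antigen_id for a in self.antigens]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate antigen ids in vaccine {self.vaccine_id!r}")

    @property
    def is_multi_antigen(self) -> bool:
        return len(self.antigens) >= 2


@dataclass(frozen=True)
class PeptideWindow:
    """A k-mer window of an antigen; [start, start+k) half-open, 0-based."""

    peptide: str
    antigen_id: str
    start: int

    @property
    def scorable(self) -> bool:
        """False when the window contains a non-standard residue (e.g. X)."""
        return all(c in _AA_INDEX for c in self.peptide)


def scan_peptides(antigen: Antigen, k: int = DEFAULT_K) -> list[PeptideWindow]:
    """All overlapping k-mer windows of an antigen, in position order.

    A length-L antigen yields exactly L - k + 1 windows.  Windows containing
    a non-standard residue are emitted but flagged unscorable.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    if len(antigen) < k:
        raise ValueError(
            f"antigen {antigen.antigen_id!r} (length {len(antigen)}) is shorter "
            f"than the scan window k={k}"
        )
    seq = antigen.sequence
    return [
        PeptideWindow(seq[i : i + k], antigen.antigen_id, i)
        for i in range(len(seq) - k + 1)
    ]


@dataclass(frozen=True)
class BindingRecord:
    percentile_rank: float
    ic50_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percentile_rank <= 100.0):
            raise ValueError(
                f"percentile rank {self.percentile_rank} outside [0, 100]"
            )
        if self.ic50_nm is not None and self.ic50_nm <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50_nm}")


class BindingTable:
    """Sparse (peptide, allele) -> prediction store with a binder policy.

    A pair absent from the table is "no prediction" and counts as a
    non-binder.  The default binder policy is percentile rank <=
    ``binder_threshold`` (2.0, the strong-binder convention); setting
    ``ic50_threshold`` switches to the affinity policy IC50 < threshold
    (150 nM is the conventional strong range).
    """

    def __init__(
        self,
        records: Mapping[tuple[str, HlaAllele], BindingRecord] | None = None,
        binder_threshold: float = DEFAULT_RANK_THRESHOLD,
        ic50_threshold: Optional[float] = None,
    ) -> None:
        self.records: dict[tuple[str, HlaAllele], BindingRecord] = dict(records or {})
        self.binder_threshold = float(binder_threshold)
        self.ic50_threshold = ic50_threshold
        self._binder_sets: Optional[dict[str, frozenset[HlaAllele]]] = None

    def __len__(self) -> int:
        return len(self.records)

    def _is_binder_record(self, rec: BindingRecord) -> bool:
        if self.ic50_threshold is not None:
            return rec.ic50_nm is not None and rec.ic50_nm < self.ic50_threshold
        return rec.percentile_rank <= self.binder_threshold

    def is_binder(self, peptide: str, allele: HlaAllele) -> bool:
        rec = self.records.get((peptide, allele))
        return rec is not None and self._is_binder_record(rec)

    def binder_alleles(self, peptide: str) -> frozenset[HlaAllele]:
        """The set of alleles predicted to bind a peptide under the policy."""
        if self._binder_sets is None:
            sets: dict[str, set[HlaAllele]] = {}
            for (pep, allele), rec in self.records.items():
                if self._is_binder_record(rec):
                    sets.setdefault(pep, set()).add(allele)
            self._binder_sets = {p: frozenset(s) for p, s in sets.items()}
        return self._binder_sets.get(peptide, frozenset())

    def with_policy(
        self,
        binder_threshold: Optional[float] = None,
        ic50_threshold: Optional[float] = None,
    ) -> "BindingTable":
        """A view of the same records under a different binder policy."""
        return BindingTable(
            self.records,
            binder_threshold=self.binder_threshold
            if binder_threshold is None
            else binder_threshold,
            ic50_threshold=ic50_threshold,
        )

    @property
    def alleles(self) -> frozenset[HlaAllele]:
        return frozenset(a for (_, a) in self.records)


@dataclass(frozen=True)
class ScoringMatrix:
    """Position-specific scoring matrix for one allele, with an empirical
    percentile-rank transform.

    ``weights`` is k x 20 (columns in :data:`AMINO_ACIDS` order); a peptide's
    raw score is the sum of its per-position weights.  ``background_scores``
    is a sorted ascending sample of raw scores of background peptides; the
    percentile rank of a peptide is 100 x (fraction of background scores
    strictly greater), so rank 0 is the best possible binder.
    """

    allele: HlaAllele
    weights: np.ndarray
    background_scores: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        bg = np.asarray(self.background_scores, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(AMINO_ACIDS):
            raise ValueError("weights must be k x 20")
        if bg.size == 0:
            raise ValueError("background_scores must be non-empty")
        if np.any(np.diff(bg) < 0):
            raise ValueError("background_scores must be sorted ascending")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background_scores", bg)

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def raw_score(self, peptide: str) -> Optional[float]:
        if len(peptide) != self.k:
            raise ValueError(
                f"peptide length {len(peptide)} != matrix window {self.k}"
            )
        try:
            cols = [_AA_INDEX[c] for c in peptide]
        except KeyError:
            return None  # unscorable residue
        return float(self.weights[np.arange(self.k), cols].sum())


def matrix_percentile_rank(peptide: str, matrix: ScoringMatrix) -> Optional[float]:
    """Percentile rank of a peptide under a scoring matrix (lower = stronger).

    Returns ``None`` for unscorable peptides (non-standard residue).
    The rank is 100 x (fraction of background scores strictly greater than
    the peptide's raw score), computed on the sorted background sample.
    """
    raw = matrix.raw_score(peptide)
    if raw is None:
        return None
    bg = matrix.background_scores
    n_greater = bg.size - int(np.searchsorted(bg, raw, side="right"))
    return 100.0 * n_greater / bg.size


def predict_binding_table(
    peptides: Iterable[str],
    matrices: Sequence[ScoringMatrix],
    binder_threshold: float = DEFAULT_RANK_THRESHOLD,
) -> BindingTable:
    """Score peptides against per-allele matrices into a BindingTable.

    Unscorable peptides produce no records (hence count as non-binders).
    """
    records: dict[tuple[str, HlaAllele], BindingRecord] = {}
    for pep in set(peptides):
        for m in matrices:
            rank = matrix_percentile_rank(pep, m)
            if rank is not None:
                records[(pep, m.allele)] = BindingRecord(percentile_rank=rank)
    return BindingTable(records, binder_threshold=binder_threshold)


def count_binding_alleles(
    peptide: str, genotype: Genotype, table: BindingTable
) -> int:
    """Number of DISTINCT autologous alleles predicted to bind a peptide.

    Homozygous alleles count once (the same molecule presents the same
    peptide); absent predictions count as non-binders.
    """
    return len(genotype.distinct_alleles & table.binder_alleles(peptide))


@dataclass(frozen=True)
class EpitopeHit:
    """A qualifying epitope of one subject: a (peptide, antigen) pair together
    with the number of distinct autologous alleles it is predicted to bind."""

    peptide: str
    antigen_id: str
    n_bound: int


@dataclass(frozen=True)
class SubjectEpitopeProfile:
    """Per-subject record of every vaccine epitope binding >= 1 autologous allele."""

    subject_id: str
    hits: tuple[EpitopeHit, ...]

    def hits_at(self, hla_threshold: int) -> tuple[EpitopeHit, ...]:
        return tuple(h for h in self.hits if h.n_bound >= hla_threshold)


def build_subject_profile(
    subject: Subject,
    vaccine: Vaccine,
    table: BindingTable,
    k: int = DEFAULT_K,
) -> SubjectEpitopeProfile:
    """Scan every antigen of a vaccine against one subject's genotype.

    Epitope identity is (peptide, antigen of origin): a 9-mer repeated inside
    one antigen counts once, while the same 9-mer occurring in two antigens is
    retained once per antigen — the multi-antigen estimators depend on that
    distinction.  Only windows binding at least one autologous allele are kept.
    """
    alleles = subject.genotype.distinct_alleles
    hits: list[EpitopeHit] = []
    for antigen in vaccine.antigens:
        seen: set[str] = set()
        for window in scan_peptides(antigen, k=k):
            pep = window.peptide
            if pep in seen:
                continue
            seen.add(pep)
            n = len(alleles & table.binder_alleles(pep))
            if n >= 1:
                hits.append(EpitopeHit(pep, antigen.antigen_id, n))
    return SubjectEpitopeProfile(subject.subject_id, tuple(hits))
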