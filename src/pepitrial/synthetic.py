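"""Seeded generators for populations, antigens, binding tables and trials.

Everything the pipeline consumes can be synthesized: multi-ethnic-style
genotype sampling from a per-locus allele-frequency catalog, random protein
antigens, sparse binding tables with a planted fraction of promiscuous
(multi-allele-binding) epitopes, and trial outcomes drawn binomially around a
chosen in silico response rate.  All generators are pure functions of their
parameters and a seed; the single run seed fans out to per-component child
seeds through ``numpy.random.SeedSequence`` so adding a generator never
perturbs existing streams.

The binding model plants promiscuity explicitly: each (peptide, allele) pair
binds with a base probability equal to the binder-threshold percentile (a
rank cutoff of 2 marks ~2% of random peptides per allele, by definition of a
percentile), and once a peptide has one binding allele the remaining alleles
bind at base_binder_rate x promiscuity_boost.  The default boost of 2.8 makes
roughly a quarter of a subject's binding epitopes bind >= 2 of their alleles,
the empirically observed promiscuous fraction in genotyped cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .epitopes import (
    AMINO_ACIDS,
    Antigen,
    BindingRecord,
    BindingTable,
    Vaccine,
    scan_peptides,
)
from .hla import (
    AlleleFrequencyCatalog,
    Genotype,
    HlaAllele,
    ModelPopulation,
    Subject,
    parse_allele,
)
from .trial import IrrSpec, RatePoint, TrialRecord, in_silico_irr

__all__ = [
    "PopulationModel",
    "BindingModel",
    "TrialModel",
    "default_locus_catalogs",
    "catalog_from_locus_catalogs",
    "sample_population",
    "sample_antigens",
    "partition_total_length",
    "sample_binding_table",
    "sample_vaccine_suite",
    "simulate_trials",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan one run seed out to n independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# A compact per-locus frequency panel of globally common class I alleles.
# Frequencies are plausible order-of-magnitude values for a mixed-ethnicity
# panel, normalized at sampling time; the panel is synthetic and serves as a
# stand-in for a full allele-frequency catalog.
_DEFAULT_PANEL: dict[str, list[tuple[str, float]]] = {
    "A": [
        ("A*02:01", 0.25), ("A*01:01", 0.14), ("A*03:01", 0.12),
        ("A*24:02", 0.11), ("A*11:01", 0.09), ("A*26:01", 0.05),
        ("A*68:01", 0.04), ("A*31:01", 0.04), ("A*33:03", 0.03),
        ("A*29:02", 0.03),
    ],
    "B": [
        ("B*07:02", 0.12), ("B*08:01", 0.09), ("B*44:02", 0.08),
        ("B*35:01", 0.07), ("B*51:01", 0.07), ("B*15:01", 0.06),
        ("B*40:01", 0.06), ("B*18:01", 0.05), ("B*57:01", 0.04),
        ("B*58:01", 0.04),
    ],
    "C": [
        ("C*07:01", 0.15), ("C*07:02", 0.14), ("C*04:01", 0.12),
        ("C*06:02", 0.09), ("C*03:04", 0.08), ("C*05:01", 0.07),
        ("C*12:03", 0.06), ("C*01:02", 0.05), ("C*08:02", 0.04),
        ("C*02:02", 0.04),
    ],
}


def default_locus_catalogs() -> dict[str, AlleleFrequencyCatalog]:
    """The built-in per-locus allele panel used by the synthetic cohort sampler."""
    return {
        locus: AlleleFrequencyCatalog(
            {parse_allele(a): f for a, f in entries}
        )
        for locus, entries in _DEFAULT_PANEL.items()
    }


def catalog_from_locus_catalogs(
    locus_catalogs: Mapping[str, AlleleFrequencyCatalog],
    scale_to: float = 1.0,
) -> AlleleFrequencyCatalog:
    """Merge per-locus catalogs into one global catalog whose total is
    ``scale_to`` (each locus contributes scale_to/3, mirroring a catalog
    whose grand total over the three class I loci is treated as 1.00)."""
    entries: dict[HlaAllele, float] = {}
    per_locus = scale_to / len(locus_catalogs)
    for catalog in locus_catalogs.values():
        total = catalog.total
        for allele, f in catalog.entries.items():
            entries[allele] = per_locus * f / total
    return AlleleFrequencyCatalog(entries)


@dataclass(frozen=True)
class PopulationModel:
    """Genotype sampler: two independent draws per locus from each locus's
    frequency catalog (homozygosity allowed, loci unlinked)."""

    catalogs: Mapping[str, AlleleFrequencyCatalog]
    size: int
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.catalogs) != {"A", "B", "C"}:
            raise ValueError("catalogs must cover exactly loci A, B, C")
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        for locus, cat in self.catalogs.items():
            if len(cat) == 0 or cat.total <= 0:
                raise ValueError(f"locus {locus}: empty or zero-total catalog")


def sample_population(model: PopulationModel) -> ModelPopulation:
    """Draw a genotyped cohort; deterministic under a fixed seed."""
    rng = np.random.default_rng(model.seed)
    locus_pools: dict[str, tuple[list[HlaAllele], np.ndarray]] = {}
    for locus in ("A", "B", "C"):
        cat = model.catalogs[locus]
        alleles = sorted(cat.entries)
        freqs = np.array([cat.entries[a] for a in alleles], dtype=float)
        locus_pools[locus] = (alleles, freqs / freqs.sum())
    subjects = []
    for i in range(model.size):
        slots: list[HlaAllele] = []
        for locus in ("A", "B", "C"):
            alleles, probs = locus_pools[locus]
            picks = rng.choice(len(alleles), size=2, p=probs)
            slots.extend(alleles[j] for j in picks)
        subjects.append(Subject(f"S{i:05d}", Genotype(tuple(slots))))
    return ModelPopulation(tuple(subjects))


def sample_antigens(
    count: int,
    length_range: tuple[int, int] = (50, 400),
    seed: int = 0,
    prefix: str = "AG",
) -> list[Antigen]:
    """Random protein antigens with uniform residues over the 20-letter alphabet."""
    lo, hi = length_range
    if lo < 9:
        raise ValueError("minimum antigen length must be >= 9 (one 9-mer window)")
    if hi < lo or count < 1:
        raise ValueError("bad antigen count or length range")
    rng = np.random.default_rng(seed)
    out = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for i in range(count):
        length = int(rng.integers(lo, hi + 1))
        seq = bytes(aa[rng.integers(0, len(AMINO_ACIDS), size=length)]).decode()
        out.append(Antigen(f"{prefix}{i:03d}", seq))
    return out


def partition_total_length(
    total: int, count: int, seed: int = 0, min_length: int = 9
) -> list[int]:
    """Split a total amino-acid length into ``count`` antigen lengths, each
    >= min_length, summing exactly to ``total`` (seeded)."""
    if total < count * min_length:
        raise ValueError("total too small for the requested antigen count")
    rng = np.random.default_rng(seed)
    spare = total - count * min_length
    cuts = np.sort(rng.integers(0, spare + 1, size=count - 1))
    parts = np.diff(np.concatenate([[0], cuts, [spare]]))
    return [int(p) + min_length for p in parts]


@dataclass(frozen=True)
class BindingModel:
    """Planted-promiscuity binding sampler.

    base_binder_rate: probability that a given allele binds a given peptide
    in the first pass (default 0.02, the mass below a percentile-rank cutoff
    of 2).  promiscuity_boost: once a peptide has >= 1 binding allele, each
    remaining allele binds with base_binder_rate x promiscuity_boost
    (capped at 1), planting multi-allele epitopes.  Binder ranks are drawn
    uniformly below the threshold, so every stored record passes the policy.
    """

    base_binder_rate: float = 0.02
    promiscuity_boost: float = 2.8
    binder_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_binder_rate <= 1.0:
            raise ValueError("base_binder_rate must be in [0, 1]")
        if self.promiscuity_boost < 0:
            raise ValueError("promiscuity_boost must be >= 0")


def sample_binding_table(
    alleles: Sequence[HlaAllele],
    peptides: Sequence[str],
    model: BindingModel,
) -> BindingTable:
    """Draw a sparse binder table over peptides x alleles.

    Only binder records are stored (an absent pair is a non-binder, matching
    the table policy), with percentile ranks uniform on [0, threshold).
    """
    if not alleles or not peptides:
        raise ValueError("alleles and peptides must be non-empty")
    alleles = list(dict.fromkeys(alleles))
    peptides = list(dict.fromkeys(peptides))
    rng = np.random.default_rng(model.seed)
    n_pep, n_al = len(peptides), len(alleles)
    base = rng.random((n_pep, n_al)) < model.base_binder_rate
    boosted_p = min(1.0, model.base_binder_rate * model.promiscuity_boost)
    extra = rng.random((n_pep, n_al)) < boosted_p
    has_binder = base.any(axis=1)
    binds = base | (extra & has_binder[:, None])
    ranks = rng.uniform(0.0, model.binder_threshold, size=(n_pep, n_al))
    records: dict[tuple[str, HlaAllele], BindingRecord] = {}
    rows, cols = np.nonzero(binds)
    for i, j in zip(rows.tolist(), cols.tolist()):
        records[(peptides[i], alleles[j])] = BindingRecord(
            percentile_rank=float(ranks[i, j])
        )
    return BindingTable(records, binder_threshold=model.binder_threshold)


def sample_vaccine_suite(
    n_vaccines: int,
    alleles: Sequence[HlaAllele],
    seed: int = 0,
    antigens_per_vaccine: tuple[int, int] = (2, 3),
    antigen_length_range: tuple[int, int] = (45, 75),
    binder_rate_range: tuple[float, float] = (0.005, 0.05),
    promiscuity_boost: float = 2.8,
    k: int = 9,
) -> tuple[list[Vaccine], dict[str, BindingTable]]:
    """A suite of synthetic vaccines with per-vaccine binding tables.

    Each vaccine gets its own base binder rate drawn from
    ``binder_rate_range``, creating a realistic spread of true population
    response rates across vaccines (some broadly immunogenic, some barely).
    Returns the vaccines and a vaccine_id -> BindingTable mapping.
    """
    seeds = _child_seeds(seed, 3 * n_vaccines)
    rng = np.random.default_rng(_child_seeds(seed + 1, 1)[0])
    vaccines: list[Vaccine] = []
    tables: dict[str, BindingTable] = {}
    lo_n, hi_n = antigens_per_vaccine
    for v in range(n_vaccines):
        n_ag = int(rng.integers(lo_n, hi_n + 1))
        ags = sample_antigens(
            n_ag, antigen_length_range, seed=seeds[3 * v], prefix=f"V{v:02d}_AG"
        )
        vaccine = Vaccine(f"VAC{v:03d}", tuple(ags))
        rate = float(rng.uniform(*binder_rate_range))
        peptides = sorted(
            {w.peptide for a in ags for w in scan_peptides(a, k=k)}
        )
        table = sample_binding_table(
            alleles,
            peptides,
            BindingModel(
                base_binder_rate=rate,
                promiscuity_boost=promiscuity_boost,
                seed=seeds[3 * v + 1],
            ),
        )
        vaccines.append(vaccine)
        tables[vaccine.vaccine_id] = table
    return vaccines, tables


@dataclass(frozen=True)
class TrialModel:
    """Outcome sampler: measured responders ~ Binomial(cohort, true in silico
    rate) under ``truth_spec`` — trials with known ground truth."""

    truth_spec: IrrSpec
    cohort_size: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cohort_size
        if lo < 1 or hi < lo:
            raise ValueError("cohort_size range must satisfy 1 <= lo <= hi")


def simulate_trials(
    population: ModelPopulation,
    vaccines: Sequence[Vaccine],
    trial_model: TrialModel,
    tables: BindingTable | Mapping[str, BindingTable],
    k: int = 9,
) -> list[TrialRecord]:
    """Simulate one measured trial per vaccine.

    For each vaccine the true response probability is its in silico rate over
    the population under ``truth_spec``; the measured responder count is a
    binomial draw at that probability.  ``tables`` may be a single shared
    binding table or a per-vaccine mapping.
    """
    if not vaccines:
        raise ValueError("no vaccines to simulate")
    rng = np.random.default_rng(trial_model.seed)
    lo, hi = trial_model.cohort_size
    records = []
    for vaccine in vaccines:
        table = (
            tables[vaccine.vaccine_id] if isinstance(tables, Mapping) else tables
        )
        truth = in_silico_irr(
            population, vaccine, table, trial_model.truth_spec, k=k
        ).rate
        cohort = int(rng.integers(lo, hi + 1))
        responders = int(rng.binomial(cohort, truth))
        records.append(
            TrialRecord(
                trial_id=f"TR_{vaccine.vaccine_id}",
                vaccine_id=vaccine.vaccine_id,
                irr=RatePoint(responders, cohort),
                restriction=vaccine.restriction,
            )
        )
    return records
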