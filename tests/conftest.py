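"""Shared fixtures: tiny deterministic cohorts, vaccines and binding tables."""

import pytest

from pepitrial.epitopes import Antigen, BindingRecord, BindingTable, Vaccine
from pepitrial.hla import Genotype, ModelPopulation, Subject, parse_allele


def genotype(*alleles: str) -> Genotype:
    return Genotype.from_strings(list(alleles))


@pytest.fixture
def geno_het() -> Genotype:
    """A fully heterozygous genotype (six distinct alleles)."""
    return genotype("A*02:01", "A*24:02", "B*07:02", "B*08:01", "C*07:01", "C*04:01")


@pytest.fixture
def geno_hom_a() -> Genotype:
    """Homozygous at A (A*02:01/A*02:01): five distinct alleles."""
    return genotype("A*02:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*04:01")


@pytest.fixture
def small_population(geno_het, geno_hom_a) -> ModelPopulation:
    third = genotype("A*01:01", "A*03:01", "B*44:02", "B*35:01", "C*06:02", "C*03:04")
    return ModelPopulation(
        (
            Subject("s1", geno_het),
            Subject("s2", geno_hom_a),
            Subject("s3", third),
        )
    )


def binding_table(entries, threshold=2.0) -> BindingTable:
    """entries: iterable of (peptide, allele_str, rank[, ic50])."""
    records = {}
    for entry in entries:
        pep, allele, rank = entry[0], entry[1], entry[2]
        ic50 = entry[3] if len(entry) > 3 else None
        records[(pep, parse_allele(allele))] = BindingRecord(rank, ic50)
    return BindingTable(records, binder_threshold=threshold)


@pytest.fixture
def one_window_vaccine() -> Vaccine:
    return Vaccine("vax1", (Antigen("ag1", "ACDEFGHIK"),))
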