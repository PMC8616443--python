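"""The in silico trial: population-level response-rate estimators.

An in silico immune response rate (IRR) is the fraction of a genotyped model
population predicted to respond to a vaccine.  Twelve estimators form the
standard battery — the cross of three breadth requirements with four HLA
promiscuity thresholds n = 1..4:

==============================  ===========  ===========  =================
estimator family                #epitopes    #antigens    HLA threshold n
==============================  ===========  ===========  =================
IRR (n x HLA)                   >= 1         >= 1         1, 2, 3, 4
multi-epitope IRR (n x HLA)     >= 2         >= 1         1, 2, 3, 4
multi-Ag IRR (n x HLA)          >= 2         >= 2         1, 2, 3, 4
==============================  ===========  ===========  =================

A subject qualifies under a spec when their profile holds enough epitopes,
from enough distinct antigens, each binding at least n of their own distinct
HLA class I alleles.  Thresholds n = 5, 6 are computable but flagged
out-of-grid (too few such epitopes exist per person for stable rates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as _sps

from .epitopes import (
    DEFAULT_K,
    BindingTable,
    SubjectEpitopeProfile,
    Vaccine,
    build_subject_profile,
    count_binding_alleles,
    scan_peptides,
)
from .hla import HlaRestriction, ModelPopulation, stratify_population

__all__ = [
    "IrrSpec",
    "RatePoint",
    "TrialRecord",
    "DEFAULT_BATTERY",
    "subject_qualifies",
    "build_profiles",
    "irr_from_profiles",
    "in_silico_irr",
    "run_trial_battery",
    "per_peptide_irrs",
    "combine_cohorts",
    "prob_zero_responders",
]

#: Out-of-grid HLA thresholds: computable but excluded from the default battery.
OUT_OF_GRID_THRESHOLDS = (5, 6)


@dataclass(frozen=True, order=True)
class IrrSpec:
    """Which response-rate estimator to compute.

    min_epitopes >= 1 qualifying epitopes, from min_antigens >= 1 distinct
    antigens, each binding >= hla_threshold distinct autologous alleles.
    """

    min_epitopes: int = 1
    min_antigens: int = 1
    hla_threshold: int = 1

    def __post_init__(self) -> None:
        if self.min_epitopes < 1 or self.min_antigens < 1:
            raise ValueError("min_epitopes and min_antigens must be >= 1")
        if self.min_antigens > self.min_epitopes:
            raise ValueError(
                "min_antigens > min_epitopes is unsatisfiable "
                "(each qualifying antigen contributes at least one epitope)"
            )
        if not 1 <= self.hla_threshold <= 6:
            raise ValueError("hla_threshold must be in 1..6")

    @property
    def out_of_grid(self) -> bool:
        return self.hla_threshold in OUT_OF_GRID_THRESHOLDS

    @property
    def family(self) -> str:
        if self.min_antigens >= 2:
            return "multi-Ag IRR"
        if self.min_epitopes >= 2:
            return "multi-epitope IRR"
        return "IRR"

    def __str__(self) -> str:
        return f"{self.family} ({self.hla_threshold}×HLA)"


#: The twelve standard estimators: three families x n in 1..4.
DEFAULT_BATTERY: tuple[IrrSpec, ...] = tuple(
    IrrSpec(min_epitopes=e, min_antigens=a, hla_threshold=n)
    for (e, a) in ((1, 1), (2, 1), (2, 2))
    for n in (1, 2, 3, 4)
)


@dataclass(frozen=True)
class RatePoint:
    """An exact numerator/denominator response rate."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ValueError("denominator must be >= 1")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"numerator {self.numerator} outside [0, {self.denominator}]"
            )

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({100 * self.rate:.1f}%)"


@dataclass(frozen=True)
class TrialRecord:
    """A published (or simulated) trial outcome: measured immune and/or
    clinical response rates with their sample sizes."""

    trial_id: str
    vaccine_id: str
    irr: Optional[RatePoint] = None
    crr: Optional[RatePoint] = None
    restriction: HlaRestriction = HlaRestriction()
    per_peptide: bool = False

    def __post_init__(self) -> None:
        if self.irr is None and self.crr is None:
            raise ValueError(
                f"trial {self.trial_id!r}: at least one of IRR/CRR must be present"
            )


def subject_qualifies(profile: SubjectEpitopeProfile, spec: IrrSpec) -> bool:
    """Does one subject count as a predicted responder under a spec?"""
    qualifying = profile.hits_at(spec.hla_threshold)
    if len(qualifying) < spec.min_epitopes:
        return False
    return len({h.antigen_id for h in qualifying}) >= spec.min_antigens


def build_profiles(
    population: ModelPopulation,
    vaccine: Vaccine,
    table: BindingTable,
    k: int = DEFAULT_K,
) -> list[SubjectEpitopeProfile]:
    return [build_subject_profile(s, vaccine, table, k=k) for s in population]


def irr_from_profiles(
    profiles: Sequence[SubjectEpitopeProfile], spec: IrrSpec
) -> RatePoint:
    n = sum(1 for p in profiles if subject_qualifies(p, spec))
    return RatePoint(n, len(profiles))


def _maybe_stratify(
    population: ModelPopulation, vaccine: Vaccine, stratify: bool
) -> ModelPopulation:
    if not stratify or vaccine.restriction.is_empty:
        return population
    stratum = stratify_population(population, vaccine.restriction)
    if stratum is None:
        raise ValueError(
            f"no subject matches restriction {vaccine.restriction} "
            f"for vaccine {vaccine.vaccine_id!r}: empty denominator"
        )
    return stratum


def in_silico_irr(
    population: ModelPopulation,
    vaccine: Vaccine,
    table: BindingTable,
    spec: IrrSpec,
    k: int = DEFAULT_K,
    stratify: bool = False,
) -> RatePoint:
    """One in silico response rate over a model population.

    With ``stratify=True`` the population is first filtered to the vaccine's
    HLA restriction (trial preselection); the retained subjects' full six-allele
    genotypes still count toward the HLA threshold — preselection narrows who
    is enrolled, never which autologous alleles may present.
    """
    cohort = _maybe_stratify(population, vaccine, stratify)
    return irr_from_profiles(build_profiles(cohort, vaccine, table, k=k), spec)


def run_trial_battery(
    population: ModelPopulation,
    vaccine: Vaccine,
    table: BindingTable,
    k: int = DEFAULT_K,
    stratify: bool = False,
    grid: Sequence[IrrSpec] = DEFAULT_BATTERY,
) -> pd.DataFrame:
    """All twelve standard estimators for one vaccine, as a tidy table.

    Columns: vaccine_id, family, min_epitopes, min_antigens, hla_threshold,
    numerator, denominator, rate, flags.  For a single-antigen vaccine the
    multi-antigen rows are structurally zero and flagged ``not_applicable``.
    """
    cohort = _maybe_stratify(population, vaccine, stratify)
    profiles = build_profiles(cohort, vaccine, table, k=k)
    rows = []
    for spec in grid:
        point = irr_from_profiles(profiles, spec)
        flags = []
        if spec.min_antigens >= 2 and not vaccine.is_multi_antigen:
            flags.append("not_applicable")
        if spec.out_of_grid:
            flags.append("out_of_grid")
        rows.append(
            {
                "vaccine_id": vaccine.vaccine_id,
                "family": spec.family,
                "min_epitopes": spec.min_epitopes,
                "min_antigens": spec.min_antigens,
                "hla_threshold": spec.hla_threshold,
                "numerator": point.numerator,
                "denominator": point.denominator,
                "rate": point.rate,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def per_peptide_irrs(
    population: ModelPopulation,
    vaccine: Vaccine,
    table: BindingTable,
    spec: IrrSpec,
    mode: str = "antigen",
    k: int = DEFAULT_K,
    stratify: bool = False,
) -> dict[str, RatePoint]:
    """Per-peptide response rates, for trials reporting immunogenicity peptide
    by peptide.

    mode="antigen" treats each antigen as one administered peptide (a subject
    responds to it if any of its k-mer windows passes the HLA threshold);
    mode="window" rates every distinct scan window separately.  Requires a
    single-epitope spec: per-peptide reporting is single-epitope by
    construction.
    """
    if spec.min_epitopes != 1 or spec.min_antigens != 1:
        raise ValueError("per-peptide mode requires a single-epitope spec")
    if mode not in ("antigen", "window"):
        raise ValueError(f"unknown per-peptide mode {mode!r}")
    cohort = _maybe_stratify(population, vaccine, stratify)
    n_subjects = len(cohort)
    out: dict[str, RatePoint] = {}
    if mode == "antigen":
        for antigen in vaccine.antigens:
            peptides = {w.peptide for w in scan_peptides(antigen, k=k)}
            n = sum(
                1
                for s in cohort
                if any(
                    count_binding_alleles(p, s.genotype, table) >= spec.hla_threshold
                    for p in peptides
                )
            )
            out[antigen.antigen_id] = RatePoint(n, n_subjects)
    else:
        peptides = {
            w.peptide for a in vaccine.antigens for w in scan_peptides(a, k=k)
        }
        for p in sorted(peptides):
            n = sum(
                1
                for s in cohort
                if count_binding_alleles(p, s.genotype, table) >= spec.hla_threshold
            )
            out[p] = RatePoint(n, n_subjects)
    return out


def combine_cohorts(pairs: Iterable[tuple[int, int]]) -> RatePoint:
    """Pool several trials of the same vaccine into one rate:
    sum of responders over sum of analyzed subjects."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no cohorts to combine")
    num = 0
    den = 0
    for responders, total in pairs:
        if not 0 <= responders <= total:
            raise ValueError(f"responders {responders} outside [0, {total}]")
        num += responders
        den += total
    return RatePoint(num, den)


def prob_zero_responders(n_subjects: int, true_rate: float) -> float:
    """Probability that none of n independent subjects responds when the true
    per-subject response probability is ``true_rate`` — the binomial point
    mass at zero, used to judge implausibly discordant trial replicates."""
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError("true_rate must be in [0, 1]")
    return float(_sps.binom.pmf(0, n_subjects, true_rate))
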