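"""Readers and writers for the pipeline's plain-text formats.

Formats: antigens as FASTA; genotypes, allele frequencies, trial records and
data pairs as comma-separated CSV with a required header; binding tables as
tab-separated TSV.  Antigen coordinates are 0-based half-open internally and
1-based inclusive in human-readable reports.  Every CLI run also writes a
JSON manifest (configuration, seeds, input digests) sufficient to reproduce
deterministic outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .epitopes import Antigen, BindingRecord, BindingTable
from .hla import (
    AlleleFrequencyCatalog,
    Genotype,
    HlaRestriction,
    ModelPopulation,
    Subject,
    parse_allele,
    parse_restriction,
)
from .trial import RatePoint, TrialRecord
from .stats import DataPair

__all__ = [
    "RunConfig",
    "read_antigens",
    "write_antigens",
    "read_genotypes",
    "write_genotypes",
    "read_allele_frequencies",
    "write_allele_frequencies",
    "read_binding_table",
    "write_binding_table",
    "read_trial_records",
    "read_data_pairs",
    "write_data_pairs",
    "write_manifest",
]

GENOTYPE_COLUMNS = ["subject_id", "A1", "A2", "B1", "B2", "C1", "C2"]


@dataclass
class RunConfig:
    """Run parameters recorded into every manifest.

    Defaults: 9-mer windows, percentile-rank binder cutoff 2.0, HLA-threshold
    grid n in 1..4.
    """

    k: int = 9
    binder_threshold: float = 2.0
    ic50_threshold: Optional[float] = None
    hla_grid: tuple[int, ...] = (1, 2, 3, 4)
    stratify: bool = False
    seed: int = 0


def read_antigens(path: str | Path) -> list[Antigen]:
    """Load antigens from FASTA (record id = antigen_id).

    Sequences are uppercased; trailing/embedded ``*`` stop characters are
    stripped with a warning.  Duplicate ids or an empty file are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    antigens = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate antigen id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(
                f"antigen {rec.id!r}: stripping '*' stop character(s)",
                stacklevel=2,
            )
            seq = seq.replace("*", "")
        antigens.append(Antigen(rec.id, seq))
    return antigens


def write_antigens(antigens: Sequence[Antigen], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.antigen_id, description="")
        for a in antigens
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes(path: str | Path) -> ModelPopulation:
    """Load a genotyped cohort from CSV.

    Required columns: subject_id, A1, A2, B1, B2, C1, C2; optional
    group_label.  Allele cells accept all the nomenclature dialects of
    :func:`pepitrial.hla.parse_allele`.  Missing allele cells, malformed
    alleles and duplicate subject ids are errors naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing genotype columns {missing}")
    subjects = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        cells = [row[c] for c in GENOTYPE_COLUMNS[1:]]
        if any(pd.isna(c) or not str(c).strip() for c in cells):
            raise ValueError(f"{path} row {rownum}: incomplete genotype")
        try:
            genotype = Genotype.from_strings([str(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path} row {rownum}: {exc}") from exc
        label = row.get("group_label")
        subjects.append(
            Subject(
                str(row["subject_id"]),
                genotype,
                None if pd.isna(label) else str(label),
            )
        )
    try:
        return ModelPopulation(tuple(subjects))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_genotypes(population: ModelPopulation, path: str | Path) -> None:
    rows = []
    for s in population:
        row = {"subject_id": s.subject_id}
        row.update(
            {c: str(a) for c, a in zip(GENOTYPE_COLUMNS[1:], s.genotype.slots)}
        )
        if s.group_label is not None:
            row["group_label"] = s.group_label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_allele_frequencies(path: str | Path) -> AlleleFrequencyCatalog:
    """Load an allele-frequency catalog from CSV (columns: allele, frequency)."""
    df = pd.read_csv(path)
    for col in ("allele", "frequency"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    entries = {
        parse_allele(str(row.allele)): float(row.frequency)
        for row in df.itertuples()
    }
    return AlleleFrequencyCatalog(entries)


def write_allele_frequencies(
    catalog: AlleleFrequencyCatalog, path: str | Path
) -> None:
    df = pd.DataFrame(
        sorted(
            ((str(a), f) for a, f in catalog.entries.items()),
        ),
        columns=["allele", "frequency"],
    )
    df.to_csv(path, index=False)


def read_binding_table(
    path: str | Path,
    binder_threshold: float = 2.0,
    ic50_threshold: Optional[float] = None,
) -> BindingTable:
    """Load a binding-prediction TSV (columns: peptide, allele,
    percentile_rank[, ic50_nm]).

    Duplicate (peptide, allele) rows keep the best (lowest) rank with a
    warning; a rank outside [0, 100] is a hard error naming the row.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "allele", "percentile_rank"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    has_ic50 = "ic50_nm" in df.columns
    records: dict[tuple[str, object], BindingRecord] = {}
    n_dupes = 0
    for idx, row in df.iterrows():
        rownum = idx + 2
        rank = float(row["percentile_rank"])
        if not 0.0 <= rank <= 100.0:
            raise ValueError(
                f"{path} row {rownum}: percentile rank {rank} outside [0, 100]"
            )
        ic50 = None
        if has_ic50 and not pd.isna(row["ic50_nm"]):
            ic50 = float(row["ic50_nm"])
        key = (str(row["peptide"]), parse_allele(str(row["allele"])))
        rec = BindingRecord(percentile_rank=rank, ic50_nm=ic50)
        if key in records:
            n_dupes += 1
            if rec.percentile_rank < records[key].percentile_rank:
                records[key] = rec
        else:
            records[key] = rec
    if n_dupes:
        warnings.warn(
            f"{path}: {n_dupes} duplicate (peptide, allele) row(s); "
            "kept the lowest rank",
            stacklevel=2,
        )
    return BindingTable(
        records, binder_threshold=binder_threshold, ic50_threshold=ic50_threshold
    )


def write_binding_table(table: BindingTable, path: str | Path) -> None:
    rows = [
        {
            "peptide": pep,
            "allele": str(allele),
            "percentile_rank": rec.percentile_rank,
            "ic50_nm": rec.ic50_nm,
        }
        for (pep, allele), rec in sorted(
            table.records.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
        )
    ]
    df = pd.DataFrame(rows, columns=["peptide", "allele", "percentile_rank", "ic50_nm"])
    df.to_csv(path, sep="\t", index=False)


def _optional_rate(row, num_col: str, den_col: str) -> Optional[RatePoint]:
    num, den = row.get(num_col), row.get(den_col)
    if pd.isna(num) or pd.isna(den):
        return None
    return RatePoint(int(num), int(den))


def read_trial_records(path: str | Path) -> list[TrialRecord]:
    """Load a trial-records CSV: trial_id, vaccine_id, irr_responders,
    irr_total, crr_responders, crr_total, restriction, per_peptide.
    Empty response cells mean "not reported"."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        per_pep = row.get("per_peptide")
        records.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                vaccine_id=str(row["vaccine_id"]),
                irr=_optional_rate(row, "irr_responders", "irr_total"),
                crr=_optional_rate(row, "crr_responders", "crr_total"),
                restriction=parse_restriction(
                    None if pd.isna(row.get("restriction")) else str(row["restriction"])
                ),
                per_peptide=bool(per_pep) and not pd.isna(per_pep),
            )
        )
    return records


def read_data_pairs(path: str | Path) -> list[DataPair]:
    """Load measured/predicted data pairs (columns: label,
    measured_responders, measured_total, predicted_numerator,
    predicted_denominator)."""
    df = pd.read_csv(path)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            DataPair(
                label=str(row["label"]),
                measured=RatePoint(
                    int(row["measured_responders"]), int(row["measured_total"])
                ),
                predicted=RatePoint(
                    int(row["predicted_numerator"]),
                    int(row["predicted_denominator"]),
                ),
            )
        )
    return pairs


def write_data_pairs(pairs: Sequence[DataPair], path: str | Path) -> None:
    rows = [
        {
            "label": p.label,
            "measured_responders": p.measured.numerator,
            "measured_total": p.measured.denominator,
            "predicted_numerator": p.predicted.numerator,
            "predicted_denominator": p.predicted.denominator,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    config: RunConfig,
    inputs: Mapping[str, str | Path] = (),
    extra: Mapping[str, object] | None = None,
) -> None:
    """Write the reproducibility manifest for a run (JSON)."""
    from . import __version__

    manifest: dict[str, object] = {
        "tool": "pepitrial",
        "version": __version__,
        "coordinates": "0-based half-open internally; 1-based inclusive in reports",
        "config": asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in dict(inputs).items()
        },
    }
    if extra:
        manifest["extra"] = dict(extra)
    Path(out_path).write_text(json.dumps(manifest, indent=2, default=str))
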