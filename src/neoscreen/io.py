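"""Readers and writers for the tables and sequence files the pipeline touches.

Conventions
-----------
* Protein coordinates are 1-based throughout, matching mutation labels such
  as ``HHAT_L75F``.
* Tables are tab-separated UTF-8 with a mandatory header row; lines starting
  with ``#`` are comments.
* Parsers never silently drop rows: readers that can reject rows return the
  rejections alongside the accepted records, with a reason per row.
* JSON reports carry a schema version and round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .neoepitope import AllelePrediction, SomaticMutation
from .repertoire import ClonotypeRead

REPORT_SCHEMA_VERSION = "1.0"

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}


@dataclass(frozen=True)
class ProteomeRecord:
    """One protein sequence, keyed by the first token of its FASTA header."""

    protein_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET_X
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid residues {sorted(bad)} "
                "(allowed: 20 standard amino acids plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_proteome(path: str | Path) -> dict[str, ProteomeRecord]:
    """Read a protein FASTA into a mapping of protein_id -> record.

    Sequences are upper-cased; identifiers are the first whitespace-delimited
    token of each header. Duplicate identifiers and empty files are errors.
    """
    records: dict[str, ProteomeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in records:
            raise ValueError(f"duplicate protein id in proteome: {pid}")
        records[pid] = ProteomeRecord(protein_id=pid, sequence=str(rec.seq).upper())
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str


def read_mutation_table(
    path: str | Path,
    proteome: dict[str, ProteomeRecord] | None = None,
) -> tuple[list[SomaticMutation], list[RejectedRow]]:
    """Read a somatic missense mutation table.

    Required columns: patient_id, gene, protein_id, position (1-based),
    ref_aa, alt_aa. Rows where ref_aa == alt_aa (synonymous) are rejected
    with a reason rather than raising. If a proteome is supplied, positions
    are cross-checked against protein length and reference residue, and a
    mismatch is a hard error.

    Returns ``(mutations, rejected)``; the caller can verify that
    ``len(mutations) + len(rejected)`` equals the input row count.
    """
    df = _read_tsv(path, ["patient_id", "gene", "protein_id", "position", "ref_aa", "alt_aa"])
    mutations: list[SomaticMutation] = []
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        pos = int(row["position"])
        if pos < 1:
            raise ValueError(f"{path} row {idx}: position {pos} is not 1-based")
        if row["ref_aa"] == row["alt_aa"]:
            rejected.append(RejectedRow(int(idx), f"synonymous change {row['ref_aa']}=={row['alt_aa']}"))
            continue
        mut = SomaticMutation(
            patient_id=row["patient_id"],
            gene=row["gene"],
            protein_id=row["protein_id"],
            position=pos,
            ref_aa=row["ref_aa"],
            alt_aa=row["alt_aa"],
        )
        if proteome is not None:
            protein = proteome.get(mut.protein_id)
            if protein is None:
                raise ValueError(f"{path} row {idx}: unknown protein {mut.protein_id}")
            mut.validate_against(protein.sequence)
        mutations.append(mut)
    return mutations, rejected


def read_affinity_table(path: str | Path) -> list[AllelePrediction]:
    """Read predicted (peptide, allele, IC50 nM) rows."""
    df = _read_tsv(path, ["peptide", "allele", "ic50_nm"])
    preds = []
    for idx, row in df.iterrows():
        try:
            ic50 = float(row["ic50_nm"])
        except ValueError as exc:
            raise ValueError(f"{path} row {idx}: non-numeric ic50_nm {row['ic50_nm']!r}") from exc
        preds.append(AllelePrediction(peptide=row["peptide"], allele=row["allele"], ic50_nm=ic50))
    return preds


def write_affinity_table(preds: list[AllelePrediction], path: str | Path) -> None:
    pd.DataFrame(
        {"peptide": [p.peptide for p in preds],
         "allele": [p.allele for p in preds],
         "ic50_nm": [repr(p.ic50_nm) for p in preds]}
    ).to_csv(path, sep="\t", index=False)


def read_repertoire_table(path: str | Path) -> list[ClonotypeRead]:
    """Read TCR amplicon reads (nt sequence, read count, chain, compartment)."""
    df = _read_tsv(path, ["sequence_nt", "read_count", "chain", "compartment"])
    reads = []
    for idx, row in df.iterrows():
        count = int(row["read_count"])
        if count < 1:
            raise ValueError(f"{path} row {idx}: read_count {count} < 1")
        reads.append(
            ClonotypeRead(
                sequence_nt=row["sequence_nt"],
                read_count=count,
                chain=row["chain"],
                compartment=row["compartment"],
                v_segment=row.get("v_segment") or None,
                j_segment=row.get("j_segment") or None,
            )
        )
    return reads


def write_repertoire_table(reads: list[ClonotypeRead], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sequence_nt": [r.sequence_nt for r in reads],
            "read_count": [r.read_count for r in reads],
            "chain": [r.chain for r in reads],
            "compartment": [r.compartment for r in reads],
            "v_segment": [r.v_segment or "" for r in reads],
            "j_segment": [r.j_segment or "" for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def write_report(results: dict, path: str | Path, seed: int | None = None) -> None:
    """Write a versioned JSON report; the seed of the run is always recorded."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "seed": seed}
    doc.update(results)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported report schema {doc.get('schema_version')!r}")
    return doc
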