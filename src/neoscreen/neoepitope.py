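"""Candidate neo-epitope enumeration and MHC-I binding-affinity filtering.

A somatic missense mutation in a protein of length N gives rise, for each
peptide length L, to every length-L window that lies fully inside the protein
and covers the mutated position — at most L windows, fewer near the termini.
The mutant peptide carries the altered residue; its wild-type counterpart is
the unsubstituted window. Candidates are then filtered against predicted
peptide–HLA affinities, keeping (peptide, allele) pairs with IC50 <= 500 nM
(inclusive) restricted to the patient's own HLA class-I alleles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SomaticMutation:
    """One protein-level missense change in one patient.

    ``position`` is 1-based; ``label`` is auto-built as gene_refPOSalt
    (e.g. HHAT_L75F) when not given.
    """

    patient_id: str
    gene: str
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str = ""

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.gene} position {self.position}: ref_aa equals alt_aa (synonymous)")
        if self.position < 1:
            raise ValueError(f"position must be 1-based and positive, got {self.position}")
        if not self.label:
            self.label = f"{self.gene}_{self.ref_aa}{self.position}{self.alt_aa}"

    def validate_against(self, sequence: str) -> None:
        """Check the mutation is consistent with its protein sequence."""
        if self.position > len(sequence):
            raise ValueError(
                f"{self.label}: position {self.position} outside protein "
                f"{self.protein_id} (length {len(sequence)})"
            )
        found = sequence[self.position - 1]
        if found != self.ref_aa:
            raise ValueError(
                f"{self.label}: protein {self.protein_id} has {found} at position "
                f"{self.position}, expected {self.ref_aa}"
            )


@dataclass(frozen=True)
class CandidatePeptide:
    """A mutant 9/10-mer with its wild-type counterpart.

    ``mut_offset`` is the 1-based position of the altered residue within the
    peptide; mutant and wild type differ at exactly that position.
    """

    mutant_seq: str
    wt_seq: str
    length: int
    mut_offset: int
    source: SomaticMutation

    def __post_init__(self):
        if len(self.mutant_seq) != self.length or len(self.wt_seq) != self.length:
            raise ValueError("peptide length mismatch")
        if not 1 <= self.mut_offset <= self.length:
            raise ValueError("mut_offset out of range")
        diffs = [i for i in range(self.length) if self.mutant_seq[i] != self.wt_seq[i]]
        if diffs != [self.mut_offset - 1]:
            raise ValueError("mutant and wild-type peptides must differ at exactly mut_offset")
        if self.mutant_seq[self.mut_offset - 1] != self.source.alt_aa:
            raise ValueError("mutant peptide does not carry alt_aa at mut_offset")
        if self.wt_seq[self.mut_offset - 1] != self.source.ref_aa:
            raise ValueError("wild-type peptide does not carry ref_aa at mut_offset")


@dataclass(frozen=True)
class AllelePrediction:
    """Predicted binding affinity of one peptide to one HLA-I allele, in nM."""

    peptide: str
    allele: str
    ic50_nm: float

    def __post_init__(self):
        if not self.ic50_nm > 0:
            raise ValueError(f"ic50_nm must be positive, got {self.ic50_nm}")


@dataclass(frozen=True)
class FilteredCandidate:
    """A candidate retained by the affinity filter for one allele."""

    candidate: CandidatePeptide
    allele: str
    ic50_nm: float


def enumerate_mutant_peptides(
    protein: "ProteomeRecord",
    mutation: SomaticMutation,
    lengths: Iterable[int] = (9, 10),
) -> tuple[list[CandidatePeptide], int]:
    """Enumerate every full-length mutant window covering the mutated residue.

    For each length L the windows run from start position
    max(1, position-L+1) to min(position, N-L+1) so that each window lies
    fully inside the protein and contains the altered residue; windows that
    would be truncated by a protein end are omitted, not padded. Peptides
    containing 'X' (unknown residue, unsynthesizable) are excluded and
    tallied.

    Returns ``(candidates, n_rejected_nonstandard)``.
    """
    seq = protein.sequence
    mutation.validate_against(seq)
    pos0 = mutation.position - 1  # 0-based
    mutant_protein = seq[:pos0] + mutation.alt_aa + seq[pos0 + 1:]
    candidates: list[CandidatePeptide] = []
    n_rejected = 0
    for length in sorted(set(int(l) for l in lengths)):
        first = max(0, pos0 - length + 1)
        last = min(pos0, len(seq) - length)  # last valid 0-based window start
        for start in range(first, last + 1):
            wt = seq[start:start + length]
            mut = mutant_protein[start:start + length]
            if set(mut) - STANDARD_AA or set(wt) - STANDARD_AA:
                n_rejected += 1
                continue
            candidates.append(
                CandidatePeptide(
                    mutant_seq=mut,
                    wt_seq=wt,
                    length=length,
                    mut_offset=pos0 - start + 1,
                    source=mutation,
                )
            )
    return candidates, n_rejected


def pair_wildtype(
    candidates: Iterable[CandidatePeptide],
) -> dict[str, dict]:
    """Deduplicate mutant peptides for the synthesis list, keeping provenance.

    Candidates from one patient are pooled by mutant sequence: each unique
    mutant peptide appears once, mapped to its wild-type counterpart and to
    every source mutation that produced it.
    """
    pooled: dict[str, dict] = {}
    for cand in candidates:
        entry = pooled.setdefault(
            cand.mutant_seq, {"wt_seq": cand.wt_seq, "sources": []}
        )
        entry["sources"].append(cand.source)
    return pooled


def apply_affinity_filter(
    candidates: Iterable[CandidatePeptide],
    predictions: Iterable[AllelePrediction],
    patient_alleles: set[str],
    threshold_nm: float = 500.0,
) -> tuple[list[FilteredCandidate], int]:
    """Retain (candidate, allele) pairs with IC50 <= threshold (inclusive).

    Only the patient's own HLA alleles are considered. Candidates whose
    mutant sequence has no prediction for any patient allele are tallied as
    unpredicted. Output is sorted by ascending IC50 (ties by peptide then
    allele, for determinism).

    Returns ``(retained, n_unpredicted)``.
    """
    if not patient_alleles:
        raise ValueError("patient_alleles must be non-empty")
    by_peptide: dict[str, list[AllelePrediction]] = defaultdict(list)
    for pred in predictions:
        if pred.allele in patient_alleles:
            by_peptide[pred.peptide].append(pred)

    retained: list[FilteredCandidate] = []
    n_unpredicted = 0
    for cand in candidates:
        preds = by_peptide.get(cand.mutant_seq)
        if not preds:
            n_unpredicted += 1
            continue
        for pred in preds:
            if pred.ic50_nm <= threshold_nm:
                retained.append(
                    FilteredCandidate(candidate=cand, allele=pred.allele, ic50_nm=pred.ic50_nm)
                )
    retained.sort(key=lambda fc: (fc.ic50_nm, fc.candidate.mutant_seq, fc.allele))
    return retained, n_unpredicted


def predicted_load(
    filtered_by_patient: dict[str, list[FilteredCandidate]],
) -> dict:
    """Per-patient predicted neo-epitope counts and cohort summary.

    Counts unique retained mutant peptides per patient (a peptide binding
    several alleles counts once); the (peptide, allele) pair count is
    reported alongside since both readings of a cohort total are of
    interest. Patients with zero retained peptides participate in the range.
    """
    per_patient = {}
    for patient, hits in filtered_by_patient.items():
        unique_peptides = {fc.candidate.mutant_seq for fc in hits}
        per_patient[patient] = {
            "unique_peptides": len(unique_peptides),
            "peptide_allele_pairs": len({(fc.candidate.mutant_seq, fc.allele) for fc in hits}),
        }
    counts = [v["unique_peptides"] for v in per_patient.values()]
    summary = {
        "per_patient": per_patient,
        "total_unique_peptides": sum(counts),
        "total_peptide_allele_pairs": sum(v["peptide_allele_pairs"] for v in per_patient.values()),
        "range": [min(counts), max(counts)] if counts else [0, 0],
    }
    return summary


def candidates_to_frame(hits: Iterable[FilteredCandidate]) -> pd.DataFrame:
    """Tabulate retained candidates for TSV export."""
    rows = [
        {
            "patient_id": fc.candidate.source.patient_id,
            "label": fc.candidate.source.label,
            "mutant_seq": fc.candidate.mutant_seq,
            "wt_seq": fc.candidate.wt_seq,
            "length": fc.candidate.length,
            "mut_offset": fc.candidate.mut_offset,
            "allele": fc.allele,
            "ic50_nm": fc.ic50_nm,
        }
        for fc in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "label", "mutant_seq", "wt_seq", "length",
                 "mut_offset", "allele", "ic50_nm"],
    )
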