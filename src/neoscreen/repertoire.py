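"""TCR clonotype construction, cross-compartment tracking and V–J usage.

Amplicon reads are processed in three steps: translate each nucleotide
sequence in reading frame 1; discard out-of-frame reads (length not a
multiple of 3, or a stop codon in the translation); pool reads coding for
the same protein sequence into clonotypes and drop those below the read
floor (default 2 — single-read TCRs are not considered). Clonotype identity
is (chain, translated protein sequence); V/J segment names are annotations.

Reading frame 1 is assumed because the amplicons are primer-anchored; a
3-frame rescue can be enabled for unanchored input.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class ClonotypeRead:
    """One distinct amplicon nucleotide sequence with its read count."""

    sequence_nt: str
    read_count: int
    chain: str = "beta"
    compartment: str = "PBL"
    v_segment: str | None = None
    j_segment: str | None = None

    def __post_init__(self):
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class Clonotype:
    """Reads pooled by identical translated protein sequence."""

    protein_seq: str
    chain: str
    read_count: int
    frequency: float
    v_segment: str | None = None
    j_segment: str | None = None


@dataclass
class Repertoire:
    """Clonotypes of one compartment plus full read accounting.

    ``total_reads_in`` equals retained reads plus every discarded category,
    so no read is ever silently dropped; frequencies are computed over
    retained reads and sum to 1.
    """

    compartment: str
    clonotypes: list[Clonotype]
    total_reads_in: int
    reads_discarded_outframe: int = 0
    reads_discarded_invalid: int = 0
    reads_discarded_singleton: int = 0

    @property
    def retained_reads(self) -> int:
        return sum(c.read_count for c in self.clonotypes)

    def check_conservation(self) -> None:
        total = (self.retained_reads + self.reads_discarded_outframe
                 + self.reads_discarded_invalid + self.reads_discarded_singleton)
        if total != self.total_reads_in:
            raise AssertionError(
                f"read conservation violated in {self.compartment}: "
                f"{total} accounted vs {self.total_reads_in} in"
            )


@dataclass(frozen=True)
class TranslatedRead:
    read: ClonotypeRead
    protein_seq: str


def translate_and_filter(
    reads: Iterable[ClonotypeRead],
    three_frame_rescue: bool = False,
) -> tuple[list[TranslatedRead], dict[str, int]]:
    """Translate reads in frame 1 and drop out-of-frame ones.

    A read is out-of-frame when its length is not a multiple of 3 or its
    translation contains a stop codon. With ``three_frame_rescue`` the two
    shifted frames are tried before a read is discarded. Reads with
    characters outside A/C/G/T are rejected under their own tally. Tallies
    are in read-count units.

    Returns ``(translated_reads, tallies)`` with tallies keyed
    ``out_of_frame`` and ``invalid_chars``.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("reads must be non-empty")
    translated: list[TranslatedRead] = []
    tallies = {"out_of_frame": 0, "invalid_chars": 0}
    for read in reads:
        seq = read.sequence_nt.upper()
        if set(seq) - NT_ALPHABET:
            tallies["invalid_chars"] += read.read_count
            continue
        frames = [0, 1, 2] if three_frame_rescue else [0]
        protein = None
        for offset in frames:
            sub = seq[offset:]
            if len(sub) % 3 != 0 or not sub:
                continue
            aa = str(Seq(sub).translate())
            if "*" not in aa:
                protein = aa
                break
        if protein is None:
            tallies["out_of_frame"] += read.read_count
            continue
        translated.append(TranslatedRead(read=read, protein_seq=protein))
    return translated, tallies


def build_clonotypes(
    translated: list[TranslatedRead],
    min_reads: int = 2,
    compartment: str | None = None,
    prior_tallies: dict[str, int] | None = None,
    extra_input_reads: int = 0,
) -> Repertoire:
    """Pool translated reads into clonotypes and apply the read floor.

    Reads with identical protein sequence (within one chain and compartment)
    are pooled and their counts summed; pooled clonotypes below ``min_reads``
    are removed and tallied (the singleton rule at the default of 2 — the
    floor applies after pooling). Frequencies are computed over retained
    reads. Clonotypes are ordered by descending count, ties broken by
    lexicographic protein sequence. V/J annotations are taken by majority
    read vote within the pool.
    """
    if translated:
        compartments = {t.read.compartment for t in translated}
        chains = {t.read.chain for t in translated}
        if len(compartments) > 1 or len(chains) > 1:
            raise ValueError("all reads must share one compartment and one chain")
        compartment = compartment or next(iter(compartments))
        chain = next(iter(chains))
    else:
        compartment = compartment or "unknown"
        chain = "beta"

    pooled: dict[str, list[TranslatedRead]] = defaultdict(list)
    for t in translated:
        pooled[t.protein_seq].append(t)

    clonotypes: list[tuple[str, int, str | None, str | None]] = []
    n_singleton_reads = 0
    for protein, members in pooled.items():
        count = sum(m.read.read_count for m in members)
        if count < min_reads:
            n_singleton_reads += count
            continue
        votes: dict[tuple, int] = defaultdict(int)
        for m in members:
            votes[(m.read.v_segment, m.read.j_segment)] += m.read.read_count
        (v_seg, j_seg), _ = max(votes.items(), key=lambda kv: (kv[1], str(kv[0])))
        clonotypes.append((protein, count, v_seg, j_seg))

    clonotypes.sort(key=lambda c: (-c[1], c[0]))
    retained_total = sum(c[1] for c in clonotypes)
    prior = prior_tallies or {}
    total_in = (sum(t.read.read_count for t in translated)
                + prior.get("out_of_frame", 0) + prior.get("invalid_chars", 0)
                + extra_input_reads)
    rep = Repertoire(
        compartment=compartment,
        clonotypes=[
            Clonotype(
                protein_seq=p, chain=chain, read_count=c,
                frequency=c / retained_total if retained_total else 0.0,
                v_segment=v, j_segment=j,
            )
            for p, c, v, j in clonotypes
        ],
        total_reads_in=total_in,
        reads_discarded_outframe=prior.get("out_of_frame", 0),
        reads_discarded_invalid=prior.get("invalid_chars", 0),
        reads_discarded_singleton=n_singleton_reads,
    )
    rep.check_conservation()
    return rep


def build_repertoire(
    reads: Iterable[ClonotypeRead],
    min_reads: int = 2,
    three_frame_rescue: bool = False,
) -> Repertoire:
    """Full pipeline: translate, filter out-of-frame, pool, apply read floor."""
    translated, tallies = translate_and_filter(reads, three_frame_rescue=three_frame_rescue)
    return build_clonotypes(translated, min_reads=min_reads, prior_tallies=tallies)


@dataclass(frozen=True)
class TrackingResult:
    """Presence of one specific clonotype in one bulk compartment."""

    protein_seq: str
    chain: str
    compartment: str
    present: bool
    frequency: float
    rank: int | None
    below_lod: bool
    uninformative: bool = False


def track_clonotypes(
    specific: Iterable[Clonotype],
    bulk: Iterable[Repertoire],
    lod_fraction: float = 1e-5,
) -> list[TrackingResult]:
    """Track specific clonotypes (e.g. from multimer-sorted cells) in bulk.

    For each specific clonotype, keyed by (chain, protein sequence), and each
    bulk repertoire: presence, frequency, and dense rank (1 = most frequent,
    ties broken lexicographically). An absent clonotype gets frequency 0 and
    is marked ``below_lod`` only when the repertoire is too shallow to have
    detected it at the LOD fraction (1/total reads > lod_fraction) —
    otherwise the absence stands on its own. Empty bulk repertoires yield
    uninformative absences.
    """
    results: list[TrackingResult] = []
    bulk = list(bulk)
    ranked: dict[str, dict[tuple[str, str], tuple[float, int]]] = {}
    for rep in bulk:
        ordered = sorted(rep.clonotypes, key=lambda c: (-c.frequency, c.protein_seq))
        table: dict[tuple[str, str], tuple[float, int]] = {}
        rank = 0
        prev_freq = None
        for c in ordered:
            if c.frequency != prev_freq:
                rank += 1
                prev_freq = c.frequency
            table[(c.chain, c.protein_seq)] = (c.frequency, rank)
        ranked[rep.compartment] = table

    for clone in specific:
        key = (clone.chain, clone.protein_seq)
        for rep in bulk:
            hit = ranked[rep.compartment].get(key)
            if rep.total_reads_in == 0 or not rep.clonotypes:
                results.append(TrackingResult(
                    protein_seq=clone.protein_seq, chain=clone.chain,
                    compartment=rep.compartment, present=False, frequency=0.0,
                    rank=None, below_lod=True, uninformative=True,
                ))
            elif hit is not None:
                freq, rank = hit
                results.append(TrackingResult(
                    protein_seq=clone.protein_seq, chain=clone.chain,
                    compartment=rep.compartment, present=True, frequency=freq,
                    rank=rank, below_lod=False,
                ))
            else:
                too_shallow = 1.0 / rep.total_reads_in > lod_fraction
                results.append(TrackingResult(
                    protein_seq=clone.protein_seq, chain=clone.chain,
                    compartment=rep.compartment, present=False, frequency=0.0,
                    rank=None, below_lod=too_shallow,
                ))
    return results


@dataclass
class SegmentReference:
    """Chromosomal ordering of V and J segments for one chain.

    Maps segment name to order index; indices must be unique within each
    class so the V×J matrix axes are well defined.
    """

    v_order: dict[str, int]
    j_order: dict[str, int]
    chain: str = "beta"

    def __post_init__(self):
        for cls, mapping in (("V", self.v_order), ("J", self.j_order)):
            if len(set(mapping.values())) != len(mapping):
                raise ValueError(f"{cls} segment order indices must be unique")


def vj_usage(
    repertoire: Repertoire,
    segments: SegmentReference,
) -> tuple[pd.DataFrame, float]:
    """Summed clonotype frequency per (V, J) recombination.

    Rows are V segments and columns J segments, both in chromosomal order.
    Clonotypes lacking either annotation are excluded from the matrix and
    their summed frequency returned separately; an annotated segment missing
    from the reference is an error naming the segment.
    """
    v_names = sorted(segments.v_order, key=segments.v_order.get)
    j_names = sorted(segments.j_order, key=segments.j_order.get)
    matrix = pd.DataFrame(0.0, index=v_names, columns=j_names)
    unannotated = 0.0
    for clone in repertoire.clonotypes:
        if clone.v_segment is None or clone.j_segment is None:
            unannotated += clone.frequency
            continue
        if clone.v_segment not in segments.v_order:
            raise KeyError(f"V segment {clone.v_segment!r} not in reference")
        if clone.j_segment not in segments.j_order:
            raise KeyError(f"J segment {clone.j_segment!r} not in reference")
        matrix.loc[clone.v_segment, clone.j_segment] += clone.frequency
    return matrix, unannotated


def diversity_summary(repertoire: Repertoire, top_n: int = 10) -> dict:
    """Clonotype count, read totals and top-N clonotype frequencies."""
    freqs = sorted((c.frequency for c in repertoire.clonotypes), reverse=True)
    return {
        "compartment": repertoire.compartment,
        "n_clonotypes": len(repertoire.clonotypes),
        "retained_reads": repertoire.retained_reads,
        "total_reads_in": repertoire.total_reads_in,
        "top_frequencies": freqs[:top_n],
        "dominance": freqs[0] if freqs else 0.0,
    }
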