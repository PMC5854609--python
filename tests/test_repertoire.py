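"""Clonotype construction, tracking and V-J usage against group-by oracles."""

from collections import defaultdict

import numpy as np
import pytest
from Bio.Seq import Seq

from neoscreen.repertoire import (
    Clonotype,
    ClonotypeRead,
    Repertoire,
    SegmentReference,
    build_clonotypes,
    build_repertoire,
    diversity_summary,
    track_clonotypes,
    translate_and_filter,
    vj_usage,
)


def _read(nt, count=2, **kw):
    return ClonotypeRead(sequence_nt=nt, read_count=count, **kw)


class TestTranslateAndFilter:
    def test_in_frame_translation(self):
        translated, tallies = translate_and_filter([_read("ATGGCT")])
        assert translated[0].protein_seq == "MA"
        assert tallies == {"out_of_frame": 0, "invalid_chars": 0}

    def test_stop_codon_is_out_of_frame(self):
        translated, tallies = translate_and_filter([_read("ATGTAAGCT", count=3)])
        assert not translated and tallies["out_of_frame"] == 3

    def test_length_not_multiple_of_three(self):
        translated, tallies = translate_and_filter([_read("ATGGCTA", count=2)])
        assert not translated and tallies["out_of_frame"] == 2

    def test_invalid_characters_own_tally(self):
        translated, tallies = translate_and_filter([_read("ATGNCT", count=4)])
        assert not translated
        assert tallies == {"out_of_frame": 0, "invalid_chars": 4}

    def test_three_frame_rescue(self):
        # frame 1 hits a stop; frame 2 is clean
        nt = "G" + "ATGGCTAAG"  # 10 nt: frame 1 invalid length
        assert not translate_and_filter([_read(nt)])[0]
        translated, _ = translate_and_filter([_read(nt)], three_frame_rescue=True)
        assert translated and translated[0].protein_seq == "MAK"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            translate_and_filter([])


class TestBuildClonotypes:
    def test_synonymous_reads_pool_to_one_clonotype(self):
        # GCT and GCC both code A: counts 3 + 4 pool to 7
        reads = [_read("ATGGCT", count=3), _read("ATGGCC", count=4)]
        rep = build_repertoire(reads)
        assert len(rep.clonotypes) == 1
        clone = rep.clonotypes[0]
        assert clone.protein_seq == "MA" and clone.read_count == 7
        assert clone.frequency == 1.0

    def test_singleton_rule_removes_pooled_count_one(self):
        reads = [_read("ATGGCT", count=1), _read("ATGAAA", count=5)]
        rep = build_repertoire(reads)
        assert [c.protein_seq for c in rep.clonotypes] == ["MK"]
        assert rep.reads_discarded_singleton == 1

    def test_floor_applies_after_pooling(self):
        # two single-read synonymous variants pool to 2 and survive
        reads = [_read("ATGGCT", count=1), _read("ATGGCC", count=1)]
        rep = build_repertoire(reads)
        assert len(rep.clonotypes) == 1 and rep.clonotypes[0].read_count == 2

    def test_empty_retained_set_is_valid(self):
        rep = build_repertoire([_read("ATGGCT", count=1)])
        assert rep.clonotypes == [] and rep.reads_discarded_singleton == 1
        rep.check_conservation()

    def test_mixed_compartments_rejected(self):
        reads = [_read("ATGGCT", compartment="PBL"), _read("ATGAAA", compartment="TIL")]
        with pytest.raises(ValueError):
            build_repertoire(reads)

    def test_random_reads_match_groupby_oracle(self):
        rng = np.random.default_rng(21)
        codons = ["GCT", "GCC", "AAA", "AAG", "TGG", "GAT", "GAC"]
        reads = []
        for _ in range(300):
            nt = "".join(rng.choice(codons) for _ in range(rng.integers(3, 6)))
            reads.append(_read(nt, count=int(rng.integers(1, 9))))
        rep = build_repertoire(reads, min_reads=2)

        # oracle: brute-force group-by over translations
        groups = defaultdict(int)
        for r in reads:
            groups[str(Seq(r.sequence_nt).translate())] += r.read_count
        kept = {p: c for p, c in groups.items() if c >= 2}
        assert {c.protein_seq: c.read_count for c in rep.clonotypes} == kept
        total = sum(kept.values())
        for c in rep.clonotypes:
            assert c.frequency == pytest.approx(c.read_count / total)
        rep.check_conservation()

    def test_pooling_idempotence(self):
        rng = np.random.default_rng(8)
        codons = ["GCT", "GCC", "AAA", "TGG"]
        reads = [_read("".join(rng.choice(codons) for _ in range(4)),
                       count=int(rng.integers(1, 6))) for _ in range(100)]
        rep1 = build_repertoire(reads, min_reads=2)
        # re-feed one read per clonotype with its pooled count
        reads2 = [_read("".join({"A": "GCT", "K": "AAA", "W": "TGG"}[aa] for aa in c.protein_seq),
                        count=c.read_count) for c in rep1.clonotypes]
        rep2 = build_repertoire(reads2, min_reads=2)
        assert {(c.protein_seq, c.read_count) for c in rep1.clonotypes} == \
               {(c.protein_seq, c.read_count) for c in rep2.clonotypes}

    def test_deterministic_ordering(self):
        reads = [_read("ATGGCT", count=3), _read("ATGAAA", count=3), _read("TGGTGG", count=9)]
        rep = build_repertoire(reads)
        assert [c.protein_seq for c in rep.clonotypes] == ["WW", "MA", "MK"]


def _bulk(compartment, clones, total=None):
    retained = sum(c[1] for c in clones)
    total = total if total is not None else retained
    return Repertoire(
        compartment=compartment,
        clonotypes=[Clonotype(protein_seq=p, chain="beta", read_count=n,
                              frequency=n / retained) for p, n in clones],
        total_reads_in=total,
    )


class TestTracking:
    def test_absent_in_deep_repertoire_not_excused_by_lod(self):
        bulk = _bulk("PBL", [("AAAA", 999_990), ("CCCC", 10)], total=1_000_000)
        spec = [Clonotype(protein_seq="WWWW", chain="beta", read_count=5, frequency=1.0)]
        res = track_clonotypes(spec, [bulk], lod_fraction=1e-5)[0]
        assert not res.present and not res.below_lod

    def test_absent_in_shallow_repertoire_excused(self):
        bulk = _bulk("PBL", [("AAAA", 100)], total=100)
        spec = [Clonotype(protein_seq="WWWW", chain="beta", read_count=5, frequency=1.0)]
        res = track_clonotypes(spec, [bulk], lod_fraction=1e-5)[0]
        assert not res.present and res.below_lod

    def test_rank_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        clones = [(f"CL{i:03d}", int(rng.integers(1, 1000))) for i in range(50)]
        bulk = _bulk("tumor", clones)
        spec = [Clonotype(protein_seq=p, chain="beta", read_count=1, frequency=1.0)
                for p, _ in clones[:10]]
        results = {r.protein_seq: r for r in track_clonotypes(spec, [bulk])}
        # oracle: dense rank over distinct frequencies
        freqs = sorted({n for _, n in clones}, reverse=True)
        for p, n in clones[:10]:
            assert results[p].rank == freqs.index(n) + 1
            assert results[p].present

    def test_row_order_invariance(self):
        clones = [("AAA", 10), ("CCC", 5), ("DDD", 1)]
        spec = [Clonotype(protein_seq="CCC", chain="beta", read_count=1, frequency=1.0)]
        a = track_clonotypes(spec, [_bulk("PBL", clones)])
        b = track_clonotypes(spec, [_bulk("PBL", clones[::-1])])
        assert a == b

    def test_empty_repertoire_uninformative(self):
        bulk = Repertoire(compartment="TIL", clonotypes=[], total_reads_in=0)
        spec = [Clonotype(protein_seq="AAA", chain="beta", read_count=1, frequency=1.0)]
        res = track_clonotypes(spec, [bulk])[0]
        assert res.uninformative and not res.present

    def test_compartment_discordance_pattern(self):
        # present in sorted-TIL-derived list and tumor, absent in PBL
        tumor = _bulk("tumor", [("SPEC", 100), ("BG", 900)])
        pbl = _bulk("PBL", [("BG", 1000)])
        spec = [Clonotype(protein_seq="SPEC", chain="beta", read_count=50, frequency=1.0)]
        res = {r.compartment: r for r in track_clonotypes(spec, [tumor, pbl])}
        assert res["tumor"].present and not res["PBL"].present


class TestVjUsage:
    def _ref(self):
        return SegmentReference(v_order={"TRBV1": 0, "TRBV2": 1},
                                j_order={"TRBJ1": 0, "TRBJ2": 1})

    def test_single_clonotype_single_cell(self):
        rep = Repertoire("PBL", [Clonotype("AAA", "beta", 10, 1.0, "TRBV2", "TRBJ1")], 10)
        matrix, unannotated = vj_usage(rep, self._ref())
        assert matrix.loc["TRBV2", "TRBJ1"] == 1.0
        assert matrix.values.sum() == 1.0 and unannotated == 0.0

    def test_total_equals_annotated_fraction(self):
        rep = Repertoire("PBL", [
            Clonotype("AAA", "beta", 6, 0.6, "TRBV1", "TRBJ2"),
            Clonotype("CCC", "beta", 4, 0.4, None, None),
        ], 10)
        matrix, unannotated = vj_usage(rep, self._ref())
        assert matrix.values.sum() == pytest.approx(0.6)
        assert unannotated == pytest.approx(0.4)

    def test_marginals_match_per_v_summation(self):
        rng = np.random.default_rng(2)
        clones, freq_left = [], 1.0
        for i in range(20):
            f = freq_left if i == 19 else float(rng.uniform(0, freq_left / 2))
            freq_left -= f if i < 19 else freq_left
            clones.append(Clonotype(f"C{i}", "beta", 1, f,
                                    f"TRBV{rng.integers(1, 3)}", f"TRBJ{rng.integers(1, 3)}"))
        rep = Repertoire("PBL", clones, 20)
        matrix, _ = vj_usage(rep, self._ref())
        for v in ("TRBV1", "TRBV2"):
            direct = sum(c.frequency for c in clones if c.v_segment == v)
            assert matrix.loc[v].sum() == pytest.approx(direct)

    def test_unknown_segment_named_in_error(self):
        rep = Repertoire("PBL", [Clonotype("AAA", "beta", 10, 1.0, "TRBV9", "TRBJ1")], 10)
        with pytest.raises(KeyError, match="TRBV9"):
            vj_usage(rep, self._ref())

    def test_duplicate_order_index_rejected(self):
        with pytest.raises(ValueError):
            SegmentReference(v_order={"A": 0, "B": 0}, j_order={})


class TestDiversity:
    def test_empty_repertoire(self):
        rep = Repertoire("PBL", [], 0)
        assert diversity_summary(rep)["n_clonotypes"] == 0

    def test_hundred_equal_clones(self):
        clones = [Clonotype(f"C{i:03d}", "beta", 5, 0.01) for i in range(100)]
        rep = Repertoire("PBL", clones, 500)
        summary = diversity_summary(rep)
        assert summary["n_clonotypes"] == 100
        assert all(f == pytest.approx(0.01) for f in summary["top_frequencies"])


class TestConservation:
    def test_read_conservation_random_inputs(self):
        rng = np.random.default_rng(17)
        codons = ["GCT", "AAA", "TGG", "TAA"]  # includes a stop codon
        for _ in range(10):
            reads = []
            for _ in range(200):
                nt = "".join(rng.choice(codons) for _ in range(rng.integers(2, 5)))
                if rng.random() < 0.1:
                    nt += "A"  # frame break
                if rng.random() < 0.05:
                    nt = nt[:-1] + "N"  # invalid character
                reads.append(_read(nt, count=int(rng.integers(1, 10))))
            rep = build_repertoire(reads)
            total_in = sum(r.read_count for r in reads)
            assert rep.total_reads_in == total_in
            rep.check_conservation()
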