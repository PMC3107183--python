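import math

import numpy as np
import pytest

import importlib

se = importlib.import_module("teharvest.search")
from teharvest.seqio import Genome, LibraryEntry, revcomp
from tests.conftest import random_dna


class TestTranslation:
    def test_forward_frame_one(self):
        frames = {f.frame: f for f in se.translate_six_frames("ATGAAA")}
        assert frames[1].aa == "MK"

    def test_forward_frame_two_hits_stop(self):
        # hand-translated: frame +2 reads TGA|AA -> one codon, a stop
        frames = {f.frame: f for f in se.translate_six_frames("ATGAAA")}
        assert frames[2].aa == "*"

    def test_n_codon_translates_to_x(self):
        frames = {f.frame: f for f in se.translate_six_frames("ATGNNN")}
        assert frames[1].aa == "MX"

    def test_reverse_frame_coordinate_map(self):
        # hand-derived: 9 bp input, frame -1, aa index 0 covers the last codon
        frames = {f.frame: f for f in se.translate_six_frames("AAACCCGGG")}
        assert frames[-1].aa_to_nt(0, 1) == (6, 9)

    def test_coordinate_map_roundtrip_against_translation(self):
        nt = "ATGGCCAAATTTGGGCCCTAA"
        for ft in se.translate_six_frames(nt):
            for i, aa in enumerate(ft.aa):
                s, e = ft.aa_to_nt(i, i + 1)
                codon = nt[s:e]
                if ft.frame < 0:
                    codon = revcomp(codon)
                (expected,) = [
                    f.aa[0] for f in se.translate_six_frames(codon) if f.frame == 1
                ]
                assert aa == expected

    def test_empty_input_gives_six_empty_frames(self):
        assert [f.aa for f in se.translate_six_frames("")] == [""] * 6


class TestEvalue:
    def test_linear_in_database_length(self):
        e1 = se.estimate_evalue(100, 200, 1_000_000)
        e2 = se.estimate_evalue(100, 200, 2_000_000)
        assert e2 == pytest.approx(2 * e1)

    def test_strictly_decreasing_in_score(self):
        assert se.estimate_evalue(101, 200, 1e6) < se.estimate_evalue(100, 200, 1e6)

    def test_exact_100aa_self_match_passes_default_cutoff(self):
        # a 100-residue exact self-match scores >= 100 * min diagonal of
        # BLOSUM62 (>=4 for the rarest residues); even the conservative
        # floor of 400 gives E far below 1e-20 in a 1 Mb database
        lam, k = se.KA_PARAMS["blosum62"]
        e = k * 100 * 1_000_000 * math.exp(-lam * 400)
        assert e < 1e-20
        assert se.estimate_evalue(400, 100, 1_000_000) == pytest.approx(e)

    def test_unknown_matrix_raises(self):
        with pytest.raises(KeyError):
            se.estimate_evalue(100, 100, 1e6, scoring="pam999")


def orf_genome(rng, orf_nt, genome_len=50_000, pos=20_000, rc=False):
    bg = random_dna(rng, genome_len)
    ins = revcomp(orf_nt) if rc else orf_nt
    seq = bg[:pos] + ins + bg[pos:]
    return Genome(records={"chr": seq}), pos, pos + len(orf_nt)


class TestSearch:
    def test_planted_orf_found_by_translated_search(self, rng, ancestor):
        orf = ancestor.sequence[ancestor.orf_start:ancestor.orf_end - 3]
        genome, s, e = orf_genome(rng, orf)
        query = LibraryEntry("q", "fam", "II", "aa", ancestor.aa)
        hits = se.search([query], genome, se.SearchConfig(mode="tblastn_like"))["q"]
        assert hits, "exact self-match must be found"
        best = max(hits, key=lambda h: h.score)
        assert best.strand == "+"
        assert abs(best.start - s) <= 3 and abs(best.end - e) <= 3

    def test_reverse_planted_orf_reported_on_forward_coordinates(self, rng, ancestor):
        orf = ancestor.sequence[ancestor.orf_start:ancestor.orf_end - 3]
        genome, s, e = orf_genome(rng, orf, rc=True)
        query = LibraryEntry("q", "fam", "II", "aa", ancestor.aa)
        hits = se.search([query], genome, se.SearchConfig(mode="tblastn_like"))["q"]
        best = max(hits, key=lambda h: h.score)
        assert best.strand == "-"
        assert abs(best.start - s) <= 3 and abs(best.end - e) <= 3

    def test_no_homology_means_no_hits(self, rng):
        genome = Genome(records={"chr": random_dna(rng, 50_000)})
        query = LibraryEntry("q", "fam", "II", "aa", "M" + random_dna(rng, 99).replace("T", "W"))
        result = se.search_with_stats([query], genome, se.SearchConfig(mode="tblastn_like"))
        assert result.hits["q"] == []
        assert result.best_evalue is None or result.best_evalue > 1e-20

    def test_blastn_finds_planted_copy_on_both_strands(self, rng):
        element = random_dna(rng, 800)
        for rc in (False, True):
            genome, s, e = orf_genome(rng, element, rc=rc)
            query = LibraryEntry("q", "fam", "II", "nt", element)
            hits = se.search([query], genome, se.SearchConfig(mode="blastn_like"))["q"]
            best = max(hits, key=lambda h: h.score)
            assert (best.start, best.end) == (s, e)
            assert best.strand == ("-" if rc else "+")

    def test_tblastx_mode_accepts_nucleotide_query(self, rng, ancestor):
        orf = ancestor.sequence[ancestor.orf_start:ancestor.orf_end - 3]
        genome, s, e = orf_genome(rng, orf)
        query = LibraryEntry("q", "fam", "II", "nt", orf)
        hits = se.search([query], genome, se.SearchConfig(mode="tblastx_like"))["q"]
        assert any(h.start < e and s < h.end for h in hits)

    def test_mode_alphabet_mismatch_raises(self):
        genome = Genome(records={"chr": "ACGT" * 100})
        aa_query = LibraryEntry("q", "f", "II", "aa", "MKLVMKLV")
        with pytest.raises(se.ModeAlphabetError):
            se.search([aa_query], genome, se.SearchConfig(mode="blastn_like"))

    def test_hits_never_exceed_contig_bounds_and_pass_cutoff(self, rng, ancestor):
        orf = ancestor.sequence[ancestor.orf_start:ancestor.orf_end - 3]
        genome, _, _ = orf_genome(rng, orf, genome_len=30_000)
        cfg = se.SearchConfig(mode="tblastn_like")
        query = LibraryEntry("q", "fam", "II", "aa", ancestor.aa)
        for h in se.search([query], genome, cfg)["q"]:
            assert 0 <= h.start < h.end <= len(genome.records[h.contig])
            assert h.evalue < cfg.evalue_cutoff

    def test_determinism(self, rng, ancestor):
        orf = ancestor.sequence[ancestor.orf_start:ancestor.orf_end - 3]
        genome, _, _ = orf_genome(rng, orf)
        query = LibraryEntry("q", "fam", "II", "aa", ancestor.aa)
        cfg = se.SearchConfig(mode="tblastn_like")
        first = se.search([query], genome, cfg)["q"]
        second = se.search([query], genome, cfg)["q"]
        assert [(h.start, h.end, h.score) for h in first] == [
            (h.start, h.end, h.score) for h in second
        ]


class TestChaining:
    def test_colinear_segments_merge(self):
        segs = [(0, 100, 0, 100, 80), (105, 200, 110, 205, 70)]
        chained = se._chain_segments(segs)
        assert chained == [(0, 200, 0, 205, 150)]

    def test_distant_segments_stay_separate(self):
        segs = [(0, 100, 0, 100, 80), (0, 100, 500, 600, 70)]
        assert len(se._chain_segments(segs)) == 2
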