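import edlib
import numpy as np
import pytest

from teharvest import assembly as asm
from teharvest.fixtures import mutate_sequence
from teharvest.seqio import revcomp
from tests.conftest import random_dna


# ---------------------------------------------------------------------------
# Independent naive trimming oracle: O(n*w) window scan, naive stitching,
# terminal shave — implemented directly from the documented rule.

def oracle_trim(quality, window, threshold, max_low_gap):
    n = len(quality)
    if n == 0:
        return (0, 0)
    if n < window:
        high = [float(np.mean(quality)) > threshold] * n
    else:
        high = [False] * n
        for i in range(n - window + 1):
            if np.mean(quality[i : i + window]) > threshold:
                for j in range(i, i + window):
                    high[j] = True
    runs = []
    i = 0
    while i < n:
        if high[i]:
            j = i
            while j < n and high[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return (0, 0)
    segments = [runs[0]]
    for s, e in runs[1:]:
        if s - segments[-1][1] <= max_low_gap:
            segments[-1] = (segments[-1][0], e)
        else:
            segments.append((s, e))
    s, e = max(segments, key=lambda se: (se[1] - se[0], -se[0]))
    while s < e and quality[s] < threshold:
        s += 1
    while e > s and quality[e - 1] < threshold:
        e -= 1
    return (s, e)


def qc(quality, seq=None):
    quality = np.asarray(quality, dtype=np.int64)
    seq = seq or "A" * len(quality)
    return asm.QualContig("c", seq, quality, 2, ["a", "b"])


class TestTrimExamples:
    def test_uniformly_high_quality_kept_whole(self):
        t = asm.trim_by_quality(qc([30] * 100))
        assert (t.start, t.end) == (0, 100)

    def test_uniformly_low_quality_trims_to_nothing(self):
        t = asm.trim_by_quality(qc([10] * 100))
        assert t.empty and t.sequence == ""

    def test_short_low_gap_is_stitched(self):
        quality = [30] * 30 + [5] * 40 + [30] * 30
        t = asm.trim_by_quality(qc(quality), asm.TrimConfig(max_low_gap=50))
        assert (t.start, t.end) == (0, 100)

    def test_long_low_gap_splits_and_longest_run_wins(self):
        quality = [30] * 30 + [5] * 40 + [30] * 35
        t = asm.trim_by_quality(qc(quality), asm.TrimConfig(max_low_gap=20))
        assert (t.start, t.end) == (70, 105)

    def test_leftmost_wins_on_tied_segments(self):
        quality = [30] * 30 + [0] * 60 + [30] * 30
        t = asm.trim_by_quality(qc(quality), asm.TrimConfig(max_low_gap=20))
        assert (t.start, t.end) == (0, 30)

    def test_whole_contig_mean_used_below_window_size(self):
        assert not asm.trim_by_quality(qc([40] * 5)).empty
        assert asm.trim_by_quality(qc([10] * 5)).empty

    def test_output_is_contiguous_substring(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = random_dna(rng, 80)
            quality = rng.integers(0, 41, size=80)
            t = asm.trim_by_quality(qc(quality, seq))
            assert t.sequence == seq[t.start : t.end]


def test_trim_matches_naive_oracle_on_random_instances(rng):
    cfg = asm.TrimConfig(window=7, threshold=18, max_low_gap=9)
    for _ in range(1000):
        n = int(rng.integers(1, 120))
        quality = rng.choice([0, 10, 20, 30, 40], size=n)
        t = asm.trim_by_quality(qc(quality), cfg)
        assert (t.start, t.end) == oracle_trim(quality, 7, 18, 9)


class TestAssemble:
    def test_two_reads_with_exact_overlap_merge(self, rng):
        whole = random_dna(rng, 160)
        contigs, singlets = asm.assemble([whole[:100], whole[40:]])
        assert len(contigs) == 1 and not singlets
        assert contigs[0].sequence == whole

    def test_three_identical_reads_reproduce_the_read(self, rng):
        read = random_dna(rng, 500)
        contigs, singlets = asm.assemble([read] * 3)
        assert len(contigs) == 1 and not singlets
        assert contigs[0].sequence == read
        assert set(contigs[0].quality.tolist()) == {30}  # n=3 agreement level

    def test_tiling_reads_recover_planted_element(self, rng):
        element = random_dna(rng, 2000)
        reads = []
        for start in range(0, 1600, 200):
            reads.append(mutate_sequence(element[start : start + 600], 0.02, 0.0, rng))
        reads.append(mutate_sequence(element[1500:], 0.02, 0.0, rng))
        contigs, _ = asm.assemble(reads)
        best = max(contigs, key=lambda c: len(c.sequence))
        dist = edlib.align(best.sequence, element, mode="NW")["editDistance"]
        assert 1 - dist / len(element) >= 0.99

    def test_unrelated_reads_stay_singlets(self, rng):
        contigs, singlets = asm.assemble([random_dna(rng, 300), random_dna(rng, 300)])
        assert not contigs and len(singlets) == 2
        assert all((s.quality == asm.SINGLET_QUAL).all() for s in singlets)

    def test_reverse_complement_read_is_assembled(self, rng):
        read = random_dna(rng, 400)
        contigs, singlets = asm.assemble([read, revcomp(read)])
        assert len(contigs) == 1 and not singlets
        assert contigs[0].sequence in (read, revcomp(read))

    def test_determinism_across_runs(self, rng):
        element = random_dna(rng, 1000)
        reads = [mutate_sequence(element, 0.03, 0.003, rng) for _ in range(6)]
        a_contigs, a_singlets = asm.assemble(reads)
        b_contigs, b_singlets = asm.assemble(reads)
        assert [c.sequence for c in a_contigs] == [c.sequence for c in b_contigs]
        assert [c.quality.tolist() for c in a_contigs] == [
            c.quality.tolist() for c in b_contigs
        ]
        assert len(a_singlets) == len(b_singlets)

    def test_empty_input_rejected(self):
        with pytest.raises(asm.AssemblyError):
            asm.assemble([])


class TestBestCodingRegion:
    def test_many_copies_yield_single_candidate(self, rng):
        element = random_dna(rng, 900)
        copies = [mutate_sequence(element, 0.02, 0.002, rng) for _ in range(8)]
        candidates = asm.best_coding_region(copies)
        assert len(candidates) == 1
        dist = edlib.align(candidates[0], element, mode="NW")["editDistance"]
        assert 1 - dist / len(element) >= 0.98

    def test_single_sequence_survives_via_singlet_path(self, rng):
        seq = random_dna(rng, 600)
        (candidate,) = asm.best_coding_region([seq])
        assert candidate == seq

    def test_two_unrelated_elements_give_two_candidates(self, rng):
        e1, e2 = random_dna(rng, 800), random_dna(rng, 700)
        pool = [mutate_sequence(e1, 0.02, 0.0, rng) for _ in range(4)]
        pool += [mutate_sequence(e2, 0.02, 0.0, rng) for _ in range(4)]
        candidates = asm.best_coding_region(pool)
        assert len(candidates) == 2
        d11 = edlib.align(candidates[0], e1, mode="NW")["editDistance"]
        d22 = edlib.align(candidates[1], e2, mode="NW")["editDistance"]
        assert d11 / len(e1) < 0.05 and d22 / len(e2) < 0.05
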