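import pytest

from teharvest import hits as hm
from teharvest.seqio import Genome, revcomp
from tests.conftest import make_hit, random_dna


# ---------------------------------------------------------------------------
# Independent oracle: all-pairs merging repeated to a fixpoint

def oracle_combine(hits, distance, same_query_bridge=True):
    regions = [
        {"contig": h.contig, "start": h.start, "end": h.end,
         "queries": {h.query_id}, "ids": {h.id}}
        for h in hits
    ]

    def mergeable(a, b):
        if a["contig"] != b["contig"]:
            return False
        if a["start"] < b["end"] and b["start"] < a["end"]:
            return True
        gap = max(a["start"], b["start"]) - min(a["end"], b["end"])
        if gap > distance:
            return False
        if same_query_bridge:
            return bool(a["queries"] & b["queries"])
        return True

    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if mergeable(regions[i], regions[j]):
                    a, b = regions[i], regions[j]
                    merged = {
                        "contig": a["contig"],
                        "start": min(a["start"], b["start"]),
                        "end": max(a["end"], b["end"]),
                        "queries": a["queries"] | b["queries"],
                        "ids": a["ids"] | b["ids"],
                    }
                    regions = [r for k, r in enumerate(regions) if k not in (i, j)]
                    regions.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (r["contig"], r["start"], r["end"], frozenset(r["ids"])) for r in regions
    )


def as_tuples(regions):
    return sorted(
        (r.contig, r.start, r.end, frozenset(r.source_hits)) for r in regions
    )


class TestSortHits:
    def test_positional_order(self):
        hits = [make_hit(start=30, end=40), make_hit(start=10, end=20)]
        assert [(h.start, h.end) for h in hm.sort_hits(hits)] == [(10, 20), (30, 40)]

    def test_contig_grouping(self):
        hits = [make_hit(contig="c2", start=0, end=5), make_hit(contig="c1", start=9, end=12)]
        assert [h.contig for h in hm.sort_hits(hits)] == ["c1", "c2"]

    def test_stability_for_equal_keys(self):
        a = make_hit(start=5, end=9, query="qa", hid="first")
        b = make_hit(start=5, end=9, query="qb", hid="second")
        assert [h.id for h in hm.sort_hits([a, b])] == ["first", "second"]

    def test_input_unmodified(self):
        hits = [make_hit(start=30, end=40), make_hit(start=10, end=20)]
        hm.sort_hits(hits)
        assert hits[0].start == 30


class TestCombineExamples:
    def test_overlap_merges_any_query(self):
        hits = [make_hit(start=100, end=200, query="qa"),
                make_hit(start=150, end=300, query="qb")]
        (region,) = hm.combine_hits(hits)
        assert (region.start, region.end) == (100, 300)

    def test_nesting_merges(self):
        hits = [make_hit(start=100, end=400), make_hit(start=150, end=300)]
        (region,) = hm.combine_hits(hits)
        assert (region.start, region.end) == (100, 400)

    def test_gap_bridge_needs_same_query_and_distance(self):
        near = [make_hit(start=100, end=200, query="q"),
                make_hit(start=230, end=300, query="q")]
        (region,) = hm.combine_hits(near, hm.CombineConfig(distance=50))
        assert (region.start, region.end) == (100, 300)  # intervening 30 bp included
        assert len(hm.combine_hits(near, hm.CombineConfig(distance=20))) == 2
        other_query = [make_hit(start=100, end=200, query="qa"),
                       make_hit(start=230, end=300, query="qb")]
        assert len(hm.combine_hits(other_query, hm.CombineConfig(distance=50))) == 2

    def test_bridge_can_absorb_interposed_foreign_hit(self):
        # A and C bridge on a shared query; B then nests inside the union
        hits = [make_hit(start=0, end=100, query="qa", hid="A"),
                make_hit(start=110, end=115, query="qb", hid="B"),
                make_hit(start=120, end=170, query="qa", hid="C")]
        (region,) = hm.combine_hits(hits, hm.CombineConfig(distance=50))
        assert (region.start, region.end) == (0, 170)
        assert set(region.source_hits) == {"A", "B", "C"}

    def test_majority_strand_rule(self):
        hits = [make_hit(start=0, end=100, strand="-"),
                make_hit(start=50, end=80, strand="+")]
        (region,) = hm.combine_hits(hits)
        assert region.strand == "-"


class TestCombineProperties:
    def random_hits(self, rng):
        n = int(rng.integers(1, 12))
        hits = []
        for i in range(n):
            start = int(rng.integers(0, 300))
            hits.append(make_hit(
                contig=str(rng.choice(["c1", "c2"])),
                start=start, end=start + int(rng.integers(1, 60)),
                query=str(rng.choice(["qa", "qb", "qc"])),
                hid=f"h{i}",
            ))
        return hits

    def test_matches_bruteforce_oracle_on_random_sets(self, rng):
        cfg = hm.CombineConfig(distance=25)
        for _ in range(1000):
            hits = self.random_hits(rng)
            assert as_tuples(hm.combine_hits(hits, cfg)) == oracle_combine(hits, 25)

    def test_order_invariance(self, rng):
        cfg = hm.CombineConfig(distance=25)
        for _ in range(100):
            hits = self.random_hits(rng)
            shuffled = list(hits)
            rng.shuffle(shuffled)
            assert as_tuples(hm.combine_hits(hits, cfg)) == as_tuples(
                hm.combine_hits(shuffled, cfg)
            )

    def test_every_hit_in_exactly_one_region_and_coverage_grows(self, rng):
        cfg = hm.CombineConfig(distance=25)
        for _ in range(200):
            hits = self.random_hits(rng)
            regions = hm.combine_hits(hits, cfg)
            assigned = [hid for r in regions for hid in r.source_hits]
            assert sorted(assigned) == sorted(h.id for h in hits)
            for h in hits:
                (home,) = [r for r in regions if h.id in r.source_hits]
                assert home.start <= h.start and h.end <= home.end
            assert sum(r.length for r in regions) >= max(
                (h.length for h in hits), default=0
            )

    def test_idempotence(self, rng):
        cfg = hm.CombineConfig(distance=25)
        for _ in range(200):
            regions = hm.combine_hits(self.random_hits(rng), cfg)
            pseudo = [
                make_hit(contig=r.contig, start=r.start, end=r.end,
                         query=sorted(r.query_ids)[0], hid=f"r{i}")
                for i, r in enumerate(regions)
            ]
            again = hm.combine_hits(pseudo, cfg)
            assert [(r.contig, r.start, r.end) for r in again] == [
                (r.contig, r.start, r.end) for r in regions
            ]


class TestExtraction:
    def test_flank_arithmetic(self, rng):
        genome = Genome(records={"c1": random_dna(rng, 10_000)})
        region = hm.Region("c1", 500, 800, "+", ["h"])
        (ext,) = hm.extract_regions(genome, [region], flank=100)
        assert (ext.extracted_start, ext.extracted_end) == (400, 900)
        assert len(ext.sequence) == 500
        assert ext.sequence == genome.records["c1"][400:900]

    def test_clamping_reported(self, rng):
        genome = Genome(records={"c1": random_dna(rng, 10_000)})
        region = hm.Region("c1", 20, 120, "+", ["h"])
        (ext,) = hm.extract_regions(genome, [region], flank=100)
        assert (ext.extracted_start, ext.extracted_end) == (0, 220)
        assert ext.clamped_left and not ext.clamped_right

    def test_minus_strand_region_reverse_complemented(self, rng):
        genome = Genome(records={"c1": random_dna(rng, 2_000)})
        region = hm.Region("c1", 500, 800, "-", ["h"])
        (ext,) = hm.extract_regions(genome, [region], flank=0)
        assert ext.sequence == revcomp(genome.records["c1"][500:800])
        assert ext.orientation_flipped

    def test_unknown_contig_fails(self):
        genome = Genome(records={"c1": "ACGT" * 100})
        region = hm.Region("nope", 0, 10, "+", ["h"])
        with pytest.raises(Exception):
            hm.extract_regions(genome, [region])


def test_bed_export_format():
    regions = [hm.Region("c1", 5, 50, "-", ["a", "b"])]
    bed = hm.regions_to_bed(regions)
    assert bed == "c1\t5\t50\tregion1\t2\t-\n"
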