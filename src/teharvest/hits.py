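"""Combining alignment hits into genomic regions and extracting them.

A homology search against a repeat-rich genome returns many short,
nearly-adjacent hits per element copy.  Before assembly these are merged:
hits whose intervals overlap or nest are combined regardless of query, and
hits separated by a short gap (50 bp by default) are bridged — including the
intervening genomic sequence — when they originate from the same query.
Merging is run to a fixpoint, so a bridge formed by one query can absorb
overlapping hits from another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .search import Hit
from .seqio import Genome, clamp_interval, extract_subsequence

log = logging.getLogger(__name__)


@dataclass
class Region:
    """A combined genomic interval covering one or more hits."""

    contig: str
    start: int
    end: int
    strand: str
    source_hits: list[str]
    query_ids: frozenset[str] = field(default_factory=frozenset)
    flank_applied: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region with empty interval")
        if not self.source_hits:
            raise ValueError("region without source hits")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CombineConfig:
    distance: int = 50
    same_query_only_for_gap_bridge: bool = True
    flank: int = 0

    def __post_init__(self) -> None:
        if self.distance < 0 or self.flank < 0:
            raise ValueError("distance and flank must be >= 0")


def sort_hits(hits: list[Hit]) -> list[Hit]:
    """Stable sort by (contig, start, end); the input list is untouched."""
    return sorted(hits, key=lambda h: (h.contig, h.start, h.end))


@dataclass
class _Working:
    contig: str
    start: int
    end: int
    hit_ids: list[str]
    queries: set[str]
    plus_bp: int
    minus_bp: int

    @classmethod
    def from_hit(cls, h: Hit) -> "_Working":
        return cls(
            contig=h.contig, start=h.start, end=h.end,
            hit_ids=[h.id], queries={h.query_id},
            plus_bp=h.length if h.strand == "+" else 0,
            minus_bp=h.length if h.strand == "-" else 0,
        )

    def absorb(self, other: "_Working") -> None:
        self.start = min(self.start, other.start)
        self.end = max(self.end, other.end)
        self.hit_ids.extend(other.hit_ids)
        self.queries |= other.queries
        self.plus_bp += other.plus_bp
        self.minus_bp += other.minus_bp


def _mergeable(a: _Working, b: _Working, cfg: CombineConfig) -> bool:
    """a and b sorted so a.start <= b.start, same contig."""
    if b.start < a.end:  # overlap or nesting, any query
        return True
    gap = b.start - a.end
    if gap > cfg.distance:
        return False
    if cfg.same_query_only_for_gap_bridge:
        return bool(a.queries & b.queries)
    return True


def combine_hits(hits: Iterable[Hit], cfg: CombineConfig | None = None) -> list[Region]:
    """Merge hits to a fixpoint of pairwise combination.

    Two hits (or partially built regions) on the same contig merge when
    their intervals overlap or nest, or when the gap between them is within
    ``cfg.distance`` and — with the default same-query restriction — they
    share a contributing query.  The merged interval is the union including
    any gap.  The result is order-invariant, idempotent, and each input hit
    is contained in exactly one output region.

    Region strand is the strand carrying the majority of contributing hit
    bp; ties resolve to "+".
    """
    cfg = cfg or CombineConfig()
    by_contig: dict[str, list[_Working]] = {}
    for h in sort_hits(list(hits)):
        by_contig.setdefault(h.contig, []).append(_Working.from_hit(h))

    regions: list[Region] = []
    for contig in sorted(by_contig):
        work = by_contig[contig]
        changed = True
        while changed:
            changed = False
            work.sort(key=lambda w: (w.start, w.end))
            i = 0
            while i < len(work):
                j = i + 1
                while j < len(work) and work[j].start - work[i].end <= cfg.distance:
                    if _mergeable(work[i], work[j], cfg):
                        work[i].absorb(work.pop(j))
                        changed = True
                    else:
                        j += 1
                i += 1
        for w in work:
            strand = "+" if w.plus_bp >= w.minus_bp else "-"
            regions.append(Region(
                contig=w.contig, start=w.start, end=w.end, strand=strand,
                source_hits=sorted(w.hit_ids), query_ids=frozenset(w.queries),
            ))
    regions.sort(key=lambda r: (r.contig, r.start, r.end))
    return regions


@dataclass
class Extraction:
    """One extracted region sequence with provenance."""

    sequence: str
    contig: str
    region_start: int
    region_end: int
    extracted_start: int
    extracted_end: int
    clamped_left: bool
    clamped_right: bool
    orientation_flipped: bool
    region: Region

    @property
    def id(self) -> str:
        strand = "-" if self.orientation_flipped else "+"
        return f"{self.contig}:{self.extracted_start}-{self.extracted_end}({strand})"


def extract_regions(
    genome: Genome, regions: list[Region], flank: int = 0
) -> list[Extraction]:
    """Extract each region ± `flank` bp, clamped to contig bounds.

    Regions whose contributing hits are mostly on the minus strand are
    reverse-complemented so every extraction shares the coding orientation.
    """
    out = []
    for region in regions:
        want_s, want_e = region.start - flank, region.end + flank
        s, e = clamp_interval(genome, region.contig, want_s, want_e)
        flipped = region.strand == "-"
        seq = extract_subsequence(genome, region.contig, s, e, revcomp_flag=flipped)
        region.flank_applied = (region.start - s, e - region.end)
        out.append(Extraction(
            sequence=seq, contig=region.contig,
            region_start=region.start, region_end=region.end,
            extracted_start=s, extracted_end=e,
            clamped_left=s != want_s, clamped_right=e != want_e,
            orientation_flipped=flipped, region=region,
        ))
    return out


def regions_to_bed(regions: list[Region]) -> str:
    """Render regions as BED6 (0-based half-open, strand in column 6)."""
    lines = []
    for i, r in enumerate(regions):
        lines.append(
            f"{r.contig}\t{r.start}\t{r.end}\tregion{i + 1}\t{len(r.source_hits)}\t{r.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
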