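"""Three-phase discovery of a full-length consensus transposable element.

Phase 1 — identify the coding region: protein (or translated-nucleotide)
search of the family's library queries against the genome, e-value
filtering, hit combination, extraction and assembly/trimming down to the
best putative coding sequences.

Phase 2 — encompass the complete element: nucleotide search of each coding
candidate back against the genome, extraction with generous flanks sized by
element class, multiple alignment of the instances, and the gap-aware
majority consensus.  With a single genomic instance the lone flanked
extraction stands in for the consensus.

Phase 3 — validate: nucleotide search of the consensus, extraction with
short flanks, reassembly and quality trimming to the final element, then a
final instance search for copy counts and genome density.

All defaults reproduce the suggested parameter set: e-value cutoff 1e-20,
combine distance 50 bp, trimming window 20 bp with quality threshold 18,
consensus threshold 49%.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import assembly, hits as hits_mod, msa, seqio
from .assembly import NoViableCodingRegion, TrimConfig
from .hits import CombineConfig, Region, combine_hits, regions_to_bed, sort_hits
from .search import Hit, SearchConfig, search_with_stats
from .seqio import Genome, LibraryEntry

log = logging.getLogger(__name__)

#: Default phase-2 flank per element class: sized to span the typical
#: distance from the coding region to the element ends.
FLANK_BY_CLASS = {"II": 1000, "I": 1500, "unknown": 1000}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class FamilyAbsentError(PipelineError):
    """No hit passed the e-value cutoff in phase 1."""

    def __init__(self, best_evalue: Optional[float]):
        shown = "none" if best_evalue is None else f"{best_evalue:.3g}"
        super().__init__(
            "phase1", f"family absent at this stringency (best e-value: {shown})"
        )
        self.best_evalue = best_evalue


@dataclass
class PipelineConfig:
    evalue_cutoff: float = 1e-20
    combine_distance: int = 50
    flank_phase2: Optional[int] = None  # None: class-dependent default
    flank_phase3: int = 50
    trim: TrimConfig = field(default_factory=TrimConfig)
    consensus_threshold: float = 0.49
    full_length_fraction: float = 0.9
    max_refine_rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.full_length_fraction <= 1:
            raise ValueError("full_length_fraction must be in (0, 1]")
        if not 0 <= self.consensus_threshold < 1:
            raise ValueError("consensus_threshold must be in [0, 1)")
        if self.max_refine_rounds < 1:
            raise ValueError("max_refine_rounds must be >= 1")


@dataclass
class ConsensusTE:
    """The final full-length consensus element and its genome accounting."""

    family: str
    sequence: str
    copies: int
    full_length_copies: int
    density_percent: float
    instances: list[Region]
    provenance: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _combine_cfg(cfg: PipelineConfig) -> CombineConfig:
    return CombineConfig(distance=cfg.combine_distance)


def phase1_identify_coding(
    entries: list[LibraryEntry], genome: Genome, cfg: PipelineConfig
) -> list[str]:
    """Search the family's queries and reduce hits to coding candidates."""
    if not entries:
        raise PipelineError("phase1", "no library entries for this family")
    all_hits: list[Hit] = []
    best_e: Optional[float] = None
    for mode in ("tblastn_like", "tblastx_like"):
        want = "aa" if mode == "tblastn_like" else "nt"
        group = [e for e in entries if e.alphabet == want]
        if not group:
            continue
        result = search_with_stats(
            group, genome,
            SearchConfig(mode=mode, evalue_cutoff=cfg.evalue_cutoff),
        )
        for hit_list in result.hits.values():
            all_hits.extend(hit_list)
        if result.best_evalue is not None:
            best_e = result.best_evalue if best_e is None else min(best_e, result.best_evalue)
    if not all_hits:
        raise FamilyAbsentError(best_e)
    regions = combine_hits(sort_hits(all_hits), _combine_cfg(cfg))
    extractions = hits_mod.extract_regions(genome, regions, flank=0)
    log.info("phase1: %d hits -> %d regions", len(all_hits), len(regions))
    try:
        candidates = assembly.best_coding_region(
            [x.sequence for x in extractions], cfg.trim,
            ids=[f"p1x{i + 1:03d}" for i in range(len(extractions))],
        )
    except NoViableCodingRegion as exc:
        raise PipelineError("phase1", str(exc)) from exc
    log.info("phase1: %d coding candidates", len(candidates))
    return candidates


def phase2_encompass(
    candidates: list[str],
    genome: Genome,
    cfg: PipelineConfig,
    te_class: str = "unknown",
) -> str:
    """Extend coding candidates to a consensus spanning the whole element."""
    if not candidates:
        raise PipelineError("phase2", "no candidates from phase 1")
    flank = cfg.flank_phase2
    if flank is None:
        flank = FLANK_BY_CLASS.get(te_class, FLANK_BY_CLASS["unknown"])
    queries = [
        LibraryEntry(f"candidate{i + 1}", "candidate", "unknown", "nt", c)
        for i, c in enumerate(candidates)
    ]
    result = search_with_stats(
        queries, genome, SearchConfig(mode="blastn_like", evalue_cutoff=cfg.evalue_cutoff)
    )
    flat = [h for hl in result.hits.values() for h in hl]
    assert flat, "phase 2 found no instances although phase 1 succeeded"
    regions = combine_hits(sort_hits(flat), _combine_cfg(cfg))
    extractions = hits_mod.extract_regions(genome, regions, flank=flank)
    log.info("phase2: %d instances at flank %d", len(extractions), flank)
    if len(extractions) == 1:
        return extractions[0].sequence
    aln = msa.align_msa(
        [x.sequence for x in extractions], ids=[x.id for x in extractions]
    )
    consensus, profile = msa.call_consensus(aln, cfg.consensus_threshold)
    if not consensus:
        raise PipelineError("phase2", "empty consensus from multiple alignment")
    # trim the consensus by column support, exactly as contigs are trimmed:
    # weakly supported arms assembled from unrelated flanking sequence fall
    # away and the well-supported element core remains
    # Boundary cleanup, in two steps.  First the consensus is trimmed with
    # the standard sliding window over a support-based quality track, which
    # removes long weakly supported arms assembled from flanking sequence.
    # Then the ends are sharpened: terminal columns must hold a two-thirds
    # majority, because flanking columns can reach the emission threshold
    # through composition bias and alignment optimization alone, while the
    # element's true termini are carried by a solid majority of instances.
    qc = assembly.QualContig(
        id="phase2_consensus", sequence=consensus,
        quality=msa.profile_quality(profile), n_members=1,
        members=["phase2_consensus"],
    )
    trimmed = assembly.trim_by_quality(qc, cfg.trim)
    if trimmed.empty:
        raise PipelineError("phase2", "consensus trimmed to nothing")
    support = msa.profile_support(profile)
    s, e = trimmed.start, trimmed.end
    while s < e and 3 * support[s, 0] < 2 * (support[s, 1] + support[s, 2]):
        s += 1
    while e > s and 3 * support[e - 1, 0] < 2 * (support[e - 1, 1] + support[e - 1, 2]):
        e -= 1
    if s >= e:
        raise PipelineError("phase2", "consensus trimmed to nothing")
    return consensus[s:e]


def find_instances(
    sequence: str, genome: Genome, cfg: PipelineConfig
) -> list[Region]:
    """Combined genomic instance regions of a consensus element."""
    query = LibraryEntry("consensus", "consensus", "unknown", "nt", sequence)
    result = search_with_stats(
        [query], genome, SearchConfig(mode="blastn_like", evalue_cutoff=cfg.evalue_cutoff)
    )
    return combine_hits(sort_hits(result.hits["consensus"]), _combine_cfg(cfg))


def density_percent(instances: list[Region], genome: Genome) -> float:
    """Genome share of the merged instance regions, in percent.

    Combined regions are pairwise disjoint, so each genomic base is counted
    at most once.
    """
    covered = sum(r.length for r in instances)
    return 100.0 * covered / genome.total_length


def phase3_validate(
    consensus: str, genome: Genome, cfg: PipelineConfig, family: str = "unknown"
) -> ConsensusTE:
    """Refine the consensus against the genome and count its copies."""
    if not consensus:
        raise PipelineError("phase3", "empty consensus from phase 2")
    regions = find_instances(consensus, genome, cfg)
    if not regions:
        raise PipelineError("phase3", "consensus found no instances in the genome")
    extractions = hits_mod.extract_regions(genome, regions, flank=cfg.flank_phase3)
    try:
        finals = assembly.best_coding_region(
            [x.sequence for x in extractions], cfg.trim,
            ids=[f"p3x{i + 1:03d}" for i in range(len(extractions))],
        )
    except NoViableCodingRegion as exc:
        raise PipelineError(
            "phase3",
            f"final trimming removed everything; phase-2 consensus "
            f"({len(consensus)} bp) kept for inspection: {exc}",
        ) from exc
    final = finals[0]
    instances = find_instances(final, genome, cfg)
    copies = len(instances)
    full_length = sum(
        1 for r in instances if r.length >= cfg.full_length_fraction * len(final)
    )
    dens = density_percent(instances, genome)
    log.info(
        "phase3: final %d bp, %d copies (%d full-length), density %.3f%%",
        len(final), copies, full_length, dens,
    )
    return ConsensusTE(
        family=family, sequence=final, copies=copies,
        full_length_copies=full_length, density_percent=dens,
        instances=instances,
        provenance={"phase2_consensus_length": len(consensus)},
    )


def _report_rows(te: ConsensusTE) -> list[tuple]:
    return [(
        te.family, f"{te.family}_consensus", te.length,
        te.full_length_copies, te.copies, f"{te.density_percent:.2f}%",
    )]


def format_report_tsv(te: ConsensusTE) -> str:
    header = "family\telement\tlength_bp\tfull_length_copies\tcopies\tdensity\n"
    body = "".join("\t".join(str(v) for v in row) + "\n" for row in _report_rows(te))
    return header + body


def format_report_text(te: ConsensusTE) -> str:
    lines = [
        f"Family:             {te.family}",
        f"Length (bp):        {te.length}",
        f"Full-length Copies: {te.full_length_copies}",
        f"Copies:             {te.copies}",
        f"Density:            {te.density_percent:.2f}%",
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(
    family: str,
    library_path: str | Path,
    genome_path: str | Path,
    cfg: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
    family_table: Optional[str | Path] = None,
) -> ConsensusTE:
    """Run all three phases for one family and optionally write a run
    directory with every intermediate plus a manifest."""
    cfg = cfg or PipelineConfig()
    entries = seqio.load_library(library_path, family_filter=family,
                                 family_table=family_table)
    genome = seqio.load_genome(genome_path)
    te_classes = {e.te_class for e in entries}
    te_class = te_classes.pop() if len(te_classes) == 1 else "unknown"

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    candidates = phase1_identify_coding(entries, genome, cfg)
    if out is not None:
        seqio.write_fasta(
            [(f"candidate{i + 1}", c) for i, c in enumerate(candidates)],
            out / "phase1_candidates.fasta",
        )

    consensus = phase2_encompass(candidates, genome, cfg, te_class=te_class)
    if out is not None:
        seqio.write_fasta([("phase2_consensus", consensus)], out / "phase2_consensus.fasta")

    te = phase3_validate(consensus, genome, cfg, family=family)
    for round_idx in range(1, cfg.max_refine_rounds):
        log.info("refinement round %d", round_idx + 1)
        te = phase3_validate(te.sequence, genome, cfg, family=family)

    te.provenance.update({
        "family": family,
        "n_library_entries": len(entries),
        "n_phase1_candidates": len(candidates),
        "te_class": te_class,
    })

    if out is not None:
        seqio.write_fasta([(f"{family}_consensus", te.sequence)], out / "consensus.fasta")
        (out / "instances.bed").write_text(regions_to_bed(te.instances))
        (out / "report.tsv").write_text(format_report_tsv(te))
        (out / "report.txt").write_text(format_report_text(te))
        manifest = {
            "family": family,
            "library": str(library_path),
            "genome": str(genome_path),
            "config": dataclasses.asdict(cfg),
            "stages": {
                "phase1_candidates": len(candidates),
                "phase2_consensus_length": len(consensus),
                "final_length": te.length,
                "copies": te.copies,
                "full_length_copies": te.full_length_copies,
                "density_percent": te.density_percent,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return te
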