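"""Optional adapter running an external BLAST+ installation.

The internal seed-and-extend backend is the reference implementation; this
adapter lets a user substitute real ``tblastn``/``blastn``/``tblastx``
binaries when they are on PATH.  Only the e-value cutoff is passed; all
other flags stay at their defaults.  Tabular output (outfmt 6) is converted
from 1-based inclusive, strand-encoded-by-coordinate-order convention into
this package's 0-based half-open forward-strand convention.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .search import Hit, SearchConfig
from .seqio import Genome, LibraryEntry, write_fasta

_PROGRAMS = {
    "tblastn_like": "tblastn",
    "blastn_like": "blastn",
    "tblastx_like": "tblastx",
}


def blast_available(mode: str = "tblastn_like") -> bool:
    return (
        shutil.which(_PROGRAMS[mode]) is not None
        and shutil.which("makeblastdb") is not None
    )


def search_external(
    queries: list[LibraryEntry], genome: Genome, cfg: SearchConfig
) -> dict[str, list[Hit]]:
    """Run BLAST+ and return hits in the internal convention."""
    program = _PROGRAMS[cfg.mode]
    if not blast_available(cfg.mode):
        raise RuntimeError(f"{program} or makeblastdb not found on PATH")
    hits: dict[str, list[Hit]] = {q.id: [] for q in queries}
    with tempfile.TemporaryDirectory(prefix="teharvest_blast_") as tmp:
        tmp_path = Path(tmp)
        db_fasta = tmp_path / "genome.fasta"
        query_fasta = tmp_path / "queries.fasta"
        write_fasta(genome.records.items(), db_fasta)
        write_fasta([(q.id, q.sequence) for q in queries], query_fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(db_fasta), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        out = subprocess.run(
            [
                program, "-query", str(query_fasta), "-db", str(db_fasta),
                "-evalue", str(cfg.evalue_cutoff), "-outfmt", "6",
            ],
            check=True, capture_output=True, text=True,
        ).stdout
    serial = 0
    for line in out.splitlines():
        cols = line.split("\t")
        if len(cols) < 12:
            continue
        qseqid, sseqid = cols[0], cols[1]
        sstart, send = int(cols[8]), int(cols[9])
        evalue, bits = float(cols[10]), float(cols[11])
        if sstart <= send:
            start, end, strand = sstart - 1, send, "+"
        else:
            start, end, strand = send - 1, sstart, "-"
        frame = 0
        if cfg.mode != "blastn_like":
            # reconstruct a BLAST-style frame from the mapped interval
            offset = start % 3 if strand == "+" else (len(genome.records[sseqid]) - end) % 3
            frame = (offset + 1) if strand == "+" else -(offset + 1)
        serial += 1
        hits.setdefault(qseqid, []).append(Hit(
            id=f"x{serial}", query_id=qseqid, contig=sseqid,
            start=start, end=end, strand=strand, frame=frame,
            score=int(round(bits)), bitscore=bits, evalue=evalue,
        ))
    for key in hits:
        hits[key].sort(key=lambda h: (h.contig, h.start, h.end, h.strand, h.frame))
    return hits
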