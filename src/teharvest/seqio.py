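"""Reading, validation and writing of TE libraries and genome assemblies.

A TE library is a multi-FASTA of representative coding regions — amino-acid
transposase / reverse-transcriptase sequences for most families, nucleotide
sequences where no protein is available — grouped into families.  Family
membership is read from the header convention ``>id family=NAME class=I|II``;
alternatively a sidecar TSV (columns: id, family, class) may be supplied.

Genomes are plain multi-FASTA assemblies.  All coordinates in this package
are 0-based half-open on the forward strand; strand is carried as a flag and
never encoded by swapping coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

log = logging.getLogger(__name__)

_NT_CHARS = set("ACGTNU")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*")
# IUPAC nucleotide ambiguity codes collapse to N: they carry too little
# information to be worth scoring.
_IUPAC_AMBIG = "RYSWKMBDHV"
_AMBIG_TABLE = str.maketrans({c: "N" for c in _IUPAC_AMBIG} | {"U": "T"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class LibraryError(ValueError):
    """Raised when a TE library fails validation."""


class GenomeError(ValueError):
    """Raised when a genome FASTA fails validation."""


@dataclass(frozen=True)
class LibraryEntry:
    """One representative TE coding region."""

    id: str
    family: str
    te_class: str  # "I", "II" or "unknown"
    alphabet: str  # "aa" or "nt"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LibraryError(f"library entry {self.id!r} has empty sequence")
        if self.te_class not in ("I", "II", "unknown"):
            raise LibraryError(
                f"library entry {self.id!r}: bad class {self.te_class!r}"
            )
        allowed = _NT_CHARS if self.alphabet == "nt" else _AA_CHARS
        bad = set(self.sequence) - allowed
        if bad:
            raise LibraryError(
                f"library entry {self.id!r}: invalid {self.alphabet} "
                f"residues {sorted(bad)}"
            )


@dataclass
class Genome:
    """An assembled genome: ordered contigs of upcased A/C/G/T/N."""

    records: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def __contains__(self, contig: str) -> bool:
        return contig in self.records


def detect_alphabet(sequence: str) -> str:
    """Classify a residue string as nucleotide or amino acid.

    Any residue outside {A,C,G,T,N,U} forces the amino-acid alphabet;
    otherwise the sequence is treated as nucleotide.
    """
    return "nt" if set(sequence.upper()) <= _NT_CHARS else "aa"


def _parse_header(description: str) -> tuple[str, str, str]:
    parts = description.split()
    rec_id = parts[0]
    family = "unknown"
    te_class = "unknown"
    for tok in parts[1:]:
        if tok.startswith("family="):
            family = tok[len("family="):]
        elif tok.startswith("class="):
            te_class = tok[len("class="):]
    return rec_id, family, te_class


def _load_sidecar(path: Path) -> dict[str, tuple[str, str]]:
    table: dict[str, tuple[str, str]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise LibraryError(f"bad sidecar line: {line!r}")
        te_class = cols[2] if len(cols) > 2 else "unknown"
        table[cols[0]] = (cols[1], te_class)
    return table


def load_library(
    path: str | Path,
    family_filter: Optional[str] = None,
    family_table: Optional[str | Path] = None,
) -> list[LibraryEntry]:
    """Load a TE library FASTA, optionally keeping a single family.

    Family and class are read from ``family=``/``class=`` tokens in each
    record header, or from `family_table` (a TSV of id, family, class) which
    takes precedence.  Raises :class:`LibraryError` on duplicate ids, invalid
    residues, or when `family_filter` matches nothing.
    """
    path = Path(path)
    sidecar = _load_sidecar(Path(family_table)) if family_table else {}
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, family, te_class = _parse_header(rec.description)
        if rec_id in sidecar:
            family, te_class = sidecar[rec_id]
        if rec_id in seen:
            raise LibraryError(f"duplicate library id {rec_id!r}")
        seen.add(rec_id)
        seq = str(rec.seq).upper()
        alphabet = detect_alphabet(seq)
        if alphabet == "nt":
            seq = seq.replace("U", "T")
        entries.append(LibraryEntry(rec_id, family, te_class, alphabet, seq))
    if not entries:
        raise LibraryError(f"no FASTA records in {path}")
    if family_filter is not None:
        entries = [e for e in entries if e.family == family_filter]
        if not entries:
            raise LibraryError(f"family not found in library: {family_filter!r}")
    return entries


def load_genome(path: str | Path) -> Genome:
    """Load a multi-FASTA genome, upcasing and collapsing ambiguity to N."""
    genome = Genome()
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        if rec.id in genome.records:
            raise GenomeError(f"duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            log.warning("dropping zero-length record %s", rec.id)
            continue
        cleaned = seq.translate(_AMBIG_TABLE)
        n_ambig = sum(1 for a, b in zip(seq, cleaned) if a != b)
        if n_ambig:
            log.info("contig %s: %d ambiguity codes mapped to N", rec.id, n_ambig)
        bad = set(cleaned) - set("ACGTN")
        if bad:
            raise GenomeError(f"contig {rec.id!r}: invalid residues {sorted(bad)}")
        genome.records[rec.id] = cleaned
    if not genome.records:
        raise GenomeError(f"no usable records in {path}")
    return genome


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def clamp_interval(genome: Genome, contig: str, start: int, end: int) -> tuple[int, int]:
    """Clamp a half-open interval to the bounds of `contig`."""
    if contig not in genome.records:
        raise GenomeError(f"unknown contig {contig!r}")
    n = len(genome.records[contig])
    return max(0, start), min(n, end)


def extract_subsequence(
    genome: Genome,
    contig: str,
    start: int,
    end: int,
    revcomp_flag: bool = False,
) -> str:
    """Return genome[contig][start:end], clamped, optionally reverse-complemented.

    A fully out-of-range request raises :class:`GenomeError` rather than
    silently returning an empty string.
    """
    s, e = clamp_interval(genome, contig, start, end)
    if s >= e:
        raise GenomeError(
            f"empty extraction on {contig}: requested [{start},{end}) "
            f"clamps to [{s},{e})"
        )
    if (s, e) != (start, end):
        log.debug("extraction clamped: [%d,%d) -> [%d,%d)", start, end, s, e)
    seq = genome.records[contig][s:e]
    return revcomp(seq) if revcomp_flag else seq


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
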