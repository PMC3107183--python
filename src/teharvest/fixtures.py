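"""Synthetic genomes with planted transposable-element copies plus truth.

The generator emulates the situation the discovery pipeline is built for: a
host genome containing many diverged, partially truncated, optionally
nested copies of an ancestral element.  The default ancestor is a
mariner-like Class II element — 26 bp terminal inverted repeats (TIRs)
around untranslated leaders and a single intact transposase ORF, about
1.3 kb in total.  Copies are independently mutated (uniform substitutions;
geometric indels), optionally truncated from the 5' or 3' end, optionally
reverse-complemented, and inserted with a short target-site duplication
(TSD) drawn from the host sequence at the insertion point.  Insertion
extends the genome, so copies never destroy one another except by explicit
nesting.

Every copy is recorded in a machine-readable truth table with realized
identity to the ancestor, so recovery can be scored exactly.  A fixed seed
reproduces the genome and truth byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import edlib
import numpy as np

from .seqio import Genome, LibraryEntry, revcomp, write_fasta

_SENSE_CODONS = None


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class Ancestor:
    """An ancestral element with annotated ORF and TIR structure."""

    sequence: str
    orf_start: int  # nt coords within the element, half-open, incl. stop codon
    orf_end: int
    tir_length: int
    aa: str  # translated ORF without the stop

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic genome."""

    genome_length: int = 2_000_000
    gc_content: float = 0.40
    ancestor: Optional[Ancestor] = None  # auto-generated when None
    ancestor_aa_length: int = 300
    n_full: int = 20
    n_fragment: int = 30
    sub_rate: float = 0.02
    indel_rate: float = 0.002
    fragment_length_range: tuple[float, float] = (0.2, 0.4)
    tsd_length: int = 2
    tir_length: int = 26
    nest_prob: float = 0.0
    revcomp_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.gc_content, self.sub_rate, self.indel_rate,
                  self.nest_prob, self.revcomp_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthRecord:
    id: str
    contig: str
    start: int
    end: int
    strand: str
    kind: str  # "full" | "fragment"
    identity_to_ancestor: float
    nested_in: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Fixture:
    genome: Genome
    truth: list[TruthRecord]
    ancestor: Ancestor
    spec: FixtureSpec


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        _SENSE_CODONS = sorted(table.forward_table)
    return _SENSE_CODONS


def _random_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def make_ancestor(
    aa_length: int = 300,
    tir_length: int = 26,
    seed: int = 0,
    utr5_length: int = 150,
    utr3_length: int = 180,
    gc_content: float = 0.5,
) -> Ancestor:
    """Build a mariner-like element: TIR + 5'UTR + ORF + 3'UTR + revcomp TIR.

    The ORF is ``aa_length`` codons (ATG first) plus a stop, free of internal
    stops by construction, so its translation is a clean transposase-like
    query for protein-level searches.
    """
    if aa_length < 50:
        raise ValueError("aa_length must be >= 50")
    rng = np.random.default_rng(seed)
    table = _sense_codons()
    from Bio.Data import CodonTable

    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    codons = ["ATG"] + [
        table[i] for i in rng.integers(0, len(table), size=aa_length - 1)
    ]
    orf = "".join(codons) + "TAA"
    aa = "".join(fwd[c] for c in codons)
    left_tir = _random_nt(rng, tir_length, gc_content)
    utr5 = _random_nt(rng, utr5_length, gc_content)
    utr3 = _random_nt(rng, utr3_length, gc_content)
    seq = left_tir + utr5 + orf + utr3 + revcomp(left_tir)
    orf_start = tir_length + utr5_length
    return Ancestor(
        sequence=seq, orf_start=orf_start, orf_end=orf_start + len(orf),
        tir_length=tir_length, aa=aa,
    )


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    indel_p: float = 0.5,
    indel_max: int = 10,
) -> str:
    """Apply uniform substitutions and geometric-length indels."""
    bases = "ACGT"
    chars = list(seq)
    if sub_rate > 0:
        hit = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for i in hit:
            alternatives = [b for b in bases if b != chars[i]]
            chars[i] = alternatives[rng.integers(0, 3)]
    if indel_rate > 0:
        events = sorted(
            np.nonzero(rng.random(len(chars)) < indel_rate)[0], reverse=True
        )
        for i in events:
            length = min(int(rng.geometric(indel_p)), indel_max)
            if rng.random() < 0.5:  # insertion after position i
                ins = "".join(bases[j] for j in rng.integers(0, 4, size=length))
                chars[i] = chars[i] + ins
            else:  # deletion of up to `length` bases starting at i
                for j in range(i, min(i + length, len(chars))):
                    chars[j] = ""
    return "".join(chars)


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def plant_copies(spec: FixtureSpec, background: Optional[str] = None) -> Fixture:
    """Generate a genome with planted element copies and truth records.

    `background` may supply an existing sequence (for example a genome that
    already contains another family) instead of random host sequence.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = spec.ancestor or make_ancestor(
        aa_length=spec.ancestor_aa_length,
        tir_length=spec.tir_length,
        seed=spec.seed + 104729,
    )
    if background is None:
        genome_seq = _random_nt(rng, spec.genome_length, spec.gc_content)
    else:
        genome_seq = background.upper()

    n_total = spec.n_full + spec.n_fragment
    planted_estimate = (
        spec.n_full * ancestor.length
        + spec.n_fragment * np.mean(spec.fragment_length_range) * ancestor.length
    )
    if planted_estimate >= len(genome_seq):
        raise FixtureError("planted bp exceeds genome length; enlarge the genome")

    truth: list[TruthRecord] = []
    margin = 1000
    for i in range(n_total):
        kind = "full" if i < spec.n_full else "fragment"
        if kind == "full":
            portion = ancestor.sequence
        else:
            frac = rng.uniform(*spec.fragment_length_range)
            cut = max(50, int(round(frac * ancestor.length)))
            if rng.random() < 0.5:  # keep 5' end
                portion = ancestor.sequence[:cut]
            else:
                portion = ancestor.sequence[-cut:]
        mutated = mutate_sequence(portion, spec.sub_rate, spec.indel_rate, rng)
        identity = _identity(mutated, portion)
        strand = "-" if rng.random() < spec.revcomp_prob else "+"
        inserted = revcomp(mutated) if strand == "-" else mutated

        host: Optional[TruthRecord] = None
        if truth and rng.random() < spec.nest_prob:
            candidates = [t for t in truth if t.length >= 200]
            if candidates:
                host = candidates[int(rng.integers(0, len(candidates)))]
        if host is not None:
            p = int(rng.integers(host.start + 50, host.end - 50))
        else:
            p = None
            for _attempt in range(1000):
                cand = int(rng.integers(margin, len(genome_seq) - margin))
                window = (cand - spec.tsd_length, cand + spec.tsd_length + 1)
                if all(t.end <= window[0] or t.start >= window[1] for t in truth):
                    p = cand
                    break
            if p is None:
                raise FixtureError(
                    "could not place a copy without overlap; enlarge the genome"
                )

        t = spec.tsd_length
        ins_len = len(inserted) + t
        genome_seq = genome_seq[: p + t] + inserted + genome_seq[p:]
        for rec in truth:
            if rec.start >= p:
                rec.start += ins_len
                rec.end += ins_len
            elif rec.end > p:  # insertion lands inside this record
                rec.end += ins_len
        start = p + t
        truth.append(TruthRecord(
            id=f"copy{i + 1}", contig="chr1", start=start,
            end=start + len(inserted), strand=strand, kind=kind,
            identity_to_ancestor=identity,
            nested_in=host.id if host is not None else None,
        ))

    genome = Genome(records={"chr1": genome_seq})
    return Fixture(genome=genome, truth=truth, ancestor=ancestor, spec=spec)


def library_for_ancestor(
    ancestor: Ancestor,
    family: str = "mariner",
    te_class: str = "II",
    entry_id: Optional[str] = None,
    aa_divergence: float = 0.0,
    seed: int = 0,
) -> LibraryEntry:
    """A protein library entry for an ancestor's transposase.

    `aa_divergence` substitutes a fraction of residues, emulating a library
    sequence from a related species rather than the exact ancestor.
    """
    aa = ancestor.aa
    if aa_divergence > 0:
        rng = np.random.default_rng(seed)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        chars = list(aa)
        hit = np.nonzero(rng.random(len(chars)) < aa_divergence)[0]
        for i in hit:
            alternatives = [r for r in residues if r != chars[i]]
            chars[i] = alternatives[int(rng.integers(0, len(alternatives)))]
        aa = "".join(chars)
    return LibraryEntry(
        id=entry_id or f"{family}_tpase1", family=family,
        te_class=te_class, alphabet="aa", sequence=aa,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write genome.fasta, ancestor.fasta, truth.bed and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.genome.records.items(), outdir / "genome.fasta")
    write_fasta([("ancestor", fixture.ancestor.sequence)], outdir / "ancestor.fasta")
    with open(outdir / "truth.bed", "w") as fh:
        for t in fixture.truth:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.id}\t0\t{t.strand}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("id\tcontig\tstart\tend\tstrand\tkind\tidentity\tnested_in\n")
        for t in fixture.truth:
            fh.write(
                f"{t.id}\t{t.contig}\t{t.start}\t{t.end}\t{t.strand}\t{t.kind}"
                f"\t{t.identity_to_ancestor:.4f}\t{t.nested_in or '.'}\n"
            )
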