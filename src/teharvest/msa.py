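"""Multiple alignment of element instances and majority-rule consensus.

The consensus rule is the heart of this module.  Per alignment column with
R rows: every row showing base *b* increments the count ``c[b]``; a gap (or
an N, which carries no base evidence) increments the counts of **all four**
bases — missing data should not vote against any base.  A base whose
percentage ``c[b]/R`` exceeds the threshold (49% by default) is emitted;
among several qualifying bases the one with the highest gap-free count
wins, ties breaking alphabetically.  Columns where gaps outnumber real
bases (dominated by missing data — typically an insertion private to one
row, or alignment territory most instances never reach), and columns where
no base qualifies, are dropped rather than emitted as ambiguity codes —
the consensus is meant to be searchable against the genome, and ambiguity
characters would poison that search.

The alignment itself is standard machinery: a deterministic center-star
alignment built from optimal pairwise alignments (match +1, mismatch −1,
gap open −5, extend −1, end gaps free) computed with Biopython's
PairwiseAligner.  An adapter for reading externally produced CLUSTAL or
aligned-FASTA alignments is provided so any MSA program can stand in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Align, AlignIO

DEFAULT_CONSENSUS_THRESHOLD = 0.49

_ROW_ALPHABET = set("ACGTN-")


class MSAError(ValueError):
    pass


@dataclass
class Alignment:
    """A multiple alignment over {A,C,G,T,N,-}; row order is input order."""

    ids: list[str]
    rows: dict[str, str]
    ncol: int

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise MSAError("an alignment needs at least two rows")
        for rid in self.ids:
            row = self.rows[rid]
            if len(row) != self.ncol:
                raise MSAError(f"row {rid!r} has length {len(row)} != {self.ncol}")
            bad = set(row) - _ROW_ALPHABET
            if bad:
                raise MSAError(f"row {rid!r}: invalid symbols {sorted(bad)}")


@dataclass
class ConsensusProfile:
    """Per-column counts and the emission decision, for audit."""

    base_counts: np.ndarray  # (ncol, 4) gap-free counts of A,C,G,T
    gap_counts: np.ndarray  # (ncol,) gaps + Ns
    emitted: list[str]  # per column: "A"/"C"/"G"/"T" or "dropped"
    threshold: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _pairwise_gaps(center: str, other: str) -> tuple[list[str], list[str]]:
    """Align `other` to `center`; describe the result relative to center.

    Returns (ins_chunks, aligned_chars): ``ins_chunks[p]`` holds the `other`
    characters inserted before center position p (p = len(center) means
    after the last), and ``aligned_chars[p]`` the `other` character (or "-")
    paired with center position p.
    """
    aligner = _make_aligner()
    aln = aligner.align(center, other)[0]
    a, b = str(aln[0]), str(aln[1])
    ins_chunks: list[str] = [""] * (len(center) + 1)
    aligned: list[str] = []
    p = 0
    for ca, cb in zip(a, b):
        if ca == "-":
            ins_chunks[p] += cb
        else:
            aligned.append(cb)
            p += 1
    return ins_chunks, aligned


def align_msa(seqs: Sequence[str], ids: Optional[Sequence[str]] = None) -> Alignment:
    """Deterministic center-star multiple alignment of ≥2 sequences.

    The longest input (first on ties) is the center; every other sequence is
    optimally pairwise-aligned to it and the pairwise gap patterns are
    projected into shared columns.
    """
    if len(seqs) < 2:
        raise MSAError("align_msa requires at least two sequences")
    if any(not s for s in seqs):
        raise MSAError("empty sequence passed to align_msa")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(seqs))]
    ids = list(ids)
    seqs = [s.upper() for s in seqs]

    center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_idx]
    n_anchor = len(center) + 1

    per_seq: dict[int, tuple[list[str], list[str]]] = {}
    max_ins = [0] * n_anchor
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        ins_chunks, aligned = _pairwise_gaps(center, s)
        per_seq[i] = (ins_chunks, aligned)
        for p, chunk in enumerate(ins_chunks):
            max_ins[p] = max(max_ins[p], len(chunk))

    rows: dict[str, str] = {}
    for i, s in enumerate(seqs):
        parts: list[str] = []
        if i == center_idx:
            for p in range(len(center)):
                parts.append("-" * max_ins[p])
                parts.append(center[p])
            parts.append("-" * max_ins[len(center)])
        else:
            ins_chunks, aligned = per_seq[i]
            for p in range(len(center)):
                chunk = ins_chunks[p]
                parts.append(chunk + "-" * (max_ins[p] - len(chunk)))
                parts.append(aligned[p])
            chunk = ins_chunks[len(center)]
            parts.append(chunk + "-" * (max_ins[len(center)] - len(chunk)))
        rows[ids[i]] = "".join(parts)

    ncol = len(center) + sum(max_ins)
    return Alignment(ids=ids, rows=rows, ncol=ncol)


def call_consensus(
    aln: Alignment, threshold: float = DEFAULT_CONSENSUS_THRESHOLD
) -> tuple[str, ConsensusProfile]:
    """Apply the gap-aware majority rule to each column of an alignment.

    Every gap (or N) increments the count of all four bases; percentages
    are over all rows.  Columns where gaps outnumber real bases are
    dropped: their emission would be decided by missing data rather than
    observed sequence.
    """
    nrow = len(aln.ids)
    mat = np.frombuffer(
        "".join(aln.rows[rid] for rid in aln.ids).encode(), dtype=np.uint8
    ).reshape(nrow, aln.ncol)
    base_counts = np.stack(
        [(mat == ord(b)).sum(axis=0) for b in "ACGT"], axis=1
    ).astype(np.int64)
    gap_counts = nrow - base_counts.sum(axis=1)  # gaps and Ns
    pct_all = (base_counts + gap_counts[:, None]) / nrow

    emitted: list[str] = []
    out: list[str] = []
    for col in range(aln.ncol):
        if 2 * gap_counts[col] > nrow:
            emitted.append("dropped")
            continue
        qualifying = np.nonzero(pct_all[col] > threshold)[0]
        if len(qualifying) == 0:
            emitted.append("dropped")
            continue
        # highest gap-free support wins; np.argmax ties break A<C<G<T
        best = qualifying[np.argmax(base_counts[col, qualifying])]
        base = "ACGT"[int(best)]
        emitted.append(base)
        out.append(base)
    profile = ConsensusProfile(
        base_counts=base_counts, gap_counts=gap_counts,
        emitted=emitted, threshold=threshold,
    )
    return "".join(out), profile


def profile_support(profile: ConsensusProfile) -> np.ndarray:
    """(win, real, gaps) per emitted column: the winning base's gap-free
    count, the total real bases, and the gap count."""
    rows = []
    for col, sym in enumerate(profile.emitted):
        if sym == "dropped":
            continue
        win = int(profile.base_counts[col, "ACGT".index(sym)])
        real = int(profile.base_counts[col].sum())
        rows.append((win, real, int(profile.gap_counts[col])))
    return np.asarray(rows, dtype=np.int64).reshape(-1, 3)


def profile_quality(profile: ConsensusProfile) -> np.ndarray:
    """Per-base quality for the emitted consensus, on the assembler's scale.

    For each emitted column the winning base's gap-free support is weighed
    against everything that disagrees — dissenting real bases and gaps
    alike: ``clip(10·(win − dissent − gaps), 0, 40)``.  Columns carried by
    a coherent majority of the instances score 40, while columns emitted
    from stacked unrelated flanking sequence (where pairwise alignment
    optimization inflates chance agreement) score 0, so the standard
    sliding-window trim can cut the consensus down to the well-supported
    core.
    """
    quals = []
    for col, sym in enumerate(profile.emitted):
        if sym == "dropped":
            continue
        win = int(profile.base_counts[col, "ACGT".index(sym)])
        real = int(profile.base_counts[col].sum())
        gaps = int(profile.gap_counts[col])
        quals.append(min(max(10 * (2 * win - real - gaps), 0), 40))
    return np.asarray(quals, dtype=np.int64)


# ---------------------------------------------------------------------------
# Interchange formats

def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read a CLUSTAL ("clustal") or aligned-FASTA ("fasta") alignment."""
    aln = AlignIO.read(str(Path(path)), fmt)
    ids = [rec.id for rec in aln]
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    return Alignment(ids=ids, rows=rows, ncol=aln.get_alignment_length())


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for rid in aln.ids:
            fh.write(f">{rid}\n")
            row = aln.rows[rid]
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
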