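"""Seed-and-extend local homology search with e-value scoring.

Three search modes mirror the BLAST programs a repeat annotator would run:
protein query against a six-frame-translated genome (``tblastn_like``),
nucleotide query against the genome on both strands (``blastn_like``), and
translated nucleotide query against the translated genome (``tblastx_like``).

The internal backend is deliberately simple and fully deterministic: exact
k-mer seeding (k=4 for amino acids, k=11 for nucleotides) followed by
ungapped X-drop extension, scored with BLOSUM62 for proteins and +1/−2 for
nucleotides.  E-values use the ungapped Karlin–Altschul formula
``E = K·m·n·exp(−λ·S)`` with published ungapped constants.  Stop codons in
translated frames are retained as ``*`` and score −4 against everything —
degraded elements accumulate in-frame stops, and terminating the extension
there would shatter hits that a gapped search would report whole.  ``X``
(untranslatable / unknown) scores 0 against everything.

An adapter around an external BLAST+ installation with the same interface
lives in :mod:`teharvest.blast_adapter`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .seqio import Genome, LibraryEntry, revcomp

# ---------------------------------------------------------------------------
# Alphabets and scoring

AA_ORDER = "ARNDCQEGHILKMFPSTWYVX*"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}
_X_IDX = _AA_INDEX["X"]
_STOP_IDX = _AA_INDEX["*"]

# Ungapped Karlin-Altschul (lambda, K) for the two scoring systems used here.
KA_PARAMS = {
    "blosum62": (0.3176, 0.134),
    "nt+1-2": (1.28, 0.46),
}

NT_MATCH = 1
NT_MISMATCH = -2
STOP_SCORE = -4


def _build_blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(AA_ORDER), len(AA_ORDER)), dtype=np.int32)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            if a == "X" or b == "X":
                m[i, j] = 0
            elif a == "*" or b == "*":
                m[i, j] = STOP_SCORE
            else:
                m[i, j] = int(raw[a, b])
    return m


BLOSUM62 = _build_blosum62()

_NT_SCORE = np.full((5, 5), NT_MISMATCH, dtype=np.int32)
for _i in range(4):
    _NT_SCORE[_i, _i] = NT_MATCH
_NT_SCORE[4, :] = NT_MISMATCH  # N never matches
_NT_SCORE[:, 4] = NT_MISMATCH

_NT_ENC = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _NT_ENC[ord(_c)] = _i

_AA_ENC = np.full(256, _X_IDX, dtype=np.int64)
for _c, _i in _AA_INDEX.items():
    _AA_ENC[ord(_c)] = _i


def encode_nt(seq: str) -> np.ndarray:
    return _NT_ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _build_codon_table() -> np.ndarray:
    """Map base-5 codon codes (A,C,G,T,N = 0..4) to encoded amino acids."""
    table = CodonTable.unambiguous_dna_by_id[1]
    out = np.full(125, _X_IDX, dtype=np.int64)
    for b1 in range(4):
        for b2 in range(4):
            for b3 in range(4):
                codon = "ACGT"[b1] + "ACGT"[b2] + "ACGT"[b3]
                code = b1 * 25 + b2 * 5 + b3
                if codon in table.stop_codons:
                    out[code] = _STOP_IDX
                else:
                    out[code] = _AA_INDEX[table.forward_table[codon]]
    return out


_CODON_TABLE = _build_codon_table()
_AA_CHARS_ARR = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Six-frame translation

@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a nucleotide sequence.

    `frame` follows BLAST conventions: +1..+3 read the forward strand
    starting at offsets 0..2; −1..−3 read the reverse complement starting at
    offsets 0..2.  `aa` keeps stop codons as ``*`` and N-containing codons
    as ``X``.
    """

    frame: int
    aa: str
    nt_length: int

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval in this frame to a forward-strand nt interval."""
        off = abs(self.frame) - 1
        s = off + 3 * aa_start
        e = off + 3 * aa_end
        if self.frame > 0:
            return s, e
        return self.nt_length - e, self.nt_length - s


def _translate_frame(codes: np.ndarray, offset: int) -> str:
    usable = (len(codes) - offset) // 3
    if usable <= 0:
        return ""
    c = codes[offset : offset + usable * 3].reshape(usable, 3)
    codon_codes = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    return _AA_CHARS_ARR[_CODON_TABLE[codon_codes]].tobytes().decode()


def translate_six_frames(nt: str) -> list[FrameTranslation]:
    """Translate all six reading frames, with coordinate maps back to nt."""
    fwd = encode_nt(nt)
    rev = encode_nt(revcomp(nt))
    frames = []
    for off in range(3):
        frames.append(FrameTranslation(off + 1, _translate_frame(fwd, off), len(nt)))
    for off in range(3):
        frames.append(FrameTranslation(-(off + 1), _translate_frame(rev, off), len(nt)))
    return frames


# ---------------------------------------------------------------------------
# E-values

def estimate_evalue(
    raw_score: float, query_len: int, db_len: int, scoring: str = "blosum62"
) -> float:
    """Ungapped Karlin-Altschul e-value ``E = K·m·n·exp(−λ·S)``.

    Lengths are raw (no edge correction); only behaviour around the cutoff
    matters for this pipeline.
    """
    if scoring not in KA_PARAMS:
        raise KeyError(f"unknown scoring system {scoring!r}")
    lam, k = KA_PARAMS[scoring]
    return k * query_len * db_len * math.exp(-lam * raw_score)


def bitscore(raw_score: float, scoring: str = "blosum62") -> float:
    lam, k = KA_PARAMS[scoring]
    return (lam * raw_score - math.log(k)) / math.log(2)


# ---------------------------------------------------------------------------
# Hits and configuration

@dataclass(frozen=True)
class Hit:
    """One local alignment of a library query against the genome."""

    id: str
    query_id: str
    contig: str
    start: int  # forward-strand bp, 0-based half-open
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0 in nucleotide mode
    score: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit {self.id}: empty interval")
        if self.evalue < 0:
            raise ValueError(f"hit {self.id}: negative e-value")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SearchConfig:
    mode: str = "tblastn_like"  # tblastn_like | blastn_like | tblastx_like
    evalue_cutoff: float = 1e-20
    seed_length: Optional[int] = None  # default: 4 aa, 11 nt
    xdrop: int = 20
    scoring: Optional[str] = None  # default by mode

    def __post_init__(self) -> None:
        if self.mode not in ("tblastn_like", "blastn_like", "tblastx_like"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.seed_length is None:
            self.seed_length = 11 if self.mode == "blastn_like" else 4
        if self.seed_length < 2:
            raise ValueError("seed_length must be >= 2")
        if self.scoring is None:
            self.scoring = "nt+1-2" if self.mode == "blastn_like" else "blosum62"


@dataclass
class SearchResult:
    hits: dict[str, list[Hit]]
    best_evalue: Optional[float] = None  # best e-value seen, kept or not


class ModeAlphabetError(ValueError):
    """Query alphabet incompatible with the requested search mode."""


# ---------------------------------------------------------------------------
# Seeding and extension internals

def _kmer_codes(codes: np.ndarray, k: int, base: int, invalid: Optional[int]) -> np.ndarray:
    """Rolling k-mer integer codes; windows containing `invalid` get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = out * base + codes[i : i + n]
    if invalid is not None:
        bad = codes == invalid
        if bad.any():
            window_bad = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64))[
                k - 1 : k - 1 + n
            ]
            out[window_bad > 0] = -1
    return out


def _extend(
    q: np.ndarray,
    s: np.ndarray,
    qpos: int,
    spos: int,
    k: int,
    matrix: np.ndarray,
    xdrop: int,
) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension around an exact k-mer seed.

    Returns (q_start, q_end, s_start, s_end, score).
    """
    score = 0
    for i in range(k):
        score += matrix[q[qpos + i], s[spos + i]]
    # right
    best = score
    cur = score
    qi, si = qpos + k, spos + k
    best_q, best_s = qi, si
    while qi < len(q) and si < len(s):
        cur += matrix[q[qi], s[si]]
        qi += 1
        si += 1
        if cur > best:
            best, best_q, best_s = cur, qi, si
        elif best - cur > xdrop:
            break
    q_end, s_end = best_q, best_s
    # left
    cur = best
    best2 = best
    qi, si = qpos, spos
    best_q, best_s = qi, si
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        cur += matrix[q[qi], s[si]]
        if cur > best2:
            best2, best_q, best_s = cur, qi, si
        elif best2 - cur > xdrop:
            break
    return best_q, q_end, best_s, s_end, int(best2)


def _chain_segments(
    segments: list[tuple[int, int, int, int, int]],
    max_join_gap: int = 50,
    max_diag_drift: int = 20,
) -> list[tuple[int, int, int, int, int]]:
    """Chain co-linear ungapped segments into single hits.

    A diverged element copy accumulates indels, which break one homologous
    region into several ungapped extensions on slightly shifted diagonals.
    Chaining segments separated by a short subject gap with a small
    diagonal drift — the minimal stand-in for gapped extension — lets the
    combined alignment pass the e-value cutoff as one hit, the way a gapped
    search would report it.  Scores add; the gap itself scores nothing.
    """
    if len(segments) <= 1:
        return segments
    segs = sorted(segments, key=lambda t: (t[2], t[3], t[0]))
    out: list[list[int]] = [list(segs[0])]
    for qs, qe, ss, se, score in segs[1:]:
        cur = out[-1]
        gap = ss - cur[3]
        diag_prev = cur[2] - cur[0]
        drift = abs((ss - qs) - diag_prev)
        if -max_diag_drift <= gap <= max_join_gap and drift <= max_diag_drift and qs >= cur[0]:
            cur[1] = max(cur[1], qe)
            cur[3] = max(cur[3], se)
            cur[4] += score
        else:
            out.append([qs, qe, ss, se, score])
    return [tuple(c) for c in out]


def _seeded_hits(
    query_codes: np.ndarray,
    subject_codes: np.ndarray,
    k: int,
    base: int,
    invalid: Optional[int],
    matrix: np.ndarray,
    xdrop: int,
) -> list[tuple[int, int, int, int, int]]:
    """All deduplicated, chained ungapped extensions of exact k-mer seeds.

    Seeds on a diagonal already covered by a previous extension on that
    diagonal are skipped; co-located extensions keep the best score;
    co-linear extensions separated by short gaps are chained.
    """
    qk = _kmer_codes(query_codes, k, base, invalid)
    sk = _kmer_codes(subject_codes, k, base, invalid)
    if len(qk) == 0 or len(sk) == 0:
        return []
    qmap: dict[int, list[int]] = {}
    for i, code in enumerate(qk):
        if code >= 0:
            qmap.setdefault(int(code), []).append(i)
    cand = np.nonzero(np.isin(sk, np.fromiter(qmap.keys(), dtype=np.int64)))[0]
    seeds: list[tuple[int, int]] = []  # (diag, spos) with qpos = spos - diag
    for spos in cand:
        for qpos in qmap[int(sk[spos])]:
            seeds.append((int(spos) - qpos, int(spos)))
    seeds.sort()
    results: dict[tuple[int, int, int], tuple[int, int, int, int, int]] = {}
    covered_diag: Optional[int] = None
    covered_end = -1
    for diag, spos in seeds:
        if diag == covered_diag and spos < covered_end:
            continue
        qs, qe, ss, se, score = _extend(
            query_codes, subject_codes, spos - diag, spos, k, matrix, xdrop
        )
        covered_diag, covered_end = diag, se
        key = (diag, ss, se)
        if key not in results or results[key][4] < score:
            results[key] = (qs, qe, ss, se, score)
    return _chain_segments(list(results.values()))


# ---------------------------------------------------------------------------
# Public search

def _check_mode(entry: LibraryEntry, mode: str) -> None:
    if entry.alphabet == "aa" and mode != "tblastn_like":
        raise ModeAlphabetError(
            f"amino-acid query {entry.id!r} requires tblastn_like mode"
        )
    if entry.alphabet == "nt" and mode == "tblastn_like":
        raise ModeAlphabetError(
            f"nucleotide query {entry.id!r} cannot be used in tblastn_like mode"
        )


def search_with_stats(
    queries: list[LibraryEntry], genome: Genome, cfg: SearchConfig
) -> SearchResult:
    """Run the configured search; also report the best e-value observed.

    The best-e-value statistic covers every extension, including those above
    the cutoff, so a "family absent" outcome can state how close the nearest
    miss was.
    """
    for q in queries:
        _check_mode(q, cfg.mode)
    hits: dict[str, list[Hit]] = {q.id: [] for q in queries}
    best_e: Optional[float] = None
    serial = 0

    translated = cfg.mode in ("tblastn_like", "tblastx_like")
    if translated:
        db_len = sum(
            (len(s) - off) // 3
            for s in genome.records.values()
            for off in range(3)
        ) * 2
        frames_by_contig = {
            c: translate_six_frames(s) for c, s in genome.records.items()
        }
    else:
        db_len = genome.total_length

    for entry in queries:
        if cfg.mode == "tblastn_like":
            subqueries = [(entry.sequence, None)]  # (aa string, query frame)
        elif cfg.mode == "tblastx_like":
            subqueries = [
                (ft.aa, ft.frame) for ft in translate_six_frames(entry.sequence) if ft.aa
            ]
        else:
            subqueries = [(entry.sequence, None)]

        for qseq, _qframe in subqueries:
            m = len(qseq)
            if m < (cfg.seed_length or 0):
                continue
            if translated:
                q_codes = encode_aa(qseq)
                for contig, frames in frames_by_contig.items():
                    for ft in frames:
                        if len(ft.aa) < cfg.seed_length:
                            continue
                        s_codes = encode_aa(ft.aa)
                        for qs, qe, ss, se, score in _seeded_hits(
                            q_codes, s_codes, cfg.seed_length, len(AA_ORDER),
                            None, BLOSUM62, cfg.xdrop,
                        ):
                            ev = estimate_evalue(score, m, db_len, cfg.scoring)
                            best_e = ev if best_e is None else min(best_e, ev)
                            if ev >= cfg.evalue_cutoff:
                                continue
                            g_s, g_e = ft.aa_to_nt(ss, se)
                            serial += 1
                            hits[entry.id].append(Hit(
                                id=f"h{serial}",
                                query_id=entry.id, contig=contig,
                                start=g_s, end=g_e,
                                strand="+" if ft.frame > 0 else "-",
                                frame=ft.frame, score=score,
                                bitscore=bitscore(score, cfg.scoring), evalue=ev,
                            ))
            else:
                for strand, qseq_oriented in (("+", qseq), ("-", revcomp(qseq))):
                    q_codes = encode_nt(qseq_oriented)
                    for contig, s in genome.records.items():
                        if len(s) < cfg.seed_length:
                            continue
                        s_codes = encode_nt(s)
                        for qs, qe, ss, se, score in _seeded_hits(
                            q_codes, s_codes, cfg.seed_length, 4,
                            4, _NT_SCORE, cfg.xdrop,
                        ):
                            ev = estimate_evalue(score, m, db_len, cfg.scoring)
                            best_e = ev if best_e is None else min(best_e, ev)
                            if ev >= cfg.evalue_cutoff:
                                continue
                            serial += 1
                            hits[entry.id].append(Hit(
                                id=f"h{serial}",
                                query_id=entry.id, contig=contig,
                                start=ss, end=se, strand=strand,
                                frame=0, score=score,
                                bitscore=bitscore(score, cfg.scoring), evalue=ev,
                            ))

    for key in hits:
        hits[key].sort(key=lambda h: (h.contig, h.start, h.end, h.strand, h.frame))
    return SearchResult(hits=hits, best_evalue=best_e)


def search(
    queries: list[LibraryEntry], genome: Genome, cfg: SearchConfig
) -> dict[str, list[Hit]]:
    """Map each query id to its e-value-filtered hits (deterministic)."""
    return search_with_stats(queries, genome, cfg).hits
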