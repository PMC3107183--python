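"""Greedy overlap-layout-consensus assembly and quality-based trimming.

Extracted element copies are assembled into consensus contigs carrying
per-base integer quality scores, in the spirit of the small
overlap-assemblers classically used for repeat curation.  The assembler is
reference-free and deterministic: candidate overlaps are found by shared
16-mer diagonal voting between current consensus sequences, verified by
banded edit-distance alignment over the seeded span (minimum overlap 40 bp,
minimum identity 90%, both orientations), and merged best-score-first.

Per consensus column the quality is ``10 × (agreeing − disagreeing member
bases)``, clipped to [0, 40].  Two agreeing members with no conflict score
20, a lone member 10, and a deep but conflicted column (for example stacked
random flanking sequence) scores near 0 — so the default trimming threshold
of 18 keeps regions supported by at least two concordant copies and removes
single-copy overhangs and incoherent flanks.  Reads that assemble with
nothing are returned as singlets with uniform quality 20 so that the
downstream singlet fallback does not silently delete them.

Trimming slides a window (20 bp by default) across the quality track: a
base is high-quality if any window containing it has mean quality above the
threshold.  Short low-quality gaps (≤ 50 bp by default) flanked on both
sides by high-quality runs are retained; the longest stitched segment is
the trimmed sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

QUAL_PER_MEMBER = 10
QUAL_CAP = 40
SINGLET_QUAL = 20


class AssemblyError(ValueError):
    pass


class NoViableCodingRegion(RuntimeError):
    """All assembly products trimmed to nothing."""


@dataclass
class QualContig:
    """A consensus sequence with per-base integer quality scores."""

    id: str
    sequence: str
    quality: np.ndarray  # int, same length as sequence
    n_members: int
    members: list[str]

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int64)
        if len(self.quality) != len(self.sequence):
            raise AssemblyError(f"{self.id}: quality/sequence length mismatch")
        if self.n_members != len(self.members) or self.n_members < 1:
            raise AssemblyError(f"{self.id}: bad member bookkeeping")


@dataclass
class TrimConfig:
    window: int = 20
    threshold: float = 18.0
    max_low_gap: int = 50

    def __post_init__(self) -> None:
        if self.window < 1 or self.threshold < 0 or self.max_low_gap < 0:
            raise ValueError("invalid trim configuration")


# ---------------------------------------------------------------------------
# Internal assembly units

class _Unit:
    """A growing contig: per-column A/C/G/T member counts and span coverage.

    ``spancov[j]`` counts the members whose layout extent covers column j,
    whether or not they contribute a base there; a member spanning a column
    without a base (a deletion, or an insertion private to another member)
    is an implicit gap vote against that column.  Working consensus keeps
    every column; when a contig is finalized, only columns whose winning
    base holds a tie-inclusive majority against mismatch-plus-gap votes
    (``2·agree >= spancov``) are emitted, which removes private insertions
    and incoherently stacked flanking sequence in one stroke.
    """

    __slots__ = ("uid", "counts", "spancov", "members", "_consensus")

    def __init__(
        self, uid: str, counts: np.ndarray, spancov: np.ndarray, members: list[str]
    ):
        self.uid = uid
        self.counts = counts
        self.spancov = spancov
        self.members = members
        self._consensus: Optional[str] = None

    @classmethod
    def from_read(
        cls, uid: str, seq: str, qual: Optional[np.ndarray] = None
    ) -> "_Unit":
        """Build a unit from one read, optionally weighted by its quality.

        A read that is itself a trimmed consensus carries its quality
        forward: a column of quality q counts as ``clip(q/10, 1, 4)``
        agreeing members, so re-assembly does not mistake well-supported
        single-source sequence for thin coverage.
        """
        if qual is None:
            weight = np.ones(len(seq), dtype=np.int32)
        else:
            weight = np.clip(
                np.round(np.asarray(qual, dtype=np.float64) / QUAL_PER_MEMBER),
                1, QUAL_CAP // QUAL_PER_MEMBER,
            ).astype(np.int32)
        counts = np.zeros((len(seq), 4), dtype=np.int32)
        for i, b in enumerate(seq):
            j = _BASE_IDX.get(b)
            if j is not None:
                counts[i, j] = weight[i]
        return cls(uid, counts, weight.copy(), [uid])

    def emission_mask(self) -> np.ndarray:
        """Columns whose winning base holds a (tie-inclusive) majority
        against the combined mismatch and gap votes."""
        agree = self.counts.max(axis=1)
        return (2 * agree >= self.spancov) & (agree > 0)

    @property
    def consensus(self) -> str:
        if self._consensus is None:
            best = self.counts.argmax(axis=1)  # ties break A<C<G<T
            chars = np.frombuffer(_IDX_BASE.encode(), dtype=np.uint8)[best]
            self._consensus = chars.tobytes().decode()
        return self._consensus

    def reverse_complement(self) -> "_Unit":
        # complement swaps A<->T (cols 0,3) and C<->G (cols 1,2)
        counts = self.counts[::-1, [3, 2, 1, 0]].copy()
        return _Unit(self.uid, counts, self.spancov[::-1].copy(), self.members)

    def quality(self) -> np.ndarray:
        agree = self.counts.max(axis=1)
        q = QUAL_PER_MEMBER * (2 * agree - self.spancov)
        return np.clip(q, 0, QUAL_CAP)


@dataclass
class _Overlap:
    score: int
    diag: int  # modal layout offset: other's base 0 in self coordinates
    flipped: bool
    span: tuple[int, int]  # k-mer-supported span, in self coordinates
    edge_diags: tuple[int, int]  # local diagonals at the span's two edges
    identity: float


def _kmer_positions(seq: str, k: int, max_occ: int = 4) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i)
    return {km: p for km, p in pos.items() if len(p) <= max_occ}


def _find_overlap(
    a: str, b: str, min_overlap: int, min_identity: float, k: int = 16,
    diag_band: int = 30,
) -> Optional[tuple[int, int, tuple[int, int], tuple[int, int], float]]:
    """Best layout offset of b against a, or None.

    Returns (score, diag, (span_start, span_end), (diag_left, diag_right),
    identity).  The identity check runs over the span actually supported by
    shared k-mers (± a small diagonal band for indels), so divergent random
    overhangs outside the homologous core do not veto an otherwise solid
    overlap.  The edge diagonals give the local layout offset at the two
    span boundaries — with internal indels they can differ from the modal
    offset, and tails beyond the span must be placed with the local one.
    """
    if len(a) < k or len(b) < k:
        return None
    apos = _kmer_positions(a, k)
    votes: dict[int, int] = {}
    matches: list[tuple[int, int]] = []  # (a position, diag)
    for j in range(len(b) - k + 1):
        for i in apos.get(b[j : j + k], ()):
            d = i - j
            votes[d] = votes.get(d, 0) + 1
            matches.append((i, d))
    if not votes:
        return None
    # modal diagonal, ties to the smallest offset
    diag = min(votes, key=lambda d: (-votes[d], d))
    band = sorted((i, d) for i, d in matches if abs(d - diag) <= diag_band)
    sa, d_left = band[0]
    last_i, d_right = band[-1]
    se = last_i + k
    span = se - sa
    if span < min_overlap:
        return None
    bs = max(0, sa - d_left)
    be = min(len(b), se - d_right)
    if be - bs < min_overlap:
        return None
    res = edlib.align(a[sa:se], b[bs:be], mode="NW", task="distance")
    dist = res["editDistance"]
    identity = 1.0 - dist / max(span, be - bs)
    if identity < min_identity:
        return None
    score = span - 2 * dist
    return score, diag, (sa, se), (d_left, d_right), identity


def _merge_units(
    a: _Unit, b: _Unit, diag: int, uid: str,
    span: Optional[tuple[int, int]] = None,
    edge_diags: Optional[tuple[int, int]] = None,
) -> _Unit:
    """Merge unit b into a (b[0] sits near a[diag]).

    Within the homologous span (in a's coordinates) the column
    correspondence comes from an optimal edit-distance alignment.  Outside
    it — typically unrelated flanking sequence — columns are stacked
    position-locked at the span edge's *local* diagonal: free alignment of
    unrelated sequence manufactures spurious agreement, while locking at
    the modal offset would misplace tails that sit past internal indels.
    """
    ca, cb = a.consensus, b.consensus
    if span is None:
        sa, se = max(0, diag), min(len(ca), diag + len(cb))
        d_left = d_right = diag
    else:
        sa, se = span
        d_left, d_right = edge_diags if edge_diags is not None else (diag, diag)
    b_sa = min(max(sa - d_left, 0), len(cb))
    b_se = min(max(se - d_right, b_sa), len(cb))
    blocks: list[np.ndarray] = []
    spans: list[np.ndarray] = []

    # left tail: lock columns pairwise walking out from the span edge
    n_left = min(sa, b_sa)
    if sa > n_left:
        blocks.append(a.counts[: sa - n_left])
        spans.append(a.spancov[: sa - n_left])
    elif b_sa > n_left:
        blocks.append(b.counts[: b_sa - n_left])
        spans.append(b.spancov[: b_sa - n_left])
    if n_left:
        blocks.append(a.counts[sa - n_left : sa] + b.counts[b_sa - n_left : b_sa])
        spans.append(a.spancov[sa - n_left : sa] + b.spancov[b_sa - n_left : b_sa])

    res = edlib.align(ca[sa:se], cb[b_sa:b_se], mode="NW", task="path")
    ai, bi = sa, b_sa
    for num, op in _CIGAR_RE.findall(res["cigar"] or ""):
        n = int(num)
        if op in ("=", "X", "M"):
            blocks.append(a.counts[ai : ai + n] + b.counts[bi : bi + n])
            spans.append(a.spancov[ai : ai + n] + b.spancov[bi : bi + n])
            ai += n
            bi += n
        elif op == "I":  # columns private to a; b still spans them
            blocks.append(a.counts[ai : ai + n])
            b_at = b.spancov[min(bi, len(b.spancov) - 1)]
            spans.append(a.spancov[ai : ai + n] + b_at)
            ai += n
        else:  # "D": columns private to b; a still spans them
            blocks.append(b.counts[bi : bi + n])
            a_at = a.spancov[min(ai, len(a.spancov) - 1)]
            spans.append(b.spancov[bi : bi + n] + a_at)
            bi += n

    # right tail, symmetric
    n_right = min(len(ca) - se, len(cb) - b_se)
    if n_right:
        blocks.append(a.counts[se : se + n_right] + b.counts[b_se : b_se + n_right])
        spans.append(a.spancov[se : se + n_right] + b.spancov[b_se : b_se + n_right])
    if len(ca) - se > n_right:
        blocks.append(a.counts[se + n_right :])
        spans.append(a.spancov[se + n_right :])
    elif len(cb) - b_se > n_right:
        blocks.append(b.counts[b_se + n_right :])
        spans.append(b.spancov[b_se + n_right :])
    counts = np.concatenate(blocks, axis=0)
    spancov = np.concatenate(spans, axis=0)
    # drop columns where most spanning members have no base at all —
    # insertions private to a small minority.  The working consensus must
    # stay indel-clean or growing contigs drift below the overlap identity
    # floor and the assembly shatters.  Columns where members disagree but
    # all have bases (stacked flanking sequence) are kept: pruning them
    # would survivorship-select chance agreements.
    cov = counts.sum(axis=1)
    keep = 3 * cov >= spancov
    if not keep.all():
        counts = counts[keep]
        spancov = spancov[keep]
    return _Unit(uid, counts, spancov, sorted(a.members + b.members))


# ---------------------------------------------------------------------------
# Public assembly interface

def assemble(
    seqs: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    quals: Optional[Sequence[Optional[np.ndarray]]] = None,
    min_overlap: int = 40,
    min_identity: float = 0.9,
) -> tuple[list[QualContig], list[QualContig]]:
    """Greedy best-first OLC assembly of nucleotide sequences.

    Returns ``(contigs, singlets)``: contigs have ≥2 members and
    agreement-based quality; singlets are unmerged inputs, with uniform
    quality 20 unless they brought their own quality track (`quals`).
    Deterministic for a fixed input list.
    """
    if not seqs:
        raise AssemblyError("assemble() requires at least one input sequence")
    if ids is None:
        width = len(str(len(seqs)))
        ids = [f"s{i + 1:0{width}d}" for i in range(len(seqs))]
    if quals is None:
        quals = [None] * len(seqs)
    units: dict[str, _Unit] = {}
    had_qual: dict[str, bool] = {}
    for uid, seq, qual in zip(ids, seqs, quals):
        if uid in units:
            raise AssemblyError(f"duplicate read id {uid!r}")
        units[uid] = _Unit.from_read(uid, seq.upper(), qual)
        had_qual[uid] = qual is not None

    cache: dict[tuple[str, str], Optional[_Overlap]] = {}

    def overlap(ua: _Unit, ub: _Unit) -> Optional[_Overlap]:
        key = (ua.uid, ub.uid)
        if key in cache:
            return cache[key]
        best: Optional[_Overlap] = None
        for flipped in (False, True):
            cb = ub.reverse_complement().consensus if flipped else ub.consensus
            found = _find_overlap(ua.consensus, cb, min_overlap, min_identity)
            if found:
                score, diag, span, edge_diags, ident = found
                if best is None or score > best.score or (
                    score == best.score and not flipped and best.flipped
                ):
                    best = _Overlap(score, diag, flipped, span, edge_diags, ident)
        cache[key] = best
        return best

    serial = 0
    while len(units) > 1:
        keys = sorted(units)
        best_pair: Optional[tuple[str, str]] = None
        best_ov: Optional[_Overlap] = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                ov = overlap(units[ka], units[kb])
                if ov is None:
                    continue
                if best_ov is None or ov.score > best_ov.score:
                    best_pair, best_ov = (ka, kb), ov
                elif ov.score == best_ov.score and best_pair is not None:
                    # tie-break: longer resulting contig, then member ids
                    cand_len = len(units[ka].consensus) + len(units[kb].consensus)
                    cur_len = (
                        len(units[best_pair[0]].consensus)
                        + len(units[best_pair[1]].consensus)
                    )
                    cand_ids = sorted(units[ka].members + units[kb].members)
                    cur_ids = sorted(
                        units[best_pair[0]].members + units[best_pair[1]].members
                    )
                    if cand_len > cur_len or (
                        cand_len == cur_len and cand_ids < cur_ids
                    ):
                        best_pair, best_ov = (ka, kb), ov
        if best_ov is None:
            break
        ka, kb = best_pair
        ua, ub = units.pop(ka), units.pop(kb)
        if best_ov.flipped:
            ub = ub.reverse_complement()
        serial += 1
        merged = _merge_units(
            ua, ub, best_ov.diag, f"m{serial}",
            span=best_ov.span, edge_diags=best_ov.edge_diags,
        )
        for key in list(cache):
            if ka in key or kb in key:
                del cache[key]
        units[merged.uid] = merged

    contigs, singlets = [], []
    finished = sorted(
        units.values(), key=lambda u: (-len(u.consensus), u.consensus, u.uid)
    )
    for u in finished:
        if len(u.members) >= 2:
            mask = u.emission_mask()
            # In deep contigs (peak member coverage >= 6, the shape produced
            # by stacking many extracted instances) terminal columns spanned
            # by almost none of the members are chance agreements of a
            # couple of flanking bases, not element sequence; a third of the
            # peak coverage separates the two.  Shallow contigs keep their
            # overhangs: there a single-member extension is ordinary
            # assembly territory and the quality trim decides its fate.
            sc = u.spancov[mask]
            if len(sc) and sc.max() >= 6:
                floor = sc.max() / 3
                lo, hi = 0, len(sc)
                while lo < hi and sc[lo] < floor:
                    lo += 1
                while hi > lo and sc[hi - 1] < floor:
                    hi -= 1
                idx = np.nonzero(mask)[0][lo:hi]
                mask = np.zeros_like(mask)
                mask[idx] = True
            seq = "".join(c for c, keep in zip(u.consensus, mask) if keep)
            contigs.append(QualContig(
                id=f"contig{len(contigs) + 1}", sequence=seq,
                quality=u.quality()[mask], n_members=len(u.members),
                members=u.members,
            ))
        else:
            if had_qual.get(u.members[0], False):
                qual = np.clip(u.quality(), SINGLET_QUAL, QUAL_CAP)
            else:
                qual = np.full(len(u.consensus), SINGLET_QUAL, dtype=np.int64)
            singlets.append(QualContig(
                id=f"singlet{len(singlets) + 1}", sequence=u.consensus,
                quality=qual, n_members=1, members=u.members,
            ))
    return contigs, singlets


# ---------------------------------------------------------------------------
# Quality trimming

@dataclass
class TrimResult:
    sequence: str
    start: int  # kept interval in contig coordinates, half-open
    end: int
    quality: Optional[np.ndarray] = None  # quality track of the kept interval

    @property
    def empty(self) -> bool:
        return self.start >= self.end


def _high_quality_mask(quality: np.ndarray, cfg: TrimConfig) -> np.ndarray:
    """A base is high-quality iff some full window covering it has mean
    quality above the threshold; short contigs use the whole-contig mean."""
    q = np.asarray(quality, dtype=np.float64)
    n = len(q)
    w = cfg.window
    if n == 0:
        return np.zeros(0, dtype=bool)
    if n < w:
        return np.full(n, q.mean() > cfg.threshold, dtype=bool)
    cs = np.concatenate([[0.0], np.cumsum(q)])
    means = (cs[w:] - cs[:-w]) / w  # window starting at i, i in [0, n-w]
    ok = means > cfg.threshold
    oc = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    j = np.arange(n)
    lo = np.clip(j - w + 1, 0, n - w)
    hi = np.clip(j, 0, n - w)
    return (oc[hi + 1] - oc[lo]) > 0


def trim_by_quality(contig: QualContig, cfg: Optional[TrimConfig] = None) -> TrimResult:
    """Return the best high-quality segment of a contig.

    Maximal high-quality runs are stitched across low-quality gaps no longer
    than ``max_low_gap`` when flanked by high-quality runs on both sides;
    the longest stitched segment wins, leftmost on ties.  Terminal bases
    individually below the threshold are then shaved off, so boundary
    windows cannot drag weak overhangs along.  An entirely low-quality
    contig yields an empty result.
    """
    cfg = cfg or TrimConfig()
    mask = _high_quality_mask(contig.quality, cfg)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return TrimResult("", 0, 0)
    segments: list[tuple[int, int]] = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = segments[-1]
        if s - pe <= cfg.max_low_gap:
            segments[-1] = (ps, e)
        else:
            segments.append((s, e))
    best = max(segments, key=lambda se: (se[1] - se[0], -se[0]))
    # shave terminal bases individually below the threshold: a window
    # straddling the segment boundary can mark up to window-1 weak bases
    # as high-quality on the strength of its interior neighbours alone
    s, e = best
    q = np.asarray(contig.quality, dtype=np.float64)
    while s < e and q[s] < cfg.threshold:
        s += 1
    while e > s and q[e - 1] < cfg.threshold:
        e -= 1
    return TrimResult(
        contig.sequence[s:e], s, e,
        quality=np.asarray(contig.quality[s:e]),
    )


def best_coding_region(
    seqs: Sequence[str],
    trim_cfg: Optional[TrimConfig] = None,
    ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Assemble, trim, reassemble, trim: the best putative coding regions.

    If the first assembly yields no contigs the singlets are carried through
    the same trim/reassemble path.  Results are sorted longest-first.
    Raises :class:`NoViableCodingRegion` if everything trims to nothing.
    """
    trim_cfg = trim_cfg or TrimConfig()
    contigs, singlets = assemble(seqs, ids=ids)
    pool = contigs if contigs else singlets
    round1 = [t for c in pool if not (t := trim_by_quality(c, trim_cfg)).empty]
    if not round1:
        raise NoViableCodingRegion("all assembly products trimmed to nothing")
    # trimmed consensus sequences carry their quality into the reassembly
    contigs2, singlets2 = assemble(
        [t.sequence for t in round1], quals=[t.quality for t in round1]
    )
    pool2 = contigs2 if contigs2 else singlets2
    round2 = [t.sequence for c in pool2 if not (t := trim_by_quality(c, trim_cfg)).empty]
    if not round2:
        raise NoViableCodingRegion("reassembly products trimmed to nothing")
    return sorted(round2, key=lambda s: (-len(s), s))
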