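"""Turn a candidate alignment region into a full alignment.

The matching regions of a CAR are already exact matches, so only the unmatched
regions need work: the stretch left of the first region (LMUR), right of the
last (RMUR), and between consecutive regions (MRURs). Each unmatched region is
classified by its split cause — Mismatch, Insertion (three subtypes), Deletion
(three subtypes), or Mixed — from the read-gap/reference-gap pair; pure causes
translate directly into CIGAR operations, and only Mixed regions are handed to
Needleman-Wunsch dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import CorruptCarError, InvalidCarError
from .index_core import HybridIndex
from .seeding import CandidateAlignmentRegion, MatchingRegion

Cigar = list[tuple[int, str]]


@dataclass(frozen=True)
class SplitCause:
    """Why a matched region ends: the classified edit between two anchors."""

    kind: str  # Mismatch | Insertion | Deletion | Mixed
    n_bases: int = 0
    subtype: Optional[int] = None  # 1|2|3 for Insertion/Deletion


@dataclass(frozen=True)
class ScoringScheme:
    """Linear gap scoring for alignment; defaults 2 / -2 / -3."""

    match: int = 2
    mismatch: int = -2
    gap: int = -3

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("match must be positive; mismatch and gap negative")

    def base(self, a: str, b: str) -> int:
        return self.match if a == b else self.mismatch


@dataclass
class PairInfo:
    """Mate bookkeeping attached to one alignment of a paired read."""

    mate_index: int  # 0 = first in pair, 1 = second
    proper: bool = False
    mate_unmapped: bool = False
    mate_record: Optional[str] = None
    mate_pos: int = 0
    mate_reverse: bool = False
    tlen: int = 0


@dataclass
class AlignmentResult:
    """One read placement, serializable as a SAM record.

    ``ref_pos`` is the 0-based leftmost coordinate within ``ref_record``;
    ``cigar`` is a list of (count, op) with op in {M, I, D, S}.
    """

    ref_record: str
    ref_pos: int
    strand: str  # "+" or "-"
    cigar: Cigar
    score: int
    nm: int
    mapq: int = 0
    matches: int = 0
    read_len: int = 0
    pair: Optional[PairInfo] = None

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.cigar if op in ("M", "D"))

    @property
    def ref_end(self) -> int:
        return self.ref_pos + self.ref_span


def _emit(ops: Cigar, n: int, op: str) -> None:
    if n <= 0:
        return
    if ops and ops[-1][1] == op:
        ops[-1] = (ops[-1][0] + n, op)
    else:
        ops.append((n, op))


def classify_mrur(prev: MatchingRegion, nxt: MatchingRegion) -> Optional[SplitCause]:
    """Split cause of the unmatched region between two chained matching regions.

    With read gap g_r = nxt.ro - prev.ro_end and reference gap
    g_s = nxt.sp - prev.sp_end (negative gaps are overlaps):

    * (1, 1)                      -> Mismatch of 1
    * g_r > 0,  g_s == 0          -> Insertion 1 of g_r
    * g_r >= 0, g_s < 0           -> Insertion 2 of g_r - g_s
    * g_r < 0,  g_s < g_r         -> Insertion 3 of g_r - g_s
    * g_r == 0, g_s > 0           -> Deletion 1 of g_s
    * g_r < 0,  g_s >= 0          -> Deletion 2 of g_s - g_r
    * g_r < 0,  g_r < g_s < 0     -> Deletion 3 of g_s - g_r
    * (0, 0)                      -> no split cause (regions abut)
    * anything else               -> Mixed

    Note g_s - g_r equals the diagonal difference, i.e. deleted minus inserted
    bases, for every non-Mixed cause.
    """
    if nxt.ro < prev.ro:
        raise InvalidCarError("matching regions are not ordered by read offset")
    g_r = nxt.ro - prev.ro_end
    g_s = nxt.sp - prev.sp_end
    if g_r == 0 and g_s == 0:
        return None
    if g_r == 1 and g_s == 1:
        return SplitCause("Mismatch", 1)
    if g_r > 0 and g_s == 0:
        return SplitCause("Insertion", g_r, subtype=1)
    if g_r >= 0 and g_s < 0:
        return SplitCause("Insertion", g_r - g_s, subtype=2)
    if g_r < 0 and g_s < g_r:
        return SplitCause("Insertion", g_r - g_s, subtype=3)
    if g_r == 0 and g_s > 0:
        return SplitCause("Deletion", g_s, subtype=1)
    if g_r < 0 and g_s >= 0:
        return SplitCause("Deletion", g_s - g_r, subtype=2)
    if g_r < 0 and g_s < 0 and g_s > g_r:
        return SplitCause("Deletion", g_s - g_r, subtype=3)
    return SplitCause("Mixed", max(g_r, g_s))


def _classify_right(r: str, f: str) -> Optional[SplitCause]:
    """Flank classification with the matched region on the LEFT of ``r``.

    ``f`` is the reference immediately right of the region, possibly longer
    than ``r`` by the indel allowance.
    """
    L = len(r)
    if L == 0:
        return None
    candidates: list[tuple[int, int, SplitCause]] = []  # (cost, priority, cause)
    if len(f) >= L:
        mism = [i for i in range(L) if r[i] != f[i]]
        if not mism:
            return None  # flank matches outright (e.g. frequency-capped seed)
        if mism == list(range(mism[-1] + 1)):
            # the only mismatched bases are the ones adjacent to the region
            candidates.append((4 * len(mism), 0, SplitCause("Mismatch", len(mism))))
    for n in range(1, L):  # adjacent n read bases inserted, remainder matched
        if L - n <= len(f) and r[n:] == f[: L - n]:
            candidates.append((5 * n, 1, SplitCause("Insertion", n)))
            break
    for n in range(1, len(f) - L + 1):  # adjacent n reference bases deleted
        if r == f[n : n + L]:
            candidates.append((3 * n, 2, SplitCause("Deletion", n)))
            break
    if not candidates:
        return SplitCause("Mixed", L)
    # cheapest explanation wins (score loss per base under the default scoring:
    # a substitution forgoes a match and pays the mismatch, an inserted base
    # forgoes a match and pays a gap, a deletion pays only the gap);
    # ties break Mismatch > Insertion > Deletion for determinism
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


def classify_flank(read_flank: str, ref_flank: str, side: str) -> Optional[SplitCause]:
    """Split cause of a leftmost/rightmost unmatched region.

    ``side`` is "left" for the flank preceding the first matching region and
    "right" for the flank following the last one; "adjacent to the region"
    means the flank end that touches it. Returns None when there is nothing to
    align (empty flank, or a flank that matches the reference outright).
    """
    if side == "left":
        return _classify_right(read_flank[::-1], ref_flank[::-1])
    if side == "right":
        return _classify_right(read_flank, ref_flank)
    raise ValueError("side must be 'left' or 'right'")


def needleman_wunsch(a: str, b: str, scoring: ScoringScheme | None = None) -> tuple[int, Cigar]:
    """Global alignment of a (read-major) against b (reference), linear gaps.

    Traceback prefers diagonal over deletion (reference base consumed) over
    insertion, making the CIGAR deterministic among co-optimal alignments.
    """
    scoring = scoring or ScoringScheme()
    la, lb = len(a), len(b)
    if la == 0:
        return (lb * scoring.gap, [(lb, "D")] if lb else [])
    if lb == 0:
        return (la * scoring.gap, [(la, "I")])
    gap = scoring.gap
    prev = [j * gap for j in range(lb + 1)]
    rows = [prev]
    for i in range(1, la + 1):
        cur = [i * gap] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = max(
                prev[j - 1] + scoring.base(ai, b[j - 1]),
                cur[j - 1] + gap,
                prev[j] + gap,
            )
        rows.append(cur)
        prev = cur
    ops: Cigar = []
    i, j = la, lb
    rev: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and rows[i][j] == rows[i - 1][j - 1] + scoring.base(a[i - 1], b[j - 1]):
            rev.append("M")
            i, j = i - 1, j - 1
        elif j > 0 and rows[i][j] == rows[i][j - 1] + gap:
            rev.append("D")
            j -= 1
        else:
            rev.append("I")
            i -= 1
    for op in reversed(rev):
        _emit(ops, 1, op)
    return rows[la][lb], ops


def _semiglobal_flank(a: str, b: str, side: str, scoring: ScoringScheme) -> tuple[Cigar, int]:
    """Align flank ``a`` inside reference window ``b`` with one free window end.

    side "left": the alignment is anchored at the window's right edge (the
    matching region start) and unused window prefix is free; returns
    (cigar, ref_used) where ref_used reference bases precede the anchor.
    side "right": anchored at the window's left edge, unused suffix free.
    """
    la, lb = len(a), len(b)
    gap = scoring.gap
    if side == "left":
        a, b = a[::-1], b[::-1]
    # anchored at (0,0); free end over reference
    prev = [j * gap for j in range(lb + 1)]
    rows = [prev]
    for i in range(1, la + 1):
        cur = [i * gap] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = max(
                prev[j - 1] + scoring.base(ai, b[j - 1]),
                cur[j - 1] + gap,
                prev[j] + gap,
            )
        rows.append(cur)
        prev = cur
    best_j = max(range(lb + 1), key=lambda j: (rows[la][j], -j))
    i, j = la, best_j
    rev: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and rows[i][j] == rows[i - 1][j - 1] + scoring.base(a[i - 1], b[j - 1]):
            rev.append("M")
            i, j = i - 1, j - 1
        elif j > 0 and rows[i][j] == rows[i][j - 1] + gap:
            rev.append("D")
            j -= 1
        else:
            rev.append("I")
            i -= 1
    if side == "left":
        ordered = rev  # reversed input, so reversed traceback is in read order
    else:
        ordered = list(reversed(rev))
    ops: Cigar = []
    for op in ordered:
        _emit(ops, 1, op)
    return ops, best_j


def align_car(
    read: str,
    car: CandidateAlignmentRegion,
    index: HybridIndex,
    scoring: ScoringScheme | None = None,
    flank_allowance: int = 10,
) -> AlignmentResult:
    """Assemble the full alignment of ``read`` implied by one CAR.

    Matching regions become match runs; each unmatched region contributes the
    operations implied by its split cause, with Needleman-Wunsch run only on
    Mixed regions. Read bases that fall entirely outside the reference record
    are soft-clipped. The score, NM and matched-base count are recomputed from
    the final operation list against the reference.
    """
    scoring = scoring or ScoringScheme()
    read = read.upper()
    if not car.mrs:
        raise InvalidCarError("empty candidate alignment region")
    seq = index.sequence
    mrs = sorted(car.mrs, key=lambda r: r.ro)
    for mr in mrs:
        if read[mr.ro : mr.ro_end] != seq.fetch(mr.sp, mr.sp_end):
            raise CorruptCarError(
                f"matching region at ro={mr.ro}, sp={mr.sp} does not match the reference"
            )
    rec = seq.record_of(mrs[0].sp)

    ops: Cigar = []
    first = mrs[0]
    ref_start = first.sp
    lf = read[: first.ro]
    if lf:
        win_start = max(rec.start, first.sp - len(lf) - flank_allowance)
        window = seq.fetch(win_start, first.sp)
        if not window:
            _emit(ops, len(lf), "S")
        else:
            cause = classify_flank(lf, window, "left")
            if cause is None or cause.kind == "Mismatch":
                ref_start = first.sp - len(lf)
                _emit(ops, len(lf), "M")
            elif cause.kind == "Insertion":
                ref_start = first.sp - (len(lf) - cause.n_bases)
                _emit(ops, len(lf) - cause.n_bases, "M")
                _emit(ops, cause.n_bases, "I")
            elif cause.kind == "Deletion":
                ref_start = first.sp - cause.n_bases - len(lf)
                _emit(ops, len(lf), "M")
                _emit(ops, cause.n_bases, "D")
            else:
                fops, ref_used = _semiglobal_flank(lf, window, "left", scoring)
                ref_start = first.sp - ref_used
                for n, op in fops:
                    _emit(ops, n, op)

    _emit(ops, first.L, "M")
    cur_read, cur_ref = first.ro_end, first.sp_end

    for nxt in mrs[1:]:
        ro2, sp2, L2 = nxt.ro, nxt.sp, nxt.L
        if ro2 < cur_read:  # read overlap: leading region bases already matched
            d = cur_read - ro2
            ro2, sp2, L2 = ro2 + d, sp2 + d, L2 - d
        if L2 > 0 and sp2 < cur_ref:  # reference overlap: reassign as insertion
            t = min(cur_ref - sp2, L2)
            _emit(ops, (ro2 - cur_read) + t, "I")
            cur_read = ro2 + t
            ro2, sp2, L2 = ro2 + t, sp2 + t, L2 - t
            if L2 <= 0:
                continue
        if L2 <= 0:
            continue
        g_r, g_s = ro2 - cur_read, sp2 - cur_ref
        if g_r == 1 and g_s == 1:
            _emit(ops, 1, "M")
        elif g_s == 0:
            _emit(ops, g_r, "I")
        elif g_r == 0:
            _emit(ops, g_s, "D")
        elif g_r > 0 and g_s > 0:  # Mixed
            _, nw_ops = needleman_wunsch(
                read[cur_read:ro2], seq.fetch(cur_ref, sp2), scoring
            )
            for n, op in nw_ops:
                _emit(ops, n, op)
        _emit(ops, L2, "M")
        cur_read, cur_ref = ro2 + L2, sp2 + L2

    rf = read[cur_read:]
    if rf:
        win_end = min(rec.end, cur_ref + len(rf) + flank_allowance)
        window = seq.fetch(cur_ref, win_end)
        if not window:
            _emit(ops, len(rf), "S")
        else:
            cause = classify_flank(rf, window, "right")
            if cause is None or cause.kind == "Mismatch":
                _emit(ops, len(rf), "M")
            elif cause.kind == "Insertion":
                _emit(ops, cause.n_bases, "I")
                _emit(ops, len(rf) - cause.n_bases, "M")
            elif cause.kind == "Deletion":
                _emit(ops, cause.n_bases, "D")
                _emit(ops, len(rf), "M")
            else:
                fops, _ = _semiglobal_flank(rf, window, "right", scoring)
                for n, op in fops:
                    _emit(ops, n, op)

    score, nm, matches = _score_ops(read, seq, ref_start, ops, scoring)
    read_consumed = sum(n for n, op in ops if op in ("M", "I", "S"))
    assert read_consumed == len(read), "CIGAR does not conserve the read length"
    return AlignmentResult(
        ref_record=rec.name,
        ref_pos=ref_start - rec.start,
        strand="+",
        cigar=ops,
        score=score,
        nm=nm,
        matches=matches,
        read_len=len(read),
    )


def _score_ops(
    read: str, seq, ref_start: int, ops: Cigar, scoring: ScoringScheme
) -> tuple[int, int, int]:
    """Walk the CIGAR against read and reference: (score, NM, matched bases)."""
    ri, fi = 0, ref_start
    score = nm = matches = 0
    for n, op in ops:
        if op == "M":
            ref = seq.fetch(fi, fi + n)
            for k in range(n):
                if read[ri + k] == ref[k]:
                    score += scoring.match
                    matches += 1
                else:
                    score += scoring.mismatch
                    nm += 1
            ri += n
            fi += n
        elif op == "I":
            score += scoring.gap * n
            nm += n
            ri += n
        elif op == "D":
            score += scoring.gap * n
            nm += n
            fi += n
        elif op == "S":
            ri += n
    return score, nm, matches


def reconstruct_read(result: AlignmentResult, ref_window: str, read: str) -> str:
    """Rebuild the read by applying the CIGAR's edits to ``ref_window``.

    Match runs copy reference bases, insertions and soft clips copy read
    bases, deletions skip reference bases. The output therefore equals the
    read at every position except substitutions, whose count must equal NM
    minus the inserted and deleted bases — the invariant the tests check.
    """
    out = []
    ri = fi = 0
    for n, op in result.cigar:
        if op == "M":
            out.append(ref_window[fi : fi + n])
            ri += n
            fi += n
        elif op in ("I", "S"):
            out.append(read[ri : ri + n])
            ri += n
        elif op == "D":
            fi += n
    return "".join(out)


def compute_mapq(
    best: AlignmentResult, second: Optional[AlignmentResult] = None, scale: int = 2
) -> int:
    """Mapping quality from the best/second-best score gap.

    A unique placement gets 60; otherwise max(0, min(60, scale * gap)), so two
    equal-scoring placements get 0.
    """
    if second is None:
        return 60
    return max(0, min(60, scale * (best.score - second.score)))
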