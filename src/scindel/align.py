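"""Semi-global affine-gap pairwise alignment and amplicon assignment.

Reads are aligned end-to-end in the read and with free gaps at both
reference ends ("glocal"), the natural contract for amplicon reads that
may be clipped relative to the reference.  Gap cost for a gap of length
L is ``gap_open + L * gap_extend``.  Traceback is deterministic (on
equal score a deletion is preferred over an insertion over a diagonal
step) and indels are subsequently left-normalized, so repeated runs
produce identical operation lists.

The inner dynamic program is JIT-compiled with numba; the Python layer
handles traceback, normalization and panel assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .panel import Panel
from .seq import revcomp

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme; penalties are magnitudes (applied as negative)."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")


DEFAULT_SCORING = AlignmentScoring()


@dataclass
class ReadAlignment:
    """Base-level alignment of a read against one amplicon reference.

    ``ops`` is an ordered list of ``(op, length, ref_pos)`` tuples with
    op in {"M", "X", "I", "D"}.  For M/X/D ``ref_pos`` is the 0-based
    reference start of the run; for I it is the inter-base insertion
    point.  ``identity`` is matches over aligned columns (M+X+I+D).
    """

    amplicon_id: str
    score: int
    ref_start: int
    ref_end: int
    ops: list = field(default_factory=list)
    identity: float = 0.0
    strand: str = "+"

    @property
    def n_columns(self) -> int:
        return sum(length for _, length, _ in self.ops)


_DIAG, _DEL, _INS = 0, 1, 2


@njit(cache=True)
def _gotoh(x, y, match, mismatch, go, ge):  # pragma: no cover - jitted
    """Fill semi-global Gotoh matrices.

    x: reference codes, y: read codes.  Returns (H, ptrH, ptrD, ptrI).
    ptrH holds the state achieving H (0 diag, 1 del, 2 ins); ptrD/ptrI
    are 1 where the gap state was extended from itself.
    """
    n = x.size
    m = y.size
    NEG = -(1 << 29)
    H = np.empty((m + 1, n + 1), np.int32)
    D = np.empty((m + 1, n + 1), np.int32)
    I = np.empty((m + 1, n + 1), np.int32)
    ptrH = np.zeros((m + 1, n + 1), np.int8)
    ptrD = np.zeros((m + 1, n + 1), np.int8)
    ptrI = np.zeros((m + 1, n + 1), np.int8)
    for j in range(n + 1):
        H[0, j] = 0
        D[0, j] = NEG
        I[0, j] = NEG
    for i in range(1, m + 1):
        D[i, 0] = NEG
        iopen = H[i - 1, 0] - go - ge
        iext = I[i - 1, 0] - ge
        if iext >= iopen:
            I[i, 0] = iext
            ptrI[i, 0] = 1
        else:
            I[i, 0] = iopen
        H[i, 0] = I[i, 0]
        ptrH[i, 0] = 2
        yi = y[i - 1]
        for j in range(1, n + 1):
            if yi == x[j - 1] and yi != 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch
            dopen = H[i, j - 1] - go - ge
            dext = D[i, j - 1] - ge
            if dext >= dopen:
                D[i, j] = dext
                ptrD[i, j] = 1
            else:
                D[i, j] = dopen
            iopen = H[i - 1, j] - go - ge
            iext = I[i - 1, j] - ge
            if iext >= iopen:
                I[i, j] = iext
                ptrI[i, j] = 1
            else:
                I[i, j] = iopen
            # tie priority: deletion > insertion > diagonal
            best = D[i, j]
            p = 1
            if I[i, j] > best:
                best = I[i, j]
                p = 2
            if diag > best:
                best = diag
                p = 0
            H[i, j] = best
            ptrH[i, j] = p
    return H, ptrH, ptrD, ptrI


@njit(cache=True)
def _gotoh_score(x, y, match, mismatch, go, ge):  # pragma: no cover - jitted
    """Score-only semi-global Gotoh pass (two rolling rows, no pointers)."""
    n = x.size
    m = y.size
    NEG = -(1 << 29)
    Hprev = np.zeros(n + 1, np.int32)
    Iprev = np.full(n + 1, NEG, np.int32)
    Hcur = np.empty(n + 1, np.int32)
    Icur = np.empty(n + 1, np.int32)
    for i in range(1, m + 1):
        iopen = Hprev[0] - go - ge
        iext = Iprev[0] - ge
        Icur[0] = iext if iext >= iopen else iopen
        Hcur[0] = Icur[0]
        dprev = NEG
        yi = y[i - 1]
        for j in range(1, n + 1):
            if yi == x[j - 1] and yi != 4:
                diag = Hprev[j - 1] + match
            else:
                diag = Hprev[j - 1] - mismatch
            dopen = Hcur[j - 1] - go - ge
            dext = dprev - ge
            d = dext if dext >= dopen else dopen
            iopen = Hprev[j] - go - ge
            iext = Iprev[j] - ge
            ins = iext if iext >= iopen else iopen
            best = d
            if ins > best:
                best = ins
            if diag > best:
                best = diag
            Hcur[j] = best
            Icur[j] = ins
            dprev = d
        Hprev, Hcur = Hcur, Hprev
        Iprev, Icur = Icur, Iprev
    best = Hprev[0]
    for j in range(1, n + 1):
        if Hprev[j] > best:
            best = Hprev[j]
    return best


def semiglobal_score(read_seq: str, ref_seq: str,
                     scoring: AlignmentScoring = DEFAULT_SCORING) -> int:
    """Optimal semi-global alignment score without traceback."""
    if not read_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    return int(_gotoh_score(_encode(ref_seq), _encode(read_seq),
                            scoring.match, scoring.mismatch,
                            scoring.gap_open, scoring.gap_extend))


def _traceback(x_codes, y_codes, H, ptrH, ptrD, ptrI) -> tuple[list, int, int, int]:
    """Recover alignment columns from the pointer matrices.

    Returns (columns, score, ref_start, ref_end) where each column is
    (op, read_index, ref_index); indices are -1 where not consumed.
    """
    m = y_codes.size
    row = H[m]
    j_end = int(np.argmax(row))  # smallest index on ties
    score = int(row[j_end])
    cols: list[tuple[str, int, int]] = []
    i, j = m, j_end
    while i > 0:
        state = ptrH[i, j]
        if state == _DIAG:
            op = "M" if (y_codes[i - 1] == x_codes[j - 1] and y_codes[i - 1] != 4) else "X"
            cols.append((op, i - 1, j - 1))
            i -= 1
            j -= 1
        elif state == _DEL:
            while True:
                cols.append(("D", -1, j - 1))
                ext = ptrD[i, j]
                j -= 1
                if not ext:
                    break
        else:
            while True:
                cols.append(("I", i - 1, -1))
                ext = ptrI[i, j]
                i -= 1
                if not ext:
                    break
    cols.reverse()
    return cols, score, j, j_end


def _left_normalize(cols: list, ref: str, read: str) -> list:
    """Shift indel runs as far left as the flanking sequence allows.

    A deletion of ref[a:b) may move one base left when ref[a-1] == ref[b-1]
    and the preceding column is an aligned base; similarly for insertions
    with read bases.  Match/mismatch status of the displaced column is
    preserved by the equality condition, so the score is unchanged.
    """
    cols = list(cols)
    k = 0
    while k < len(cols):
        op = cols[k][0]
        if op not in ("I", "D"):
            k += 1
            continue
        # locate the run [k, end)
        end = k
        while end < len(cols) and cols[end][0] == op:
            end += 1
        moved = True
        while moved:
            moved = False
            prev = k - 1
            if prev < 0 or cols[prev][0] not in ("M", "X"):
                break
            if op == "D":
                a = cols[k][2]
                b = cols[end - 1][2] + 1
                if ref[a - 1] == ref[b - 1]:
                    p_op, p_read, _ = cols[prev]
                    new_run = [("D", -1, a - 1 + t) for t in range(b - a)]
                    cols[prev:end] = new_run + [(p_op, p_read, b - 1)]
                    k -= 1
                    end -= 1
                    moved = True
            else:
                c = cols[k][1]
                d = cols[end - 1][1] + 1
                if read[c - 1] == read[d - 1]:
                    p_op, _, p_ref = cols[prev]
                    new_run = [("I", c - 1 + t, -1) for t in range(d - c)]
                    cols[prev:end] = new_run + [(p_op, d - 1, p_ref)]
                    k -= 1
                    end -= 1
                    moved = True
        k = end
    return cols


def _compress(cols: list, ref_start: int) -> list:
    """Collapse columns into (op, length, ref_pos) runs."""
    ops: list[tuple[str, int, int]] = []
    ref_cursor = ref_start - 1
    for op, read_i, ref_i in cols:
        if op in ("M", "X", "D"):
            ref_cursor = ref_i
            anchor = ref_i
        else:  # insertion point = next reference position
            anchor = ref_cursor + 1
        if ops and ops[-1][0] == op and (
            op == "I" or ops[-1][2] + ops[-1][1] == anchor
        ):
            ops[-1] = (op, ops[-1][1] + 1, ops[-1][2])
        else:
            ops.append((op, 1, anchor))
    return ops


def align_semiglobal(read_seq: str, ref_seq: str,
                     scoring: AlignmentScoring = DEFAULT_SCORING,
                     amplicon_id: str = "") -> ReadAlignment:
    """Optimal affine-gap alignment, global in the read, free at ref ends."""
    if not read_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    x = _encode(ref_seq)
    y = _encode(read_seq)
    H, ptrH, ptrD, ptrI = _gotoh(x, y, scoring.match, scoring.mismatch,
                                 scoring.gap_open, scoring.gap_extend)
    cols, score, ref_start, ref_end = _traceback(x, y, H, ptrH, ptrD, ptrI)
    cols = _left_normalize(cols, ref_seq, read_seq)
    ops = _compress(cols, ref_start)
    if ops:
        ref_positions = [p for op, ln, p in ops if op != "I"]
        if ref_positions:
            ref_start = min(ref_positions)
            ref_end = max(p + ln for op, ln, p in ops if op != "I")
    n_match = sum(ln for op, ln, _ in ops if op == "M")
    n_cols = sum(ln for _, ln, _ in ops)
    identity = n_match / n_cols if n_cols else 0.0
    return ReadAlignment(amplicon_id=amplicon_id, score=score,
                         ref_start=ref_start, ref_end=ref_end,
                         ops=ops, identity=identity)


@dataclass
class Assignment:
    """Result of assigning one read to the panel."""

    amplicon_id: Optional[str]
    alignment: Optional[ReadAlignment]
    oriented_seq: Optional[str]
    status: str  # "assigned", "ambiguous", "low_identity"


def assign_amplicon(payload_seq: str, panel: Panel,
                    scoring: AlignmentScoring = DEFAULT_SCORING,
                    min_identity: float = 0.65) -> Assignment:
    """Align a read payload to every amplicon (both orientations) and pick
    the best-scoring one.

    The read is unassigned when the best identity falls below
    ``min_identity`` or when the best score is tied across two or more
    amplicons (ambiguous placement).
    """
    rc = revcomp(payload_seq)
    best_score = None
    best_amp = None
    best_seq = payload_seq
    best_strand = "+"
    tied = False
    for amp in panel:
        for seq, strand in ((payload_seq, "+"), (rc, "-")):
            score = semiglobal_score(seq, amp.ref_seq, scoring)
            if best_score is None or score > best_score:
                best_score = score
                best_amp = amp
                best_seq = seq
                best_strand = strand
                tied = False
            elif score == best_score and amp.amplicon_id != best_amp.amplicon_id:
                tied = True
    if tied:
        return Assignment(None, None, None, "ambiguous")
    aln = align_semiglobal(best_seq, best_amp.ref_seq, scoring,
                           best_amp.amplicon_id)
    aln.strand = best_strand
    if aln.identity < min_identity:
        return Assignment(None, None, None, "low_identity")
    return Assignment(aln.amplicon_id, aln, best_seq, "assigned")


def alignment_to_sam_line(aln: ReadAlignment, read_id: str, seq: str) -> str:
    """Render one alignment as a SAM record against its amplicon reference."""
    cigar_parts = []
    # leading soft-clip never occurs (read is global); D at ends folded in
    for op, ln, _ in aln.ops:
        sam_op = {"M": "M", "X": "M", "I": "I", "D": "D"}[op]
        if cigar_parts and cigar_parts[-1][1] == sam_op:
            cigar_parts[-1][0] += ln
        else:
            cigar_parts.append([ln, sam_op])
    cigar = "".join(f"{ln}{op}" for ln, op in cigar_parts) or "*"
    flag = 0 if aln.strand == "+" else 16
    return "\t".join([read_id, str(flag), aln.amplicon_id,
                      str(aln.ref_start + 1), "255", cigar, "*", "0", "0",
                      seq, "*"])


def write_sam(alignments: list, panel: Panel, path) -> None:
    """Write assigned read alignments to a SAM file (amplicons as refs)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for amp in panel:
            fh.write(f"@SQ\tSN:{amp.amplicon_id}\tLN:{len(amp.ref_seq)}\n")
        for read_id, seq, aln in alignments:
            fh.write(alignment_to_sam_line(aln, read_id, seq) + "\n")
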