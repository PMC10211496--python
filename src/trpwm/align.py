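"""Wrap-around local alignment of a cyclic PWM against a DNA sequence.

The profile has one row per repeat phase 1..n; aligning it "wrap-around"
means the phase index advances cyclically, so one n-row matrix can span any
number of adjacent repeat copies.  The recurrence is Smith-Waterman-like
(cell floor at 0, affine gaps) over the grid (sequence position j, phase r):

    E(j,r) = max(H(j-1,r) - gap_open, E(j-1,r) - gap_extend)     # insertion
    F(j,r) = max(H(j,r-1) - gap_open, F(j,r-1) - gap_extend)     # deletion
    H(j,r) = max(0, H(j-1,r-1) + w(r, col(j)), E(j,r), F(j,r))

with r-1 taken modulo n.  Insertions consume a sequence base without
advancing the phase; deletions advance the phase without consuming a base.
The cyclic F recursion is resolved with a second sweep over r, which covers
deletions wrapping across the period boundary.

In di mode col(j) indexes the pair (s(j-1), s(j)), so position 1 of a window
has no score and alignments start at j >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from numba import njit

from trpwm.pwm import PositionWeightMatrix
from trpwm.seqio import DnaSequence

NEG = -1e30


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap costs in normalised-score units (both >= 0)."""

    gap_open: float = 10.0
    gap_extend: float = 2.5

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gap_open) and np.isfinite(self.gap_extend)):
            raise ValueError("gap penalties must be finite")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local wrap-around alignment of a PWM against a sequence.

    ``columns`` holds the printable alignment: one (sequence character,
    phase character) pair per alignment column, with '*' marking the gapped
    side ('*' in the sequence line = deletion; '*' in the phase line =
    insertion).  ``phase`` lists v(j) for matched sequence positions only.
    """

    f_max: float
    start: int  # 1-based inclusive; 0 for an empty alignment
    end: int
    phase: Tuple[int, ...]
    matched_positions: Tuple[int, ...]  # 1-based sequence positions, parallel to phase
    indels: Tuple[Tuple[int, str, int], ...]  # (1-based position, 'insertion'|'deletion', length)
    copy_count: int
    columns: Tuple[Tuple[str, str], ...] = field(repr=False, default=())

    @property
    def is_empty(self) -> bool:
        return self.start == 0


def sequence_columns(seq: DnaSequence, mode: str) -> np.ndarray:
    """Per-position PWM column indices (0-based); -1 where unscorable."""
    codes = seq.codes().astype(np.int64)
    if mode == "mono":
        col = codes - 1
        col[codes == 0] = -1
    else:
        col = codes[:-1] + 4 * (codes[1:] - 1) - 1
        col[(codes[:-1] == 0) | (codes[1:] == 0)] = -1
        col = np.concatenate(([np.int64(-1)], col))
    return col


@njit(cache=True)
def score_wraparound(col, W, gap_open, gap_extend):  # pragma: no cover - numba
    """F_max only (no traceback); used in the GA loop and the Monte-Carlo null."""
    L = col.shape[0]
    n = W.shape[0]
    Hp = np.zeros(n)
    Hc = np.zeros(n)
    E = np.full(n, NEG)
    F = np.full(n, NEG)
    best = 0.0
    for j in range(L):
        cj = col[j]
        for r in range(n):
            e = Hp[r] - gap_open
            e2 = E[r] - gap_extend
            E[r] = e if e > e2 else e2
            pr = r - 1 if r > 0 else n - 1
            s = W[r, cj] if cj >= 0 else NEG
            h = Hp[pr] + s
            if E[r] > h:
                h = E[r]
            if h < 0.0:
                h = 0.0
            Hc[r] = h
            F[r] = NEG
        for _ in range(2):
            for r in range(n):
                pr = r - 1 if r > 0 else n - 1
                f = Hc[pr] - gap_open
                f2 = F[pr] - gap_extend
                if f2 > f:
                    f = f2
                if f > F[r]:
                    F[r] = f
                if F[r] > Hc[r]:
                    Hc[r] = F[r]
        for r in range(n):
            if Hc[r] > best:
                best = Hc[r]
            Hp[r] = Hc[r]
    return best


@njit(cache=True)
def _fill_wraparound(col, W, gap_open, gap_extend, H, E, F, ptrH, ptrE, ptrF):  # pragma: no cover
    """Full DP with traceback pointers.

    ptrH: 0 empty/floor, 1 diag (predecessor H > 0), 4 diag start, 2 from E,
    3 from F.  ptrE/ptrF: 0 open, 1 extend.
    """
    L = col.shape[0]
    n = W.shape[0]
    besti = -1
    bestr = -1
    best = 0.0
    for j in range(L):
        cj = col[j]
        for r in range(n):
            hp = H[j - 1, r] if j > 0 else 0.0
            ep = E[j - 1, r] if j > 0 else NEG
            e = hp - gap_open
            e2 = ep - gap_extend
            if e >= e2:
                E[j, r] = e
                ptrE[j, r] = 0
            else:
                E[j, r] = e2
                ptrE[j, r] = 1
            pr = r - 1 if r > 0 else n - 1
            hd = H[j - 1, pr] if j > 0 else 0.0
            s = W[r, cj] if cj >= 0 else NEG
            h = 0.0
            p = 0
            d = hd + s
            if d > h:
                h = d
                p = 1 if hd > 0.0 else 4
            if E[j, r] > h:
                h = E[j, r]
                p = 2
            H[j, r] = h
            ptrH[j, r] = p
            F[j, r] = NEG
        for _ in range(2):
            for r in range(n):
                pr = r - 1 if r > 0 else n - 1
                f = H[j, pr] - gap_open
                pf = 0
                f2 = F[j, pr] - gap_extend
                if f2 > f:
                    f = f2
                    pf = 1
                if f > F[j, r]:
                    F[j, r] = f
                    ptrF[j, r] = pf
                if F[j, r] > H[j, r]:
                    H[j, r] = F[j, r]
                    ptrH[j, r] = 3
        for r in range(n):
            if H[j, r] > best:
                best = H[j, r]
                besti = j
                bestr = r
    return best, besti, bestr


_EMPTY = AlignmentResult(f_max=0.0, start=0, end=0, phase=(), matched_positions=(),
                         indels=(), copy_count=0, columns=())


def local_align(m: PositionWeightMatrix, seq: DnaSequence, gaps: GapPenalties = GapPenalties()) -> AlignmentResult:
    """Best wrap-around local alignment of ``m`` against ``seq``.

    Ties among equal-scoring tracebacks are broken deterministically: the DP
    keeps the first-encountered optimum (earliest end), and each traceback
    step prefers diagonal moves over gaps, which favours earlier starts and
    fewer indels.
    """
    n = m.n
    if n > len(seq):
        raise ValueError(f"period {n} exceeds sequence length {len(seq)}")
    col = sequence_columns(seq, m.mode)
    L = len(col)
    W = np.ascontiguousarray(m.w, dtype=np.float64)
    H = np.zeros((L, n))
    E = np.zeros((L, n))
    F = np.zeros((L, n))
    ptrH = np.zeros((L, n), dtype=np.int8)
    ptrE = np.zeros((L, n), dtype=np.int8)
    ptrF = np.zeros((L, n), dtype=np.int8)
    best, bj, br = _fill_wraparound(col, W, float(gaps.gap_open), float(gaps.gap_extend),
                                    H, E, F, ptrH, ptrE, ptrF)
    if best <= 0.0 or bj < 0:
        return _EMPTY

    # traceback (collected in reverse)
    cols_rev: List[Tuple[str, str]] = []
    matched_rev: List[Tuple[int, int]] = []  # (0-based j, phase 1..n)
    indel_events_rev: List[Tuple[int, str]] = []  # (0-based j, type)
    j, r = bj, br
    state = 0  # 0=H, 1=E, 2=F
    phase_steps = 0
    start0 = bj
    while True:
        if state == 0:
            p = ptrH[j, r]
            if p == 0:
                break
            if p in (1, 4):
                cols_rev.append((seq.bases[j], _phase_char(r + 1, n)))
                matched_rev.append((j, r + 1))
                phase_steps += 1
                start0 = j
                if p == 4:
                    break
                j -= 1
                r = r - 1 if r > 0 else n - 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # insertion: sequence base, no phase
            cols_rev.append((seq.bases[j], "*"))
            indel_events_rev.append((j, "insertion"))
            start0 = j
            p = ptrE[j, r]
            j -= 1
            state = 0 if p == 0 else 1
        else:  # deletion: phase advances, no base
            cols_rev.append(("*", _phase_char(r + 1, n)))
            indel_events_rev.append((j, "deletion"))
            phase_steps += 1
            p = ptrF[j, r]
            r = r - 1 if r > 0 else n - 1
            state = 0 if p == 0 else 2
        if j < 0:
            break

    columns = tuple(reversed(cols_rev))
    matched = list(reversed(matched_rev))
    indels = _merge_indels(list(reversed(indel_events_rev)))
    return AlignmentResult(
        f_max=float(best),
        start=start0 + 1,
        end=bj + 1,
        phase=tuple(ph for _, ph in matched),
        matched_positions=tuple(j0 + 1 for j0, _ in matched),
        indels=tuple(indels),
        copy_count=phase_steps // n,
        columns=columns,
    )


def _phase_char(phase: int, n: int) -> str:
    """Single display character for a phase digit; letters beyond 9 (n > 9
    wraps the printable digits, mirroring single-character phase rows)."""
    return str(phase % 10)


def _merge_indels(events: List[Tuple[int, str]]) -> List[Tuple[int, str, int]]:
    merged: List[Tuple[int, str, int]] = []
    for j0, kind in events:
        if merged and merged[-1][1] == kind and j0 <= merged[-1][0] + merged[-1][2]:
            pos, k, ln = merged[-1]
            merged[-1] = (pos, k, ln + 1)
        else:
            merged.append((j0 + 1, kind, 1))
    return merged


def multiple_alignment_text(seq: DnaSequence, aln: AlignmentResult, width: int = 90) -> str:
    """Printable alignment block: interleaved sequence/phase lines of
    ``width`` columns, '*' marking deletions (sequence line) and insertions
    (phase line)."""
    if aln.is_empty:
        return ""
    seq_line = "".join(c for c, _ in aln.columns)
    phase_line = "".join(p for _, p in aln.columns)
    out = []
    for i in range(0, len(seq_line), width):
        out.append(seq_line[i : i + width])
        out.append(phase_line[i : i + width])
    return "\n".join(out) + "\n"
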