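"""Position weight matrices, their normalisation, and GA operators.

A PWM here is an n x K real matrix scoring each position of a repeat unit
(row = phase 1..n) against each symbol (column).  K = 4 scores single bases
(mono mode); K = 16 scores adjacent base pairs (di mode), the column for
sequence position j being determined by the pair (s(j-1), s(j)).

Every matrix in a run is affinely transformed so that two sums are shared
constants across the whole matrix set:

* sum_ij pwm(i,j) * p1(i) * p2(j) = 0   (centred under the background
  composition p1 x p2, with p1(i) = 1/n and p2 the symbol frequencies of
  the scanned window);
* sum_ij pwm(i,j)^2 = n*K              (unit root-mean-square weight).

Sharing these constants keeps the alignment-score distribution comparable
across period lengths n, which is what makes ranking periods meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from trpwm.seqio import DnaSequence

Mode = Literal["mono", "di"]

#: Mono-mode column labels in code order A=1, T=2, C=3, G=4.
MONO_LABELS: tuple = ("A", "T", "C", "G")

#: Di-mode column labels: column i = s(j-1) + 4*(s(j)-1) for the pair
#: (s(j-1), s(j)), i.e. AA, TA, CA, GA, AT, TT, CT, GT, AC, ...
DINUC_LABELS: tuple = tuple(
    f"{MONO_LABELS[prev - 1]}{MONO_LABELS[cur - 1]}" for cur in range(1, 5) for prev in range(1, 5)
)


def dinucleotide_index(prev_base: int, cur_base: int) -> int:
    """Column index 1..16 of the pair (previous base, current base).

    Bases are coded A=1, T=2, C=3, G=4; the index is
    ``prev + 4*(cur - 1)`` so that columns run AA, TA, CA, GA, AT, ... GG.
    """
    if not (1 <= prev_base <= 4 and 1 <= cur_base <= 4):
        raise ValueError(f"base codes must be in 1..4, got ({prev_base}, {cur_base})")
    return prev_base + 4 * (cur_base - 1)


@dataclass(frozen=True)
class CompositionProfile:
    """Background profile (p1, p2) of a scanned window.

    p1 is uniform over the n repeat positions; p2 holds the symbol
    frequencies of the window: base counts / L in mono mode, dinucleotide
    counts / (L - 1) in di mode.
    """

    p1: np.ndarray
    p2: np.ndarray

    @classmethod
    def from_sequence(cls, seq: DnaSequence, n: int, mode: Mode) -> "CompositionProfile":
        codes = seq.codes()
        if np.any(codes == 0):
            raise ValueError("composition profile undefined for sequences containing N")
        p1 = np.full(n, 1.0 / n)
        if mode == "mono":
            counts = np.bincount(codes, minlength=5)[1:5].astype(float)
            p2 = counts / len(seq)
        elif mode == "di":
            idx = codes[:-1] + 4 * (codes[1:] - 1) - 1
            counts = np.bincount(idx, minlength=16).astype(float)
            p2 = counts / (len(seq) - 1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return cls(p1=p1, p2=p2)

    @property
    def n(self) -> int:
        return len(self.p1)

    @property
    def K(self) -> int:
        return len(self.p2)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """An n x K weight matrix; ``mode`` is 'mono' (K=4) or 'di' (K=16)."""

    w: np.ndarray
    mode: Mode

    def __post_init__(self) -> None:
        if self.w.ndim != 2:
            raise ValueError("PWM weights must be 2-dimensional")
        K = self.w.shape[1]
        if (self.mode, K) not in (("mono", 4), ("di", 16)):
            raise ValueError(f"mode {self.mode!r} inconsistent with {K} columns")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def K(self) -> int:
        return self.w.shape[1]

    @property
    def labels(self) -> tuple:
        return MONO_LABELS if self.mode == "mono" else DINUC_LABELS

    def to_tsv(self) -> str:
        """Full-precision machine output (TSV, header of column labels)."""
        lines = ["\t".join(("pos",) + self.labels)]
        for i, row in enumerate(self.w, start=1):
            lines.append("\t".join([str(i)] + [repr(float(x)) for x in row]))
        return "\n".join(lines) + "\n"

    def format_table(self) -> str:
        """Human-readable table, one decimal place per cell."""
        head = "    " + "".join(f"{lab:>7}" for lab in self.labels)
        rows = [
            f"{i:<4}" + "".join(f"{x:7.1f}" for x in row)
            for i, row in enumerate(self.w, start=1)
        ]
        return "\n".join([head] + rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PositionWeightMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")[1:]
        w = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
        mode: Mode = "mono" if len(header) == 4 else "di"
        return cls(w=w, mode=mode)


def _normalize_weights(w: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Affine map a*w + b enforcing the two shared constants (see module doc)."""
    bg = np.outer(p1, p2)
    s1 = float((w * bg).sum())  # sum p1 p2 == 1, so centring is w - s1
    centred = w - s1
    ss = float((centred**2).sum())
    if ss <= 0 or not np.isfinite(ss):
        raise ValueError("degenerate (constant) matrix cannot be normalised")
    return centred * np.sqrt(w.size / ss)


def normalize_pwm(m: PositionWeightMatrix, prof: CompositionProfile) -> PositionWeightMatrix:
    """Return the normalised copy of ``m`` (idempotent up to float error)."""
    if prof.n != m.n or prof.K != m.K:
        raise ValueError("profile dimensions do not match matrix")
    return PositionWeightMatrix(w=_normalize_weights(m.w, prof.p1, prof.p2), mode=m.mode)


def random_pwm(n: int, K: int, seed: int, prof: CompositionProfile | None = None) -> PositionWeightMatrix:
    """A random normalised PWM: cells i.i.d. uniform on [-10, 10], then
    normalised against ``prof`` (uniform background if omitted)."""
    if n < 2:
        raise ValueError("period n must be >= 2")
    mode: Mode = "mono" if K == 4 else "di"
    rng = np.random.default_rng(seed)
    w = rng.uniform(-10.0, 10.0, size=(n, K))
    if prof is None:
        prof = CompositionProfile(p1=np.full(n, 1.0 / n), p2=np.full(K, 1.0 / K))
    return PositionWeightMatrix(w=_normalize_weights(w, prof.p1, prof.p2), mode=mode)


def mutate_pwm(m: PositionWeightMatrix, seed: int, prof: CompositionProfile | None = None,
               renormalize: bool = True) -> PositionWeightMatrix:
    """Replace one randomly selected cell with U[-10, 10]; re-normalise."""
    rng = np.random.default_rng(seed)
    w = m.w.copy()
    i = rng.integers(m.n)
    j = rng.integers(m.K)
    w[i, j] = rng.uniform(-10.0, 10.0)
    if renormalize:
        if prof is None:
            prof = CompositionProfile(p1=np.full(m.n, 1.0 / m.n), p2=np.full(m.K, 1.0 / m.K))
        w = _normalize_weights(w, prof.p1, prof.p2)
    return PositionWeightMatrix(w=w, mode=m.mode)


def crossover(parent1: PositionWeightMatrix, parent2: PositionWeightMatrix, seed: int,
              prof: CompositionProfile | None = None, renormalize: bool = True,
              rowwise: bool = False) -> PositionWeightMatrix:
    """Uniform crossover: each cell (or each row when ``rowwise``) is copied
    from either parent with probability 1/2; result re-normalised."""
    if parent1.w.shape != parent2.w.shape or parent1.mode != parent2.mode:
        raise ValueError("parents must share (n, K) and mode")
    rng = np.random.default_rng(seed)
    if rowwise:
        mask = rng.integers(0, 2, size=(parent1.n, 1)).astype(bool)
        mask = np.broadcast_to(mask, parent1.w.shape)
    else:
        mask = rng.integers(0, 2, size=parent1.w.shape).astype(bool)
    w = np.where(mask, parent1.w, parent2.w)
    if renormalize:
        if prof is None:
            prof = CompositionProfile(p1=np.full(parent1.n, 1.0 / parent1.n),
                                      p2=np.full(parent1.K, 1.0 / parent1.K))
        w = _normalize_weights(w, prof.p1, prof.p2)
    return PositionWeightMatrix(w=w, mode=parent1.mode)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Phase-by-symbol count matrix M(n, K)."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def K(self) -> int:
        return self.counts.shape[1]


def frequency_matrix(seq: DnaSequence, phase: Sequence[int], n: int, mode: Mode) -> FrequencyMatrix:
    """Accumulate the count matrix M(n, K) for a phase assignment v(j).

    Mono mode adds 1 to cell (v(j), s(j)) for every j; di mode starts at
    j = 2 and adds 1 to cell (v(j), dinucleotide_index(s(j-1), s(j))), so an
    ungapped full-length assignment contributes exactly L - 1 counts.
    """
    phase = np.asarray(phase, dtype=int)
    if len(phase) != len(seq):
        raise ValueError("phase vector length must equal sequence length")
    if np.any((phase < 1) | (phase > n)):
        raise ValueError(f"phase values must lie in 1..{n}")
    codes = seq.codes().astype(int)
    if np.any(codes == 0):
        raise ValueError("frequency matrix undefined for sequences containing N")
    K = 4 if mode == "mono" else 16
    counts = np.zeros((n, K), dtype=np.int64)
    if mode == "mono":
        np.add.at(counts, (phase - 1, codes - 1), 1)
    else:
        col = codes[:-1] + 4 * (codes[1:] - 1) - 1
        np.add.at(counts, (phase[1:] - 1, col), 1)
    return FrequencyMatrix(counts=counts)
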