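"""Sequence input, window extraction and composition-preserving shuffles.

Coordinates are 0-based half-open internally; every coordinate that leaves
the package (window starts, repeat-region bounds) is 1-based inclusive, the
convention used for chromosome positions in genome annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Tuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

# base codes follow the A=1, T=2, C=3, G=4 convention used throughout the
# dinucleotide column ordering (AA, TA, CA, GA, AT, ...)
BASE_CODE = {"A": 1, "T": 2, "C": 3, "G": 4}
CODE_BASE = {v: k for k, v in BASE_CODE.items()}


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence over {A, C, G, T, N}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(self.bases) if b in bad)
            raise ValueError(
                f"sequence {self.id!r} contains illegal character "
                f"{self.bases[pos]!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def L(self) -> int:
        return len(self.bases)

    def codes(self) -> np.ndarray:
        """Base codes A=1, T=2, C=3, G=4 (N mapped to 0)."""
        lut = np.zeros(256, dtype=np.int8)
        for b, c in BASE_CODE.items():
            lut[ord(b)] = c
        return lut[np.frombuffer(self.bases.encode(), dtype=np.uint8)]

    def window(self, start0: int, length: int) -> "DnaSequence":
        """Extract a window by 0-based start (internal convention)."""
        return DnaSequence(f"{self.id}:{start0 + 1}-{start0 + length}", self.bases[start0 : start0 + length])


@dataclass(frozen=True)
class WindowSpec:
    """Scan-window geometry.

    ``step`` is the fine scan step that drives the local-maxima vector
    indexed by window start; the coarser 600 b tiling used for whole-window
    comparison sets is a separate constructor (:func:`tiling_windows`).
    """

    window_length: int = 1200
    step: int = 10
    drop_n_windows: bool = True

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _clean(seq: str, rec_id: str) -> str:
    up = seq.upper()
    bad = set(up) - ALPHABET
    if bad:
        pos = next(i for i, b in enumerate(up) if b in bad)
        raise ValueError(
            f"record {rec_id!r}: illegal character {up[pos]!r} at position {pos + 1}"
        )
    return up


def read_fasta(path: str | Path) -> List[DnaSequence]:
    """Read a multi-record FASTA file into validated :class:`DnaSequence` objects.

    Lowercase bases are folded to uppercase; any character outside
    {A,C,G,T,N} (either case) raises ``ValueError`` naming its position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} is empty")
        out.append(DnaSequence(rec.id, _clean(seq, rec.id)))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def read_plain_sequence(path: str | Path, seq_id: str | None = None) -> DnaSequence:
    """Read a plain-text single-sequence file (optional line wrapping).

    Used for supplementary-style artificial sequence files that carry no
    FASTA header.
    """
    path = Path(path)
    text = "".join(path.read_text().split())
    if not text:
        raise ValueError(f"{path}: empty sequence file")
    return DnaSequence(seq_id or path.stem, _clean(text, path.stem))


def windows(seq: DnaSequence, spec: WindowSpec) -> Iterator[Tuple[int, DnaSequence]]:
    """Yield (1-based start k, window) sliding along ``seq``.

    Windows are exactly ``spec.window_length`` long; a final partial window
    is dropped.  When ``drop_n_windows`` is set, windows containing N are
    skipped (and counted in a log message).
    """
    L, w = len(seq), spec.window_length
    skipped = 0
    for start0 in range(0, L - w + 1, spec.step):
        win = seq.window(start0, w)
        if spec.drop_n_windows and "N" in win.bases:
            skipped += 1
            continue
        yield start0 + 1, win
    if skipped:
        logger.info("windows: skipped %d windows containing N in %s", skipped, seq.id)


def tiling_windows(seq: DnaSequence, window_length: int = 1200, tile_step: int = 600,
                   drop_n_windows: bool = True) -> List[Tuple[int, DnaSequence]]:
    """Coarse half-overlapping tiling (600 b step): fragments from
    ``tile_step*i + 1`` to ``window_length + tile_step*i``."""
    return list(windows(seq, WindowSpec(window_length, tile_step, drop_n_windows)))


def shuffle_sequence(seq: DnaSequence, seed: int) -> DnaSequence:
    """Random permutation of the bases; mononucleotide composition is
    preserved exactly.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.bases.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return DnaSequence(seq.id + "|shuffled", arr.tobytes().decode())
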