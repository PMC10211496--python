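"""Generators for artificial tandem-repeat benchmark sequences.

The St(x) family multiplies a random unit into a perfect tandem array and
then degrades it with random substitutions and indels.  The divergence
parameter x is the average number of substitutions per base separating two
repeat copies: each substitution changes one copy relative to the others,
so it contributes twice to a pairwise comparison, giving

    x = 2 * n_substitutions / L

which reproduces the standard grid (0, 100, 500, 1000, 1500, 1800, 2200,
2400 substitutions in L = 1200) -> x = (0, 0.17, 0.85, 1.7, 2.5, 3.0,
3.7, 4.0) at the printed rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np

from trpwm.seqio import DnaSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TandemSpec:
    """Recipe for one St(x) benchmark sequence."""

    unit: str
    copies: int
    n_substitutions: int = 0
    n_indels: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("copies must be >= 2")
        if self.n_substitutions < 0 or self.n_indels < 0:
            raise ValueError("substitution/indel counts must be >= 0")
        if set(self.unit) - set("ACGT"):
            raise ValueError("unit must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies


def random_unit(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_st(spec: TandemSpec) -> Tuple[DnaSequence, float]:
    """Build the degraded tandem array and return (sequence, x).

    Each substitution event picks a random position (with replacement, so
    heavily mutated grids can exceed one event per position) and always
    changes the base; the single-base indels (insertion or deletion,
    coin-flipped) are applied afterwards at random positions.
    """
    L = spec.length
    rng = np.random.default_rng(spec.seed)
    arr = np.frombuffer((spec.unit * spec.copies).encode(), dtype=np.uint8).copy()
    # substitution events pick positions with replacement: counts above L
    # (x > 2) are part of the benchmark grid and revisit positions
    pos = rng.integers(L, size=spec.n_substitutions)
    for p in pos:
        alt = _BASES[_BASES != arr[p]]
        arr[p] = alt[rng.integers(3)]
    seq = list(arr.tobytes().decode())
    for _ in range(spec.n_indels):
        if rng.integers(2) == 0 and len(seq) > 1:  # deletion
            del seq[rng.integers(len(seq))]
        else:  # insertion
            seq.insert(rng.integers(len(seq) + 1), chr(_BASES[rng.integers(4)]))
    x = 2.0 * spec.n_substitutions / L
    name = f"St_x{x:.2f}_seed{spec.seed}"
    return DnaSequence(name, "".join(seq)), x


def make_block_sequence(blocks: Sequence[str], L: int, seed: int = 0) -> DnaSequence:
    """Concatenate L/len(block) blocks drawn uniformly from ``blocks``.

    With the four blocks ATCG, TAGC, CCAA, GGTT every base has expected
    frequency 0.25, so the periodicity is invisible to mononucleotide
    frequencies and lives entirely in the dinucleotide correlation.
    """
    lens = {len(b) for b in blocks}
    if len(lens) != 1:
        raise ValueError("all blocks must have equal length")
    (bl,) = lens
    if L % bl != 0:
        raise ValueError(f"L={L} not divisible by block length {bl}")
    rng = np.random.default_rng(seed)
    picks = rng.integers(len(blocks), size=L // bl)
    return DnaSequence(f"blocks_seed{seed}", "".join(blocks[i] for i in picks))


#: Units of the two worked-example constructions.  The period-21 unit is a
#: synthetic 21-base reconstruction (ATCG x5 + G) that nests a period-4
#: repeat inside the 21-base period, matching the described structure.
HARMONIC_UNITS = {
    "period10": ("ATCGATTCGG", 120),
    "period21": ("ATCGATCGATCGATCGATCGG", 57),
}


def make_harmonic_example(kind: str, seed: int = 0, n_substitutions: int = 1200,
                          n_indels: int = 0) -> DnaSequence:
    """Synthetic regeneration of the two worked-example sequences.

    'period10': {ATCGATTCGG} x 120 (1,200 b) with 1,200 random
    substitutions - the repeat is detectable at period 10, while raw
    fitness favours the harmonic 20.
    'period21': a 21-base unit containing a nested period-4 repeat, x 57
    (1,197 b) with 1,200 random substitutions - dinucleotide scoring
    resolves the long period where mononucleotide scoring locks onto the
    nested period 4.

    These are fresh random constructions with the same recipe as the
    originals, not the original files.
    """
    if kind not in HARMONIC_UNITS:
        raise ValueError(f"kind must be one of {sorted(HARMONIC_UNITS)}")
    unit, copies = HARMONIC_UNITS[kind]
    n_sub = min(n_substitutions, len(unit) * copies)
    seq, _ = make_st(TandemSpec(unit=unit, copies=copies, n_substitutions=n_sub,
                                n_indels=n_indels, seed=seed))
    return DnaSequence(f"{kind}_seed{seed}", seq.bases)


def write_fasta_with_truth(seq: DnaSequence, truth: dict, fasta_path: str | Path,
                           truth_path: str | Path) -> None:
    """Write the sequence as FASTA plus a JSON sidecar describing how it was
    built (unit, coordinates, x, seed) for downstream harnesses."""
    fasta_path, truth_path = Path(fasta_path), Path(truth_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq.bases[i : i + 70] + "\n")
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
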