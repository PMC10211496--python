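"""Genetic algorithm maximising the wrap-around alignment score F_max.

One GA run optimises a population of PWMs against a single (window, period)
pair.  Per generation: rank fitness, point-mutate a handful of randomly
selected non-elite matrices, breed one descendant by uniform crossover of
two random parents, drop the worst matrix, and re-align only what changed.
The elite (current best) matrix is protected from mutation and replacement,
so the reported best fitness V(1) is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from trpwm.align import AlignmentResult, GapPenalties, local_align, score_wraparound, sequence_columns
from trpwm.pwm import CompositionProfile, Mode, PositionWeightMatrix, _normalize_weights
from trpwm.seqio import DnaSequence


@dataclass(frozen=True)
class GaConfig:
    """GA hyper-parameters.

    The polish settings control profile re-estimation: periodically the
    current elite's alignment is converted back into a frequency matrix,
    normalised, and re-scored; the rebuilt matrix joins the population only
    if its fitness improves on the elite.  This is a hill-climbing move on
    the same objective (an EM-style step, as in iterative profile
    refinement), so the best fitness stays monotone; it accelerates
    convergence by orders of magnitude on divergent repeats.
    ``polish_pseudocount`` shrinks the rebuilt counts towards the window's
    background composition, damping self-fit on sparse cells.
    """

    population: int = 500
    mutants_per_generation: int = 10
    stall_generations: int = 100
    max_generations: int = 5000
    seed: int = 0
    renormalize: bool = True
    rowwise_crossover: bool = False
    polish: bool = True
    polish_every: int = 10
    polish_pseudocount: float = 0.5
    polish_max_iter: int = 25

    def __post_init__(self) -> None:
        if self.population < 3:
            raise ValueError("population must be >= 3")
        if not (0 < self.mutants_per_generation < self.population):
            raise ValueError("mutants_per_generation must be in (0, population)")
        if self.polish_every < 1 or self.polish_pseudocount < 0:
            raise ValueError("invalid polish settings")


@dataclass(frozen=True)
class GaResult:
    best_matrix: PositionWeightMatrix
    v1: float
    alignment: AlignmentResult
    generations_run: int
    alignment_calls: int


def _normalize_batch(pop: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Vectorised version of the two-constant normalisation over a stack."""
    s1 = (pop * bg).sum(axis=(1, 2), keepdims=True)
    centred = pop - s1
    ss = (centred**2).sum(axis=(1, 2), keepdims=True)
    if np.any(ss <= 0):
        raise ValueError("degenerate matrix in population")
    return centred * np.sqrt(bg.size / ss)


def polish_weights(W: np.ndarray, seq: DnaSequence, col: np.ndarray,
                   prof: CompositionProfile, gaps: GapPenalties, mode: Mode,
                   pseudocount: float = 0.5, max_iter: int = 25) -> tuple:
    """Iterated profile re-estimation (EM-style hill climbing).

    Align W, rebuild an n x K count matrix from the alignment's phase
    assignment, shrink it towards the background (``pseudocount`` scales a
    background-proportional addition to the counts), normalise, and accept
    only if the alignment score improves.  Returns (weights, score,
    alignment_calls_used).
    """
    go, ge = float(gaps.gap_open), float(gaps.gap_extend)
    bg = np.outer(prof.p1, prof.p2)
    W = np.ascontiguousarray(W, dtype=np.float64)
    v = score_wraparound(col, W, go, ge)
    calls = 1
    for _ in range(max_iter):
        aln = local_align(PositionWeightMatrix(w=W, mode=mode), seq, gaps)
        calls += 1
        if aln.is_empty:
            break
        counts = np.zeros_like(W)
        for pos1, ph in zip(aln.matched_positions, aln.phase):
            c = col[pos1 - 1]
            if c >= 0:
                counts[ph - 1, c] += 1
        total = counts.sum()
        if total == 0:
            break
        counts = counts + pseudocount * total * bg
        if counts.std() == 0:
            break
        W2 = np.ascontiguousarray(_normalize_weights(counts, prof.p1, prof.p2))
        v2 = score_wraparound(col, W2, go, ge)
        calls += 1
        if v2 <= v + 1e-9:
            break
        W, v = W2, v2
    return W, float(v), calls


def optimize(seq: DnaSequence, n: int, mode: Mode, cfg: GaConfig = GaConfig(),
             gaps: GapPenalties = GapPenalties()) -> GaResult:
    """Run the GA for one (window, period) pair and return the best matrix,
    its fitness V(1), and its full alignment."""
    L = len(seq)
    if L == 0:
        raise ValueError("empty window")
    if n < 2 or n > L // 4:
        raise ValueError(f"period {n} invalid for window of length {L} (need 2 <= n <= L/4)")
    K = 4 if mode == "mono" else 16
    prof = CompositionProfile.from_sequence(seq, n, mode)
    bg = np.outer(prof.p1, prof.p2)
    col = sequence_columns(seq, mode)
    go, ge = float(gaps.gap_open), float(gaps.gap_extend)
    rng = np.random.default_rng(cfg.seed)

    N = cfg.population
    pop = _normalize_batch(rng.uniform(-10.0, 10.0, size=(N, n, K)), bg)
    V = np.empty(N)
    for i in range(N):
        V[i] = score_wraparound(col, pop[i], go, ge)
    calls = N

    best_v = float(V.max())
    stall = 0
    gen = 0
    while gen < cfg.max_generations and stall < cfg.stall_generations:
        gen += 1
        elite = int(np.argmax(V))
        # mutate: one random cell per selected non-elite matrix
        candidates = np.delete(np.arange(N), elite)
        mutants = rng.choice(candidates, size=cfg.mutants_per_generation, replace=False)
        for i in mutants:
            r = rng.integers(n)
            c = rng.integers(K)
            pop[i, r, c] = rng.uniform(-10.0, 10.0)
        # breed one descendant from two random parents
        pa, pb = rng.choice(N, size=2, replace=False)
        if cfg.rowwise_crossover:
            mask = rng.integers(0, 2, size=(n, 1)).astype(bool)
            mask = np.broadcast_to(mask, (n, K))
        else:
            mask = rng.integers(0, 2, size=(n, K)).astype(bool)
        child = np.where(mask, pop[pa], pop[pb])
        # drop the worst (never the elite) and slot the descendant in
        worst = int(np.argmin(V))
        if worst == elite:
            worst = int(np.argsort(V)[1]) if N > 1 else worst
        pop[worst] = child
        changed = set(int(i) for i in mutants)
        changed.add(worst)
        idx = np.fromiter(changed, dtype=int)
        if cfg.renormalize:
            pop[idx] = _normalize_batch(pop[idx], bg)
        for i in idx:
            V[i] = score_wraparound(col, pop[i], go, ge)
        calls += len(idx)
        if cfg.polish and gen % cfg.polish_every == 0:
            # alternate exploitation (elite) and exploration (fresh random
            # restart): re-estimation from a fresh matrix probes a new phase
            # basin, which population members of a converged GA cannot
            elite = int(np.argmax(V))
            if (gen // cfg.polish_every) % 2 == 0:
                W0 = pop[elite]
                floor = V[elite]
            else:
                W0 = _normalize_batch(rng.uniform(-10.0, 10.0, size=(1, n, K)), bg)[0]
                floor = -np.inf
            Wp, vp, used = polish_weights(W0, seq, col, prof, gaps, mode,
                                          cfg.polish_pseudocount, cfg.polish_max_iter)
            calls += used
            if vp > floor + 1e-9:
                slot = int(np.argmin(V))
                if vp > V[slot]:
                    pop[slot] = Wp
                    V[slot] = vp
        v = float(V.max())
        if v > best_v + 1e-12:
            best_v = v
            stall = 0
        else:
            stall += 1

    best = int(np.argmax(V))
    if cfg.polish:
        Wp, vp, used = polish_weights(pop[best], seq, col, prof, gaps, mode,
                                      cfg.polish_pseudocount, cfg.polish_max_iter)
        calls += used
        if vp > V[best] + 1e-9:
            pop[best] = Wp
            V[best] = vp
    matrix = PositionWeightMatrix(w=pop[best].copy(), mode=mode)
    # the final traceback alignment is for reporting, not part of the
    # incremental re-alignment budget tracked by ``alignment_calls``
    aln = local_align(matrix, seq, gaps)
    return GaResult(best_matrix=matrix, v1=float(V[best]), alignment=aln,
                    generations_run=gen, alignment_calls=calls)
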