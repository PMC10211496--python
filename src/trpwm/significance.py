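"""Monte-Carlo significance Z(n), period selection and FDR calibration.

The alignment score of the GA-optimised matrix is standardised against a
null ensemble: the window is shuffled (preserving mononucleotide
composition), the FIXED optimised matrix is re-aligned to each shuffle, and

    Z(n) = (V(1) - mean_null) / sd_null.

The GA is not re-run on the shuffles; the selection bias this leaves in Z
is absorbed into the empirically calibrated threshold Z0 (see
:func:`calibrate_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from trpwm.align import GapPenalties, score_wraparound, sequence_columns
from trpwm.ga import GaConfig, GaResult, optimize
from trpwm.pwm import Mode
from trpwm.seqio import DnaSequence, shuffle_sequence


def z_score(seq: DnaSequence, n: int, best: GaResult, replicates: int = 50,
            seed: int = 0, gaps: GapPenalties = GapPenalties(),
            cfg: Optional[GaConfig] = None) -> float:
    """Monte-Carlo Z(n) of ``best.v1`` against composition-preserving shuffles.

    Each shuffle is scored with the fixed optimised matrix; when the
    optimisation used profile-re-estimation polish (``cfg.polish``, the
    default), the null matrix is given the same polish opportunity against
    its shuffle, so the self-fit gain of the re-estimation step cancels out
    of Z instead of inflating it.

    Raises ``ValueError`` on a degenerate (zero-variance) null ensemble.
    """
    if replicates < 10:
        raise ValueError("replicates must be >= 10")
    if cfg is None:
        cfg = GaConfig()
    from trpwm.ga import polish_weights
    from trpwm.pwm import CompositionProfile

    W = np.ascontiguousarray(best.best_matrix.w, dtype=np.float64)
    mode = best.best_matrix.mode
    go, ge = float(gaps.gap_open), float(gaps.gap_extend)
    rng = np.random.default_rng(seed)
    null = np.empty(replicates)
    for i in range(replicates):
        sh = shuffle_sequence(seq, int(rng.integers(2**31)))
        col = sequence_columns(sh, mode)
        if cfg.polish:
            prof = CompositionProfile.from_sequence(sh, n, mode)
            _, null[i], _ = polish_weights(W, sh, col, prof, gaps, mode,
                                           cfg.polish_pseudocount, cfg.polish_max_iter)
        else:
            null[i] = score_wraparound(col, W, go, ge)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate null ensemble: zero variance across shuffles")
    return (best.v1 - float(null.mean())) / sd


@dataclass(frozen=True)
class PeriodScanResult:
    """Per-period GA results over a scanned period range.

    ``statistic`` records how the winning period was chosen: 'z' ranks
    periods by Monte-Carlo Z(n) (mRPWM-style), 'v1' by raw best fitness
    V(1) (RPWM-style, in which case ``z`` entries are NaN).
    """

    periods: Tuple[int, ...]
    z: Dict[int, float]
    v1: Dict[int, float]
    results: Dict[int, GaResult] = field(repr=False)
    n_max: int = 0
    statistic: str = "z"
    replicates: int = 50

    @property
    def best(self) -> GaResult:
        return self.results[self.n_max]

    @property
    def z_max(self) -> float:
        return self.z[self.n_max]

    def fundamental_period(self, margin: Optional[float] = None) -> int:
        """Fundamental of the winning period's harmonic family.

        A repeat of period d is also periodic at every multiple of d, so on
        a strong repeat the Z profile plateaus across the whole harmonic
        family and the raw argmax degenerates into a tie broken by
        Monte-Carlo estimator noise.  This returns the smallest divisor of
        ``n_max`` (within the scanned range) whose Z lies within ``margin``
        of Z(n_max); divisors below the plateau (no genuine sub-period) are
        not taken.  The default margin, 2 * Z(n_max) / sqrt(replicates),
        tracks the sampling noise of a Z estimate from ``replicates``
        shuffles.
        """
        return fundamental_period(self.z, self.n_max, margin, self.replicates)


def fundamental_period(z_by_n: Mapping[int, float], n_max: int,
                       margin: Optional[float] = None, replicates: int = 50) -> int:
    """Module-level form of :meth:`PeriodScanResult.fundamental_period`,
    usable on aggregated (e.g. median-over-replicates) Z curves."""
    z_max = z_by_n[n_max]
    if margin is None:
        margin = 2.0 * abs(z_max) / np.sqrt(replicates)
    for d in range(2, n_max):
        if n_max % d == 0 and d in z_by_n and z_by_n[d] >= z_max - margin:
            return d
    return n_max


def scan_periods(seq: DnaSequence, n_range: Tuple[int, int], mode: Mode = "di",
                 cfg: GaConfig = GaConfig(), gaps: GapPenalties = GapPenalties(),
                 replicates: int = 50, seed: int = 0,
                 statistic: Optional[str] = None) -> PeriodScanResult:
    """Run GA + Z for every period in ``n_range`` (inclusive) and pick the
    winner.

    ``statistic`` defaults to 'z' in di mode (mRPWM) and 'v1' in mono mode
    (RPWM); with 'v1' the Monte-Carlo step is skipped entirely.
    """
    n_lo, n_hi = n_range
    if n_lo > n_hi:
        raise ValueError("empty period range")
    if n_lo < 2 or n_hi > 200:
        raise ValueError("period range must lie within [2, 200]")
    if statistic is None:
        statistic = "z" if mode == "di" else "v1"
    if statistic not in ("z", "v1"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    periods = tuple(range(n_lo, n_hi + 1))
    z: Dict[int, float] = {}
    v1: Dict[int, float] = {}
    results: Dict[int, GaResult] = {}
    for n in periods:
        ga_seed = int(rng.integers(2**31))
        mc_seed = int(rng.integers(2**31))
        res = optimize(seq, n, mode, replace(cfg, seed=ga_seed), gaps)
        results[n] = res
        v1[n] = res.v1
        z[n] = (z_score(seq, n, res, replicates, mc_seed, gaps, cfg)
                if statistic == "z" else float("nan"))
    rank = z if statistic == "z" else v1
    n_max = max(periods, key=lambda n: rank[n])
    return PeriodScanResult(periods=periods, z=z, v1=v1, results=results,
                            n_max=n_max, statistic=statistic, replicates=replicates)


def local_maxima(z1: Sequence[float], z0: float, halfwidth: int = 60) -> List[int]:
    """Indices k where z1 exceeds z0 and dominates its neighbourhood.

    k qualifies when z1[k] > z0 and z1[k-i] <= z1[k] >= z1[k+i] for every
    existing neighbour within ``halfwidth``; on a plateau of equal values
    only the leftmost position is kept (left-strict dominance).
    """
    z1 = np.asarray(z1, dtype=float)
    if not np.all(np.isfinite(z1)):
        raise ValueError("z1 must be finite")
    out: List[int] = []
    m = len(z1)
    for k in range(m):
        if not z1[k] > z0:
            continue
        lo = max(0, k - halfwidth)
        hi = min(m, k + halfwidth + 1)
        if np.any(z1[lo:k] >= z1[k]):  # left side strict (tie rule)
            continue
        if np.any(z1[k + 1 : hi] > z1[k]):
            continue
        out.append(k)
    return out


@dataclass(frozen=True)
class CalibrationTable:
    """FDR table over a grid of Z0 candidates: FDR = N_random / N_real."""

    z0: Tuple[float, ...]
    n_real: Tuple[int, ...]
    n_random: Tuple[int, ...]
    fdr: Tuple[Optional[float], ...]  # fractions; None where N_real == 0
    chosen_z0: Optional[float] = None

    def fdr_percent(self) -> Tuple[Optional[float], ...]:
        return tuple(None if f is None else 100.0 * f for f in self.fdr)

    def to_tsv(self) -> str:
        rows = [
            "Z0\t" + "\t".join(f"{z:g}" for z in self.z0),
            "real\t" + "\t".join(str(x) for x in self.n_real),
            "random\t" + "\t".join(str(x) for x in self.n_random),
            "FDR\t" + "\t".join("NA" if f is None else f"{100 * f:.2f}%" for f in self.fdr),
        ]
        return "\n".join(rows) + "\n"


def calibrate_threshold(real_hits_by_z0: Mapping[float, int],
                        random_hits_by_z0: Mapping[float, int],
                        fdr_target: Optional[float] = None) -> CalibrationTable:
    """Build the FDR calibration table and optionally flag the smallest Z0
    whose FDR falls below ``fdr_target`` (a fraction, e.g. 0.03)."""
    if set(real_hits_by_z0) != set(random_hits_by_z0):
        raise ValueError("real and random counts must share the same Z0 grid")
    grid = tuple(sorted(real_hits_by_z0))
    n_real = tuple(int(real_hits_by_z0[z]) for z in grid)
    n_random = tuple(int(random_hits_by_z0[z]) for z in grid)
    if any(x < 0 for x in n_real + n_random):
        raise ValueError("hit counts must be non-negative")
    fdr = tuple(None if r == 0 else v / r for r, v in zip(n_real, n_random))
    chosen = None
    if fdr_target is not None:
        for z, f in zip(grid, fdr):
            if f is not None and f <= fdr_target:
                chosen = z
                break
    return CalibrationTable(z0=grid, n_real=n_real, n_random=n_random, fdr=fdr, chosen_z0=chosen)
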