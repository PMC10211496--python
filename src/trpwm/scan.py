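"""End-to-end tandem-repeat scan and region/annotation statistics.

The pipeline slides a fixed-length window along each sequence with a fine
step, runs the per-window period scan (GA + Monte-Carlo Z for every period),
filters the resulting Z1(k) profile for dominant local maxima above Z0, and
emits one repeat region per surviving maximum, with coordinates taken from
the winning window's alignment.  Adjacent hits reporting the same period
with strong mutual overlap are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree

from trpwm.align import AlignmentResult, GapPenalties
from trpwm.ga import GaConfig
from trpwm.pwm import Mode, PositionWeightMatrix
from trpwm.seqio import DnaSequence, WindowSpec, read_fasta, windows
from trpwm.significance import local_maxima, scan_periods

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """All knobs of the genome scan in one place."""

    n_lo: int = 2
    n_hi: int = 50
    mode: Mode = "di"
    statistic: Optional[str] = None  # None -> 'z' for di, 'v1' for mono
    window: WindowSpec = field(default_factory=WindowSpec)
    z0: float = 6.0
    min_copies: int = 4
    replicates: int = 50
    ga: GaConfig = field(default_factory=GaConfig)
    gaps: GapPenalties = field(default_factory=GapPenalties)
    halfwidth: int = 60
    merge_c: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class TrRegion:
    """One detected tandem-repeat region (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    period: int
    z: float
    copy_count: int
    matrix: PositionWeightMatrix = field(repr=False, compare=False)
    alignment: AlignmentResult = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end before start")

    def __len__(self) -> int:
        return self.end - self.start + 1


def scan_genome(source: Union[str, Path, Sequence[DnaSequence]], config: ScanConfig = ScanConfig()) -> List[TrRegion]:
    """Scan FASTA input (or in-memory sequences) and return repeat regions."""
    seqs = read_fasta(source) if isinstance(source, (str, Path)) else list(source)
    regions: List[TrRegion] = []
    for seq in seqs:
        regions.extend(_scan_sequence(seq, config))
    return regions


def _scan_sequence(seq: DnaSequence, cfg: ScanConfig) -> List[TrRegion]:
    if cfg.n_lo > cfg.n_hi or cfg.window.window_length > len(seq):
        return []
    rng = np.random.default_rng(cfg.seed)
    starts: List[int] = []
    hits = []
    for k, win in windows(seq, cfg.window):
        res = scan_periods(win, (cfg.n_lo, cfg.n_hi), cfg.mode, cfg.ga, cfg.gaps,
                           cfg.replicates, int(rng.integers(2**31)), cfg.statistic)
        starts.append(k)
        hits.append(res)
    if not starts:
        return []
    stat = hits[0].statistic
    z1 = np.array([h.z_max if stat == "z" else h.v1[h.n_max] for h in hits])
    maxima = local_maxima(z1, cfg.z0, cfg.halfwidth)
    regions: List[TrRegion] = []
    for idx in maxima:
        res = hits[idx]
        aln = res.best.alignment
        if aln.is_empty or aln.copy_count < cfg.min_copies:
            continue
        offset = starts[idx] - 1
        regions.append(TrRegion(
            seq_id=seq.id,
            start=offset + aln.start,
            end=offset + aln.end,
            period=res.n_max,
            z=float(z1[idx]),
            copy_count=aln.copy_count,
            matrix=res.best.best_matrix,
            alignment=aln,
        ))
    return _merge_regions(regions, cfg.merge_c)


def _merge_regions(regions: List[TrRegion], merge_c: float) -> List[TrRegion]:
    """Merge same-period hits from adjacent windows that overlap with
    intersection C > ``merge_c`` (union of coordinates, best Z kept)."""
    out: List[TrRegion] = []
    for reg in sorted(regions, key=lambda r: (r.seq_id, r.start, r.end)):
        if out:
            prev = out[-1]
            if (prev.seq_id == reg.seq_id and prev.period == reg.period
                    and intersection_C(prev, reg) > merge_c):
                keep = prev if prev.z >= reg.z else reg
                out[-1] = replace(keep, start=min(prev.start, reg.start),
                                  end=max(prev.end, reg.end))
                continue
        out.append(reg)
    return out


def intersection_C(a: TrRegion, b: TrRegion) -> float:
    """Intersection measure C = overlap length / length of the smaller
    region; C is in [0, 1], symmetric, and 1 when one region contains the
    other."""
    if a.seq_id != b.seq_id:
        raise ValueError(f"regions on different sequences: {a.seq_id!r} vs {b.seq_id!r}")
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap <= 0:
        return 0.0
    return overlap / min(len(a), len(b))


@dataclass(frozen=True)
class Feature:
    """An annotation interval (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    kind: str = "feature"


def read_bed(path: str | Path, kind: Optional[str] = None) -> List[Feature]:
    """BED intervals (0-based half-open on disk -> 1-based inclusive here).
    Malformed lines are skipped with a warning."""
    out: List[Feature] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        try:
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError):
            logger.warning("%s:%d malformed BED line skipped", path, ln)
            continue
        name = kind or (parts[3] if len(parts) > 3 else "bed")
        out.append(Feature(chrom, s + 1, e, name))
    return out


def read_gff3(path: str | Path, feature_types: Optional[Iterable[str]] = None) -> List[Feature]:
    """GFF3 intervals (already 1-based inclusive).  ``feature_types``
    restricts to given type column values (e.g. {'gene'})."""
    wanted = set(feature_types) if feature_types else None
    out: List[Feature] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            logger.warning("%s:%d malformed GFF3 line skipped", path, ln)
            continue
        try:
            s, e = int(parts[3]), int(parts[4])
        except ValueError:
            logger.warning("%s:%d malformed GFF3 line skipped", path, ln)
            continue
        if wanted and parts[2] not in wanted:
            continue
        out.append(Feature(parts[0], s, e, parts[2]))
    return out


@dataclass(frozen=True)
class OverlapReport:
    """Per annotation class: feature/TR overlap counts at the >= 50% rule."""

    n_features: Dict[str, int]
    n_features_with_tr: Dict[str, int]
    n_trs_overlapping: Dict[str, int]
    period_histogram: Dict[str, Dict[int, int]]


def annotate_overlap(regions: Sequence[TrRegion], features: Sequence[Feature],
                     min_fraction: float = 0.5) -> OverlapReport:
    """Count TR/feature overlaps.

    A TR counts as overlapping a feature when the overlap covers at least
    ``min_fraction`` of the TR's own length.  Both directions are reported:
    TRs overlapping each class, and features of each class containing at
    least one TR (a feature with several TRs counts once).
    """
    trees: Dict[str, IntervalTree] = {}
    n_features: Dict[str, int] = {}
    for fi, f in enumerate(features):
        n_features[f.kind] = n_features.get(f.kind, 0) + 1
        trees.setdefault(f.seq_id, IntervalTree()).addi(f.start, f.end + 1, (fi, f))
    n_trs: Dict[str, int] = {k: 0 for k in n_features}
    hist: Dict[str, Dict[int, int]] = {k: {} for k in n_features}
    features_hit: Dict[str, set] = {k: set() for k in n_features}
    for reg in regions:
        tree = trees.get(reg.seq_id)
        if tree is None:
            continue
        counted_kinds = set()
        for iv in tree.overlap(reg.start, reg.end + 1):
            fi, f = iv.data
            overlap = min(reg.end, f.end) - max(reg.start, f.start) + 1
            if overlap < min_fraction * len(reg):
                continue
            features_hit[f.kind].add(fi)
            if f.kind not in counted_kinds:
                counted_kinds.add(f.kind)
                n_trs[f.kind] += 1
                hist[f.kind][reg.period] = hist[f.kind].get(reg.period, 0) + 1
    return OverlapReport(
        n_features=n_features,
        n_features_with_tr={k: len(v) for k, v in features_hit.items()},
        n_trs_overlapping=n_trs,
        period_histogram=hist,
    )


def regions_to_tsv(regions: Sequence[TrRegion]) -> str:
    lines = ["seq_id\tstart\tend\tperiod\tZ\tcopies"]
    for r in regions:
        lines.append(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.period}\t{r.z:.3f}\t{r.copy_count}")
    return "\n".join(lines) + "\n"


def regions_to_bed(regions: Sequence[TrRegion]) -> str:
    return "".join(
        f"{r.seq_id}\t{r.start - 1}\t{r.end}\tTR_n{r.period}\t{r.z:.2f}\n" for r in regions
    )
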