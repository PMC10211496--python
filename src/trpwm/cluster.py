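"""Cyclic-shift distance between period matrices and class significance.

A repeat region can start at any phase of its unit, so two matrices
describing the same repeat family may differ by a cyclic rotation of their
rows.  The distance between matrices m1 and m2 of period n is therefore the
minimum over the n row rotations t of the Euclidean distance

    Dist^n(m1, m2) = min_t sqrt( sum_ij (m1(i,j) - m2((i+t-1 mod n)+1, j))^2 )

Matrices are clustered by complete linkage on this distance; class
significance is assessed against a null in which the cells of every matrix
are randomly permuted (destroying row structure but keeping the value
multiset) and the clustering repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from trpwm.pwm import PositionWeightMatrix


def cyclic_distance(m1: PositionWeightMatrix, m2: PositionWeightMatrix,
                    squared_differences: bool = True) -> float:
    """Minimum distance between ``m1`` and ``m2`` over all cyclic row shifts.

    With ``squared_differences`` (default) this is a true Euclidean
    distance; the alternative sums signed differences, which can cancel and
    is kept only for comparison.
    """
    if m1.w.shape != m2.w.shape:
        raise ValueError("matrices must share (n, K)")
    n = m1.n
    best = np.inf
    rows = np.arange(n)
    for t in range(n):
        shifted = m2.w[(rows + t) % n]
        if squared_differences:
            d = float(np.sqrt(((m1.w - shifted) ** 2).sum()))
        else:
            d = float((m1.w - shifted).sum())
        if d < best:
            best = d
    return best


def distance_matrix(matrices: Sequence[PositionWeightMatrix],
                    squared_differences: bool = True) -> np.ndarray:
    m = len(matrices)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = cyclic_distance(matrices[i], matrices[j], squared_differences)
    return D


@dataclass(frozen=True)
class ClusterClasses:
    """Complete-linkage classes at cut level ``dist0``.

    ``labels`` assigns each input matrix a class id (1-based);
    ``classes`` maps class id -> member indices; ``linkage_matrix`` is the
    scipy dendrogram encoding.
    """

    dist0: float
    labels: Tuple[int, ...]
    classes: Dict[int, Tuple[int, ...]]
    linkage_matrix: np.ndarray = field(repr=False, compare=False)

    @property
    def sizes(self) -> Dict[int, int]:
        return {cid: len(members) for cid, members in self.classes.items()}

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def cluster_matrices(matrices: Sequence[PositionWeightMatrix], dist0: float,
                     squared_differences: bool = True) -> ClusterClasses:
    """Agglomerative complete-linkage clustering cut at ``dist0``."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to cluster")
    D = distance_matrix(matrices, squared_differences)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = fcluster(Z, t=dist0, criterion="distance")
    classes: Dict[int, List[int]] = {}
    for i, lab in enumerate(labels):
        classes.setdefault(int(lab), []).append(i)
    return ClusterClasses(
        dist0=dist0,
        labels=tuple(int(x) for x in labels),
        classes={k: tuple(v) for k, v in sorted(classes.items())},
        linkage_matrix=Z,
    )


@dataclass(frozen=True)
class NullClassStats:
    """Shuffle-null statistics for a clustering at a fixed cut level.

    Two statistics are tracked because both are informative: the sizes of
    the classes and the number of classes at the cut.  ``per_class_z``
    standardises each observed class size against the null class-size
    distribution; ``count_z`` does the same for the class count.
    """

    mean_size: float
    var_size: float
    mean_count: float
    var_count: float
    per_class_z: Dict[int, float]
    count_z: float


def null_class_stats(matrices: Sequence[PositionWeightMatrix], dist0: float,
                     n_shuffles: int = 100, seed: int = 0,
                     squared_differences: bool = True) -> NullClassStats:
    """Cell-shuffle null for class significance.

    Every shuffle replicate permutes the cells within each matrix, then
    reclusters at ``dist0``; class sizes and class counts are pooled over
    replicates and each observed class gets z = (N - mean) / sd.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    observed = cluster_matrices(matrices, dist0, squared_differences)
    rng = np.random.default_rng(seed)
    null_sizes: List[int] = []
    null_counts: List[int] = []
    n, K = matrices[0].n, matrices[0].K
    mode = matrices[0].mode
    for _ in range(n_shuffles):
        shuffled = [
            PositionWeightMatrix(w=rng.permutation(m.w.ravel()).reshape(n, K), mode=mode)
            for m in matrices
        ]
        cc = cluster_matrices(shuffled, dist0, squared_differences)
        null_sizes.extend(cc.sizes.values())
        null_counts.append(cc.n_classes)
    mean_size = float(np.mean(null_sizes))
    var_size = float(np.var(null_sizes, ddof=1)) if len(null_sizes) > 1 else 0.0
    mean_count = float(np.mean(null_counts))
    var_count = float(np.var(null_counts, ddof=1))
    if var_size == 0.0 or var_count == 0.0:
        raise ValueError("degenerate null: zero variance across shuffles")
    per_class_z = {
        cid: (size - mean_size) / np.sqrt(var_size) for cid, size in observed.sizes.items()
    }
    count_z = (observed.n_classes - mean_count) / np.sqrt(var_count)
    return NullClassStats(mean_size=mean_size, var_size=var_size, mean_count=mean_count,
                          var_count=var_count, per_class_z=per_class_z, count_z=count_z)
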