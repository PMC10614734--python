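"""Cell-type relatedness weighting, clustering, and pre-analysis filters.

The relatedness of two cell types i and j is summarized by

    weight_ij = 1 - (O / P_i) * (O / P_j)

where ``O`` is the number of intersecting peak pairs between the two
merged peak sets and ``P_i``, ``P_j`` the peak counts.  Identical sets get
weight 0, fully disjoint sets weight 1, so the matrix behaves as a
dissimilarity.  Rows of the weight matrix are then clustered
agglomeratively under the Euclidean metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .intervals import IntervalSet, LocusSet

logger = logging.getLogger(__name__)


def count_pairwise_overlap(a: IntervalSet, b: IntervalSet) -> int:
    """Number of (peak in a, peak in b) pairs sharing >= 1 bp.

    Both sets are merged, so the count is symmetric in its arguments.
    """
    total = 0
    for chrom in a.chroms:
        a_starts, a_ends = a.arrays(chrom)
        b_starts, b_ends = b.arrays(chrom)
        if len(b_starts) == 0:
            continue
        # b peaks intersecting [s, e): b_start < e and b_end > s
        lo = np.searchsorted(b_ends, a_starts, side="right")
        hi = np.searchsorted(b_starts, a_ends, side="left")
        total += int(np.maximum(hi - lo, 0).sum())
    return total


def overlaps_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean flag per peak of ``a``: intersects >= 1 peak of ``b``.

    Flags follow the order of ``a.intervals``.
    """
    flags = []
    for chrom in a.chroms:
        a_starts, a_ends = a.arrays(chrom)
        b_starts, b_ends = b.arrays(chrom)
        if len(b_starts) == 0:
            flags.append(np.zeros(len(a_starts), dtype=bool))
            continue
        lo = np.searchsorted(b_ends, a_starts, side="right")
        hi = np.searchsorted(b_starts, a_ends, side="left")
        flags.append(hi > lo)
    if not flags:
        return np.empty(0, dtype=bool)
    return np.concatenate(flags)


def compute_weight(a: IntervalSet, b: IntervalSet) -> float:
    """Dissimilarity weight between two merged peak sets; in [0, 1]."""
    if a.peak_count == 0 or b.peak_count == 0:
        raise ValueError("cannot weight an empty peak set")
    o = count_pairwise_overlap(a, b)
    w = 1.0 - (o / a.peak_count) * (o / b.peak_count)
    if w < 0.0 or w > 1.0:
        logger.warning(
            "weight for (%s, %s) clamped from %.6g into [0, 1] "
            "(pair count %d exceeds a peak count)", a.name, b.name, w, o,
        )
        w = min(1.0, max(0.0, w))
    return w


@dataclass
class WeightMatrix:
    """Symmetric cell-type dissimilarity matrix with zero diagonal."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weight matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("weight matrix must be symmetric")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def compute_weight_matrix(sets: Sequence[IntervalSet]) -> WeightMatrix:
    """Full pairwise weight matrix over >= 2 peak sets; diagonal forced 0."""
    if len(sets) < 2:
        raise ValueError("need at least two peak sets for a weight matrix")
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w = compute_weight(sets[i], sets[j])
            values[i, j] = values[j, i] = w
    return WeightMatrix([s.name for s in sets], values)


@dataclass
class LinkageTree:
    """Agglomerative merge order over cell types.

    ``merges`` is a SciPy linkage matrix: each row joins two clusters at a
    given height; leaves are indexed in ``labels`` order.
    """

    labels: List[str]
    merges: np.ndarray

    def to_newick(self) -> str:
        """Newick text encoding topology and merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(idx: int) -> str:
            if idx < n:
                return self.labels[idx]
            a, b, h, _ = self.merges[idx - n]
            a, b = int(a), int(b)
            return (
                f"({node(a)}:{h - heights[a]:.10g},"
                f"{node(b)}:{h - heights[b]:.10g})"
            )

        for row_i, (a, b, h, _) in enumerate(self.merges):
            heights[len(self.labels) + row_i] = float(h)
        root = n + len(self.merges) - 1 if len(self.merges) else 0
        return node(root) + ";"


def cluster_cell_types(w: WeightMatrix, method: str = "average") -> LinkageTree:
    """Cluster cell types by Euclidean distance between weight-matrix rows.

    Deterministic given input order (SciPy breaks ties by lowest index).
    """
    if not np.all(np.isfinite(w.values)):
        raise ValueError("weight matrix contains non-finite entries")
    dists = pdist(w.values, metric="euclidean")
    merges = hierarchy.linkage(dists, method=method)
    return LinkageTree(list(w.labels), merges)


def uniqueness_filter(
    sets: Sequence[IntervalSet], cutoff: int
) -> List[IntervalSet]:
    """Retain only peaks found in at most ``cutoff`` cell types.

    A peak's occupancy is the number of distinct cell types (including its
    own) whose peak sets intersect it by >= 1 bp.  With cutoff 3, a peak
    shared by four or more cell types is removed from every set.
    """
    if cutoff < 1:
        raise ValueError("uniqueness cutoff must be >= 1")
    out = []
    for i, iset in enumerate(sets):
        occupancy = np.ones(iset.peak_count, dtype=np.int64)
        for j, other in enumerate(sets):
            if i == j:
                continue
            occupancy += overlaps_any(iset, other).astype(np.int64)
        kept = [
            (iv.chrom, iv.start, iv.end)
            for iv, occ in zip(iset.intervals, occupancy)
            if occ <= cutoff
        ]
        removed = iset.peak_count - len(kept)
        if removed:
            logger.info(
                "%s: uniqueness filter (cutoff %d) removed %d of %d peak(s)",
                iset.name, cutoff, removed, iset.peak_count,
            )
        out.append(IntervalSet(iset.name, kept))
    return out


def filter_loci_sets(
    sets: Sequence[LocusSet], min_count: int
) -> List[LocusSet]:
    """Retain locus sets with at least ``min_count`` loci (inclusive)."""
    kept = []
    for s in sets:
        if len(s) >= min_count:
            kept.append(s)
        else:
            logger.info(
                "dropping locus set %s (%d < %d loci)", s.name, len(s), min_count
            )
    if not kept:
        logger.warning("no locus sets survive the minimum-size cutoff %d", min_count)
    return kept
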