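"""The enrichment statistic: windowing, per-window binomial terms, and the
genome-wide tail probability.

The genome is tiled with near-equal windows close to a target size.  For
one (cell type, locus set) pair, each window holding at least one locus
contributes a Binomial(n, p) term: n = loci in the window, p = fraction
of the window covered by the cell type's open chromatin (adjusted for
multi-bp loci, see :func:`window_stats`).  Under the null of no
enrichment the genome-wide overlap count S is the sum of these
independent binomials, and the reported p-value is P(S >= k_observed)
from :mod:`rlea.sinib`.  Across n cell types and m locus sets this yields
an n x m matrix of p-values with a single multiple-testing correction.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import io as rio
from .intervals import ChromSizes, IntervalSet, LocusSet, merge_intervals
from .sinib import SumOfBinomials, log10_tail, tail

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 1_000_000


@dataclass(frozen=True)
class Window:
    """One tile of the genome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def make_windows(sizes: ChromSizes, target_size: int) -> List[Window]:
    """Tile every chromosome with windows of near-equal length.

    Per chromosome of length L the window count is W = max(1,
    round(L / target_size)); lengths are ceil(L/W) or floor(L/W), longer
    windows first, so the tiling is exact and deterministic.
    """
    if target_size < 1:
        raise ValueError("window target size must be >= 1")
    windows: List[Window] = []
    for chrom, length in sorted(sizes.items()):
        n_win = max(1, int(length / target_size + 0.5))
        base, extra = divmod(length, n_win)
        pos = 0
        for i in range(n_win):
            width = base + (1 if i < extra else 0)
            windows.append(Window(chrom, pos, pos + width))
            pos += width
        assert pos == length
    return windows


@dataclass(frozen=True)
class WindowStats:
    """Per-window quantities feeding one binomial term."""

    window: Window
    n_loci: int
    coverage: float
    k_overlap: int


def _clipped_coverage_bp(
    starts: np.ndarray, ends: np.ndarray, w_start: int, w_end: int
) -> int:
    """Total bp of (merged) intervals intersecting [w_start, w_end)."""
    if len(starts) == 0:
        return 0
    clipped = np.minimum(ends, w_end) - np.maximum(starts, w_start)
    return int(np.clip(clipped, 0, None).sum())


def _loci_overlap_flags(
    ocr: IntervalSet, chrom: str, pos: np.ndarray, length: np.ndarray
) -> np.ndarray:
    """Per locus: does the span [pos, pos+length) touch any OCR peak?"""
    o_starts, o_ends = ocr.arrays(chrom)
    if len(o_starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    lo = np.searchsorted(o_ends, pos, side="right")
    hi = np.searchsorted(o_starts, pos + length, side="left")
    return hi > lo


def window_stats(window: Window, ocr: IntervalSet, loci: LocusSet) -> WindowStats:
    """Locus count, OCR coverage fraction and overlap count for one window.

    Loci are assigned to the window whose half-open span contains their
    start position; overlap of an assigned locus is judged by its full
    span against the unextended peaks.  When multi-bp loci assigned to
    the window overlap open chromatin, every peak segment intersecting
    the window is virtually extended by (Lmax - 1) bp on each side
    (Lmax = largest such locus length) before the coverage fraction is
    computed: a locus of length L whose start falls within a peak grown
    by L - 1 bp intersects the original peak, so the window's success
    probability must use the grown footprint.
    """
    pos_all, len_all = loci.arrays(window.chrom)
    i0 = np.searchsorted(pos_all, window.start, side="left")
    i1 = np.searchsorted(pos_all, window.end, side="left")
    pos, length = pos_all[i0:i1], len_all[i0:i1]
    n_loci = len(pos)
    overlap = _loci_overlap_flags(ocr, window.chrom, pos, length)
    k_overlap = int(overlap.sum())

    o_starts, o_ends = ocr.arrays(window.chrom)
    window_len = len(window)
    multi = (length > 1) & overlap
    if np.any(multi):
        l_max = int(length[multi].max())
        grow = l_max - 1
        # peaks intersecting the window, grown symmetrically, re-unioned
        lo = np.searchsorted(o_ends, window.start, side="right")
        hi = np.searchsorted(o_starts, window.end, side="left")
        spans = [
            (window.chrom, max(0, int(s) - grow), int(e) + grow)
            for s, e in zip(o_starts[lo:hi], o_ends[lo:hi])
        ]
        merged = merge_intervals(spans)
        g_starts = np.array([s for _, s, _ in merged], dtype=np.int64)
        g_ends = np.array([e for _, _, e in merged], dtype=np.int64)
        cov_bp = _clipped_coverage_bp(g_starts, g_ends, window.start, window.end)
    else:
        cov_bp = _clipped_coverage_bp(o_starts, o_ends, window.start, window.end)
    coverage = min(1.0, cov_bp / window_len)
    return WindowStats(window, n_loci, coverage, k_overlap)


def count_genomewide_overlap(ocr: IntervalSet, loci: LocusSet) -> int:
    """Number of loci whose span [pos, pos+length) touches any peak."""
    total = 0
    for chrom in loci.chroms:
        pos, length = loci.arrays(chrom)
        total += int(_loci_overlap_flags(ocr, chrom, pos, length).sum())
    return total


@dataclass
class EnrichmentResult:
    """Enrichment of one locus set in one cell type's open chromatin."""

    cell_type: str
    locus_set: str
    k_observed: int
    n_total: int
    p_raw: float
    neg_log10_p: float
    p_adjusted: Optional[float] = None
    survives_correction: Optional[bool] = None


def enrichment_pvalue(
    ocr: IntervalSet,
    loci: LocusSet,
    windows: Sequence[Window],
    method: str = "auto",
) -> EnrichmentResult:
    """Genome-wide enrichment p-value for one (cell type, locus set) pair."""
    terms: List[Tuple[int, float]] = []
    n_total = 0
    for window in windows:
        stats = window_stats(window, ocr, loci)
        if stats.n_loci >= 1:
            terms.append((stats.n_loci, stats.coverage))
            n_total += stats.n_loci
    if n_total == 0:
        raise ValueError(
            f"no usable loci: {loci.name!r} has no locus inside any window"
        )
    model = SumOfBinomials(terms)
    k_observed = count_genomewide_overlap(ocr, loci)
    p_raw = tail(model, k_observed, method=method)
    neg_log10 = -log10_tail(model, k_observed, method=method)
    return EnrichmentResult(
        cell_type=ocr.name,
        locus_set=loci.name,
        k_observed=k_observed,
        n_total=n_total,
        p_raw=p_raw,
        neg_log10_p=neg_log10,
    )


class EnrichmentMatrix:
    """The fitted n x m grid of enrichment results.

    Rows are cell types, columns locus sets.  Exposes the raw and
    adjusted p-values as labeled DataFrames, a text ``summary()``, CSV
    export and a heatmap hook.
    """

    def __init__(self, cells: List[List[EnrichmentResult]]):
        if not cells or not cells[0]:
            raise ValueError("empty enrichment matrix")
        self.cells = cells
        self.rows = [row[0].cell_type for row in cells]
        self.cols = [c.locus_set for c in cells[0]]
        self.correction: Optional[str] = None
        self.alpha: Optional[float] = None

    # -- frame views -----------------------------------------------------

    def _frame(self, attr: str) -> pd.DataFrame:
        data = [[getattr(c, attr) for c in row] for row in self.cells]
        return pd.DataFrame(data, index=self.rows, columns=self.cols)

    @property
    def p_raw(self) -> pd.DataFrame:
        return self._frame("p_raw")

    @property
    def p_adjusted(self) -> pd.DataFrame:
        return self._frame("p_adjusted")

    @property
    def neg_log10(self) -> pd.DataFrame:
        return self._frame("neg_log10_p")

    @property
    def k_observed(self) -> pd.DataFrame:
        return self._frame("k_observed")

    @property
    def survives(self) -> pd.DataFrame:
        return self._frame("survives_correction")

    @property
    def shape(self) -> Tuple[int, int]:
        return len(self.rows), len(self.cols)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for row in self.cells:
            for c in row:
                rows.append(
                    {
                        "cell_type": c.cell_type,
                        "locus_set": c.locus_set,
                        "k_observed": c.k_observed,
                        "n_total": c.n_total,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                        "neg_log10_p": c.neg_log10_p,
                        "survives_correction": c.survives_correction,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_long_frame()
        lines = [
            "Regulatory landscape enrichment",
            f"  cell types: {len(self.rows)}   locus sets: {len(self.cols)}",
            f"  correction: {self.correction or 'none'}   alpha: {self.alpha}",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)

    def to_csv(self, out_dir: str) -> List[str]:
        """Write the matrix CSVs; returns the file paths written."""
        os.makedirs(out_dir, exist_ok=True)
        written = []
        for name, frame in (
            ("enrichment_pvalues.csv", self.p_raw),
            ("enrichment_padj.csv", self.p_adjusted),
            ("enrichment_neglog10.csv", self.neg_log10),
            ("enrichment_survives.csv", self.survives),
        ):
            path = os.path.join(out_dir, name)
            rio.write_matrix_csv(frame, path)
            written.append(path)
        path = os.path.join(out_dir, "enrichment_results.csv")
        self.to_long_frame().to_csv(path, index=False, float_format="%.12g")
        written.append(path)
        return written

    def plot_heatmap(self, path: str, alpha: Optional[float] = None):
        from .viz import render_heatmap

        return render_heatmap(self, alpha=alpha or self.alpha or 0.05, path=path)


def adjust_pvalues(
    matrix: EnrichmentMatrix,
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> EnrichmentMatrix:
    """Correct the flattened n*m raw p-values for multiple testing.

    ``bonferroni``: p_adj = min(1, n*m*p).  ``bh``: Benjamini-Hochberg
    step-up.  Cells with p_adj < alpha are flagged as surviving
    correction.
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction method {method!r}")
    flat = [c for row in matrix.cells for c in row]
    p = np.array([c.p_raw for c in flat])
    if method == "bonferroni":
        adj = np.minimum(1.0, p * len(p))
    else:
        adj = multipletests(p, method="fdr_bh")[1]
    for c, a in zip(flat, adj):
        c.p_adjusted = float(a)
        c.survives_correction = bool(a < alpha)
    matrix.correction = method
    matrix.alpha = alpha
    return matrix


def enrichment_matrix(
    ocr_sets: Sequence[IntervalSet],
    locus_sets: Sequence[LocusSet],
    sizes: ChromSizes,
    target_size: int = DEFAULT_WINDOW_SIZE,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    method: str = "auto",
) -> EnrichmentMatrix:
    """All n x m enrichment p-values over one shared genome tiling."""
    if not ocr_sets or not locus_sets:
        raise ValueError("need at least one OCR set and one locus set")
    windows = make_windows(sizes, target_size)
    cells = [
        [enrichment_pvalue(ocr, loci, windows, method=method) for loci in locus_sets]
        for ocr in ocr_sets
    ]
    matrix = EnrichmentMatrix(cells)
    return adjust_pvalues(matrix, method=correction, alpha=alpha)


class RegulatoryEnrichment:
    """Model: locus-set enrichment across cell-type open-chromatin sets.

    Parameters
    ----------
    ocr_sets : sequence of IntervalSet
        One merged peak set per cell type.
    locus_sets : sequence of LocusSet
        One locus collection per trait / study.
    chrom_sizes : ChromSizes
        Genome build sizes; peaks and loci outside it are dropped.
    window_size : int
        Target tiling size in bp (default 1 Mb).

    ``fit()`` returns an :class:`EnrichmentMatrix`.
    """

    def __init__(
        self,
        ocr_sets: Sequence[IntervalSet],
        locus_sets: Sequence[LocusSet],
        chrom_sizes: ChromSizes,
        window_size: int = DEFAULT_WINDOW_SIZE,
    ):
        if not ocr_sets:
            raise ValueError("no OCR sets provided")
        if not locus_sets:
            raise ValueError("no locus sets provided")
        self.chrom_sizes = chrom_sizes
        self.ocr_sets = [s.restrict_to(chrom_sizes) for s in ocr_sets]
        self.locus_sets = [s.restrict_to(chrom_sizes) for s in locus_sets]
        self.window_size = window_size
        self.windows = make_windows(chrom_sizes, window_size)

    @classmethod
    def from_folders(
        cls,
        ocr_dir: str,
        loci_dir: str,
        chrom_sizes_path: str,
        window_size: int = DEFAULT_WINDOW_SIZE,
        chrom_col: str = rio.DEFAULT_CHROM_COL,
        pos_col: str = rio.DEFAULT_POS_COL,
        length_col: Optional[str] = None,
    ) -> "RegulatoryEnrichment":
        """Build the model from the four on-disk inputs.

        OCR files are ``*.txt`` in ``ocr_dir``; locus tables are
        ``*.tsv``/``*.csv`` in ``loci_dir``; file stems become set names.
        """
        ocr_files = sorted(
            f for f in os.listdir(ocr_dir) if f.lower().endswith(".txt")
        )
        loci_files = sorted(
            f
            for f in os.listdir(loci_dir)
            if f.lower().endswith((".tsv", ".csv"))
        )
        if not ocr_files:
            raise ValueError(f"no .txt OCR files found in {ocr_dir}")
        if not loci_files:
            raise ValueError(f"no .tsv/.csv locus files found in {loci_dir}")
        ocr_sets = [rio.read_ocr_bed(os.path.join(ocr_dir, f)) for f in ocr_files]
        locus_sets = [
            rio.read_loci_table(
                os.path.join(loci_dir, f),
                chrom_col=chrom_col,
                pos_col=pos_col,
                length_col=length_col,
            )
            for f in loci_files
        ]
        sizes = rio.read_chrom_sizes(chrom_sizes_path)
        return cls(ocr_sets, locus_sets, sizes, window_size=window_size)

    def fit(
        self,
        correction: str = "bonferroni",
        alpha: float = 0.05,
        method: str = "auto",
    ) -> EnrichmentMatrix:
        """Compute the n x m enrichment matrix with adjusted p-values."""
        cells = [
            [
                enrichment_pvalue(ocr, loci, self.windows, method=method)
                for loci in self.locus_sets
            ]
            for ocr in self.ocr_sets
        ]
        matrix = EnrichmentMatrix(cells)
        return adjust_pvalues(matrix, method=correction, alpha=alpha)
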