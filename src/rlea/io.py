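"""Readers and writers for the external file formats.

* OCR peak files: BED-style whitespace-delimited text, ``chrom start end``
  (extra columns ignored), 0-based half-open coordinates.
* Locus tables: ``.tsv`` / ``.csv`` with a header row; positions are
  1-based on disk and converted to 0-based on read.
* Chromosome sizes: two-column ``.csv`` of name and length.
* Output matrices: labeled CSV with >= 10 significant digits.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import pandas as pd

from .intervals import ChromSizes, IntervalSet, Locus, LocusSet, normalize_chrom_name

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")

#: Default GWAS-catalog-style column names for locus tables.
DEFAULT_CHROM_COL = "CHR_ID"
DEFAULT_POS_COL = "CHR_POS"


def read_ocr_bed(path: str, name: Optional[str] = None) -> IntervalSet:
    """Read one cell type's open-chromatin peaks from a BED-style file.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Malformed coordinates raise with the file name and line number.
    Overlapping or abutting spans are merged in the returned set.
    """
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    spans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            chrom = normalize_chrom_name(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            if not (0 <= start < end):
                raise ValueError(
                    f"{path}:{lineno}: invalid span {start}-{end} "
                    "(need 0 <= start < end)"
                )
            spans.append((chrom, start, end))
    if not spans:
        raise ValueError(f"{path}: no intervals")
    return IntervalSet(name, spans)


def read_loci_table(
    path: str,
    name: Optional[str] = None,
    chrom_col: str = DEFAULT_CHROM_COL,
    pos_col: str = DEFAULT_POS_COL,
    length_col: Optional[str] = None,
) -> LocusSet:
    """Read a trait/study locus table (.tsv or .csv, header required).

    Positions are 1-based in the file.  Rows whose position does not parse
    as a positive integer are dropped (count logged); exact duplicates are
    deduplicated by the :class:`~rlea.intervals.LocusSet` constructor.
    """
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    sep = "\t" if path.lower().endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (chrom_col, pos_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing required column {col!r}; available: "
                f"{list(df.columns)}"
            )
    loci = []
    dropped = 0
    for _, row in df.iterrows():
        raw_chrom = row[chrom_col]
        raw_pos = row[pos_col]
        try:
            pos1 = int(str(raw_pos).strip())
            if pos1 < 1:
                raise ValueError
            chrom = normalize_chrom_name(str(raw_chrom))
        except (ValueError, TypeError):
            dropped += 1
            continue
        length = 1
        if length_col is not None and length_col in df.columns:
            try:
                parsed = int(float(str(row[length_col]).strip()))
                if parsed >= 1:
                    length = parsed
            except (ValueError, TypeError):
                pass
        loci.append(Locus(chrom, pos1 - 1, length))
    if dropped:
        logger.info("%s: dropped %d unparseable row(s)", path, dropped)
    if not loci:
        raise ValueError(f"{path}: zero parseable loci")
    out = LocusSet(name, loci)
    out.n_rows_dropped = dropped
    return out


def read_chrom_sizes(path: str) -> ChromSizes:
    """Read a two-column chromosome-sizes .csv (name, length)."""
    df = pd.read_csv(path, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (name, length)")
    # Tolerate a header row such as "chromosome,size".
    first = str(df.iloc[0, 1]).strip()
    try:
        int(first)
    except ValueError:
        df = df.iloc[1:]
    sizes = {}
    for _, row in df.iterrows():
        raw_name = str(row.iloc[0]).strip()
        try:
            length = int(str(row.iloc[1]).strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-integer length {row.iloc[1]!r} for {raw_name!r}"
            ) from exc
        canon = normalize_chrom_name(raw_name)
        if canon in sizes:
            raise ValueError(f"{path}: duplicate chromosome {canon!r}")
        if length <= 0:
            raise ValueError(
                f"{path}: non-positive length {length} for {raw_name!r}"
            )
        sizes[canon] = length
    if not sizes:
        raise ValueError(f"{path}: no chromosomes")
    return ChromSizes(sizes)


def write_bed(iset: IntervalSet, path: str) -> None:
    """Write a merged interval set back out as 3-column BED text."""
    with open(path, "w") as fh:
        for iv in iset.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_matrix_csv(df: pd.DataFrame, path: str) -> None:
    """Write a labeled matrix with >= 10 significant digits."""
    if df.size == 0:
        raise ValueError("refusing to write an empty matrix")
    df.to_csv(path, float_format="%.12g")


def read_matrix_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
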