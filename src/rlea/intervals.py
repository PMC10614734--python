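"""Genomic interval and locus containers.

Coordinates are 0-based, half-open throughout (BED convention).  Locus
tables use 1-based positions on disk (GWAS-catalog convention) and are
converted on read; see :mod:`rlea.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

# Canonical chromosome aliases.  Keys are the token left after stripping an
# optional leading "chr" and lowercasing; values are the canonical suffix.
_CHROM_ALIASES = {
    "x": "X",
    "y": "Y",
    "m": "M",
    "mt": "M",
    "23": "X",  # PLINK-style numeric sex/mito codes
    "24": "Y",
    "25": "M",
    "26": "M",
}


def normalize_chrom_name(raw: str) -> str:
    """Map a chromosome label to one canonical convention.

    ``"1"`` and ``"chr1"`` both become ``"chr1"``; ``"X"``/``"chrX"`` become
    ``"chrX"``; ``"MT"``/``"M"`` become ``"chrM"``; numeric codes 23/24/25
    map to X/Y/M.  Unrecognized names are returned lowercased with a
    ``"chr"`` prefix so that at least identical spellings collapse.
    """
    token = raw.strip()
    if not token:
        raise ValueError("empty chromosome name")
    body = token[3:] if token.lower().startswith("chr") else token
    body = body.strip()
    key = body.lower()
    if key in _CHROM_ALIASES:
        return "chr" + _CHROM_ALIASES[key]
    if key.isdigit():
        return "chr" + str(int(key))
    return "chr" + key


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(
    intervals: Iterable[Tuple[str, int, int]],
) -> List[Tuple[str, int, int]]:
    """Sort and merge spans; overlapping or abutting spans are unioned."""
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        per_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out: List[Tuple[str, int, int]] = []
    for chrom in sorted(per_chrom):
        spans = sorted(per_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # overlap or abut -> union
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


class IntervalSet:
    """A named, merged, sorted collection of genomic intervals (an OCR set).

    Intervals are merged on construction: overlapping or abutting input
    spans on the same chromosome are unioned, so the stored peaks are
    pairwise disjoint and sorted by ``(chrom, start)``.
    """

    def __init__(self, name: str, intervals: Iterable[Tuple[str, int, int]]):
        self.name = name
        merged = merge_intervals(
            (c, s, e) for c, s, e in intervals
        )
        for c, s, e in merged:
            if not (0 <= s < e):
                raise ValueError(f"invalid interval {c}:{s}-{e} in set {name!r}")
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        chroms = sorted({c for c, _, _ in merged})
        for chrom in chroms:
            spans = [(s, e) for c, s, e in merged if c == chrom]
            starts = np.array([s for s, _ in spans], dtype=np.int64)
            ends = np.array([e for _, e in spans], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends)

    @property
    def chroms(self) -> List[str]:
        return list(self._by_chrom)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (empty if absent)."""
        if chrom in self._by_chrom:
            return self._by_chrom[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    @property
    def intervals(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, (starts, ends) in self._by_chrom.items()
            for s, e in zip(starts, ends)
        ]

    @property
    def peak_count(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())

    @property
    def total_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._by_chrom.values())
        )

    def __len__(self) -> int:
        return self.peak_count

    def restrict_to(self, sizes: "ChromSizes") -> "IntervalSet":
        """Drop intervals on chromosomes absent from ``sizes`` (logged)."""
        kept, dropped = [], 0
        for iv in self.intervals:
            if iv.chrom in sizes.sizes:
                kept.append((iv.chrom, iv.start, iv.end))
            else:
                dropped += 1
        if dropped:
            logger.warning(
                "%s: dropped %d peak(s) on chromosomes absent from the "
                "chromosome-sizes table", self.name, dropped,
            )
        return IntervalSet(self.name, kept)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"IntervalSet({self.name!r}, peaks={self.peak_count}, "
            f"bp={self.total_bp})"
        )


@dataclass(frozen=True)
class Locus:
    """A point variant.  ``pos`` is 0-based; ``length`` is the reference
    span in bp (1 for SNVs, >1 for indels / multi-bp variants)."""

    chrom: str
    pos: int
    length: int = 1

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative locus position {self.pos}")
        if self.length < 1:
            raise ValueError(f"locus length must be >= 1, got {self.length}")

    @property
    def end(self) -> int:
        """Exclusive end of the reference span ``[pos, pos + length)``."""
        return self.pos + self.length


class LocusSet:
    """A named collection of loci (one trait / study).

    Exact duplicates (same chrom, pos, length) are removed on
    construction; the number removed is logged.
    """

    def __init__(self, name: str, loci: Iterable[Locus]):
        self.name = name
        seen = set()
        unique: List[Locus] = []
        dups = 0
        for loc in loci:
            key = (loc.chrom, loc.pos, loc.length)
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            unique.append(loc)
        if dups:
            logger.info("%s: removed %d exact-duplicate locus/loci", name, dups)
        self.loci: List[Locus] = sorted(
            unique, key=lambda l: (l.chrom, l.pos, l.length)
        )
        self.n_duplicates_removed = dups
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted({l.chrom for l in self.loci}):
            sub = [l for l in self.loci if l.chrom == chrom]
            self._by_chrom[chrom] = (
                np.array([l.pos for l in sub], dtype=np.int64),
                np.array([l.length for l in sub], dtype=np.int64),
            )

    @property
    def chroms(self) -> List[str]:
        return list(self._by_chrom)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(positions, lengths) for one chromosome (sorted by position)."""
        if chrom in self._by_chrom:
            return self._by_chrom[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    def __len__(self) -> int:
        return len(self.loci)

    def restrict_to(self, sizes: "ChromSizes") -> "LocusSet":
        """Drop loci on chromosomes absent from ``sizes`` or beyond the
        chromosome end (logged)."""
        kept, dropped = [], 0
        for loc in self.loci:
            length = sizes.sizes.get(loc.chrom)
            if length is None or loc.pos >= length:
                dropped += 1
            else:
                kept.append(loc)
        if dropped:
            logger.warning(
                "%s: dropped %d locus/loci outside the chromosome-sizes "
                "table", self.name, dropped,
            )
        return LocusSet(self.name, kept)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LocusSet({self.name!r}, n={len(self.loci)})"


@dataclass
class ChromSizes:
    """Chromosome name -> length in bp, names normalized."""

    sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: Dict[str, int] = {}
        for name, length in self.sizes.items():
            canon = normalize_chrom_name(name)
            if canon in normalized:
                raise ValueError(f"duplicate chromosome name {canon!r}")
            if int(length) <= 0:
                raise ValueError(
                    f"non-positive length {length} for chromosome {name!r}"
                )
            normalized[canon] = int(length)
        self.sizes = normalized

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def items(self):
        return self.sizes.items()

    @property
    def total_bp(self) -> int:
        return sum(self.sizes.values())
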