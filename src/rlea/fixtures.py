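"""Deterministic synthetic data: toy genomes, peak sets, locus sets.

Everything is driven by a :class:`FixtureSpec` and NumPy's PCG64
generator seeded from ``spec.seed``, so two calls with the same spec are
bit-identical on any platform (placement uses integer arithmetic only).

The generator emulates the statistical structure the enrichment model
assumes: peaks of fixed length placed uniformly without overlap, and
loci placed uniformly over the genome (null) or forced inside a target
cell type's peaks (enriched mode).  It makes no attempt to mimic real
ATAC-seq peak-length or GC distributions.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .intervals import ChromSizes, IntervalSet, Locus, LocusSet


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults give a 2 x 10 Mb toy genome, three cell types with 200
    peaks of 5 kb each (5% genome coverage per cell type) and 1000
    SNV loci — locus counts and coverage in the range of a well-powered
    GWAS trait against one cell type's open chromatin.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_cell_types: int = 3
    peaks_per_type: int = 200
    peak_length: int = 5_000
    n_loci: int = 1_000
    enrichment_fraction: float = 0.0
    indel_fraction: float = 0.0
    indel_length: int = 10
    shared_peaks: int = 0
    shared_in: Optional[int] = None  # cell types carrying the shared block

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length",
            "n_cell_types",
            "peaks_per_type",
            "peak_length",
            "n_loci",
            "indel_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("enrichment_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.shared_peaks < 0:
            raise ValueError("shared_peaks must be >= 0")

    def replace(self, **kw) -> "FixtureSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_json(cls, path: str) -> "FixtureSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_toy_genome(spec: FixtureSpec) -> ChromSizes:
    """chr1..chrN, each ``chrom_length`` bp."""
    return ChromSizes(
        {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    )


def _slot_grid(spec: FixtureSpec):
    """Peak placement slots: one peak per 2*peak_length stride, so peaks
    within a cell type can never overlap or abut."""
    stride = 2 * spec.peak_length
    per_chrom = spec.chrom_length // stride
    total = per_chrom * spec.n_chroms
    return stride, per_chrom, total


def _slot_to_span(spec: FixtureSpec, slot: int):
    stride, per_chrom, _ = _slot_grid(spec)
    chrom = f"chr{slot // per_chrom + 1}"
    start = (slot % per_chrom) * stride
    return chrom, start, start + spec.peak_length


def make_ocr_sets(spec: FixtureSpec) -> List[IntervalSet]:
    """One merged peak set per cell type, uniformly placed without overlap.

    Each cell type's own peaks occupy slots private to that cell type
    (occupancy 1 by construction); ``shared_peaks`` additional peaks are
    copied identically into the first ``shared_in`` cell types (all of
    them by default), so shared-peak occupancy is exactly ``shared_in``.
    This makes uniqueness-filter behaviour fully controlled.
    """
    _, _, total_slots = _slot_grid(spec)
    need = spec.n_cell_types * spec.peaks_per_type + spec.shared_peaks
    if need > total_slots:
        raise ValueError(
            f"cannot pack {need} peaks of {spec.peak_length} bp "
            "into the toy genome"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(total_slots, size=need, replace=False)
    shared = chosen[: spec.shared_peaks]
    shared_in = spec.shared_in if spec.shared_in is not None else spec.n_cell_types
    sets = []
    for i in range(spec.n_cell_types):
        lo = spec.shared_peaks + i * spec.peaks_per_type
        own = chosen[lo : lo + spec.peaks_per_type]
        slots = np.concatenate([own, shared]) if i < shared_in else own
        spans = [_slot_to_span(spec, int(s)) for s in np.sort(slots)]
        sets.append(IntervalSet(f"celltype{i + 1}", spans))
    return sets


def make_locus_set(
    spec: FixtureSpec,
    target: Optional[IntervalSet] = None,
    name: str = "loci",
) -> LocusSet:
    """Synthesize one locus set.

    A seeded ``enrichment_fraction`` of the loci are placed uniformly
    inside ``target``'s peaks; the rest uniformly over the genome.  An
    ``indel_fraction`` of loci get length ``indel_length`` (multi-bp),
    the others length 1 (SNV).
    """
    if spec.enrichment_fraction > 0 and target is None:
        raise ValueError("enrichment_fraction > 0 requires a target peak set")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    genome_bp = spec.n_chroms * spec.chrom_length
    n_enriched = int(round(spec.enrichment_fraction * spec.n_loci))
    loci: List[Locus] = []

    lengths = np.ones(spec.n_loci, dtype=np.int64)
    n_indel = int(round(spec.indel_fraction * spec.n_loci))
    if n_indel:
        idx = rng.choice(spec.n_loci, size=n_indel, replace=False)
        lengths[idx] = spec.indel_length

    if n_enriched:
        ivs = target.intervals
        widths = np.array([len(iv) for iv in ivs], dtype=np.int64)
        cum = np.cumsum(widths)
        draws = rng.integers(0, cum[-1], size=n_enriched)
        which = np.searchsorted(cum, draws, side="right")
        for j, d in zip(which, draws):
            iv = ivs[int(j)]
            offset = int(d) - (int(cum[j]) - int(widths[j]))
            loci.append(Locus(iv.chrom, iv.start + offset, int(lengths[len(loci)])))

    for _ in range(spec.n_loci - n_enriched):
        flat = int(rng.integers(0, genome_bp))
        chrom = f"chr{flat // spec.chrom_length + 1}"
        pos = flat % spec.chrom_length
        loci.append(Locus(chrom, pos, int(lengths[len(loci)])))
    return LocusSet(name, loci)


def write_fixture_files(spec: FixtureSpec, out_dir: str) -> dict:
    """Write a full fixture to disk in the tool's input formats.

    Creates ``ocr/*.txt`` (BED text), ``loci/*.csv`` (GWAS-catalog-style
    with 1-based positions) and ``chrom_sizes.csv``; returns the paths.
    """
    ocr_dir = os.path.join(out_dir, "ocr")
    loci_dir = os.path.join(out_dir, "loci")
    os.makedirs(ocr_dir, exist_ok=True)
    os.makedirs(loci_dir, exist_ok=True)

    sizes = make_toy_genome(spec)
    sizes_path = os.path.join(out_dir, "chrom_sizes.csv")
    with open(sizes_path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom},{length}\n")

    ocr_sets = make_ocr_sets(spec)
    for iset in ocr_sets:
        with open(os.path.join(ocr_dir, f"{iset.name}.txt"), "w") as fh:
            for iv in iset.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    null_spec = spec.replace(enrichment_fraction=0.0)
    locus_sets = [
        make_locus_set(null_spec, name="trait_null"),
        make_locus_set(
            spec.replace(
                seed=spec.seed + 1,
                enrichment_fraction=max(spec.enrichment_fraction, 0.5),
            ),
            target=ocr_sets[0],
            name="trait_enriched",
        ),
    ]
    for lset in locus_sets:
        with open(os.path.join(loci_dir, f"{lset.name}.csv"), "w") as fh:
            fh.write("CHR_ID,CHR_POS,LENGTH\n")
            for loc in lset.loci:
                fh.write(f"{loc.chrom},{loc.pos + 1},{loc.length}\n")

    return {
        "ocr_dir": ocr_dir,
        "loci_dir": loci_dir,
        "chrom_sizes": sizes_path,
    }
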