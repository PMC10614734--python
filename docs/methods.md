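# Methods

## Model

The enrichment test asks whether a set of genomic loci falls inside a
cell type's open chromatin regions (OCRs) more often than uniform
placement would predict. The genome (given by a chromosome-sizes table)
is tiled into windows of near-equal length close to a target size
(default 1 Mb): a chromosome of length L gets W = max(1, round(L /
target)) windows of length floor(L/W) or ceil(L/W), longer windows
first, tiling exactly.

For one (cell type, locus set) pair, each window *i* containing nᵢ ≥ 1
loci contributes an independent term Xᵢ ~ Binomial(nᵢ, pᵢ), where pᵢ is
the fraction of the window covered by the cell type's merged peaks.
This conditions on the observed spatial distribution of loci across
windows — clustering of GWAS hits along the genome does not inflate the
statistic — while assuming loci are exchangeable *within* a window.
Genome-wide, the null overlap count is S = ΣXᵢ, a sum of independent
non-identical binomials, and the p-value is P(S ≥ k) at the observed
count k (each locus counted once, overlap judged by its full reference
span against the merged peaks).

Assumptions worth stating: loci are treated as independent (no LD
pruning); a window is homogeneous, i.e. within a window every position
is equally likely for a null locus; and windows are independent. The
window size trades these off — smaller windows weaken the homogeneity
assumption's bite but leave fewer loci per window.

### Multi-bp loci (indels)

A locus of length ℓ > 1 occupying [pos, pos + ℓ) can overlap a peak
without starting inside it, so the success probability must use a grown
peak footprint: a locus overlaps a peak iff its start falls in the peak
extended ℓ − 1 bp leftward. We implement a window-level simplification:
if any multi-bp locus assigned to the window overlaps open chromatin,
every peak segment intersecting the window is grown by (Lmax − 1) bp on
*each* side — Lmax the largest such locus length — then re-unioned and
clipped to the window before computing pᵢ. Symmetric growth with a
single window-level Lmax slightly over-corrects relative to a
per-locus-length mixture; the rule is isolated in `window_stats` so it
can be swapped. With SNVs only, pᵢ is the plain coverage fraction.

### Edge rules

Each locus belongs to exactly one window, by its start position
(half-open rule), so Σnᵢ partitions the loci. A boundary-spanning locus
is still counted once in the genome-wide k. Loci or peaks on
chromosomes absent from the sizes table are dropped with a logged
count. Windows with pᵢ = 0 contribute nothing stochastic; windows with
pᵢ = 1 shift the support deterministically.

## Tail probability of a sum of non-identical binomials

`rlea.sinib` provides two evaluators.

**Exact.** Dynamic-programming convolution of the term-wise binomial
PMFs (float64; the survival function is accumulated from the top of the
support so small tails keep relative accuracy). Practical to N = Σnᵢ of
order 10⁵; the `tail(..., method="auto")` entry point uses it for
N ≤ 2000.

**Saddlepoint.** The CGF of the stochastic part is K(u) = Σ nᵢ ln(1 −
pᵢ + pᵢeᵘ), evaluated in log-sum form so it is stable for any |u|.
For P(S ≥ k) we use the integer-lattice ("second continuity
correction") Lugannani–Rice form: solve K′(û) = s with s = k − ½ by
safeguarded Newton (bracketed, tolerance 1e−12 relative), then

    w  = sign(û) √(2(û·s − K(û))),
    u₂ = 2 sinh(û/2) √K″(û),
    P(S ≥ k) ≈ 1 − Φ(w) − φ(w)(1/w − 1/u₂).

A second-order correction, on by default, adds

    φ(w)·[ 1/w³ + A/u₂ + (κ̂₃/(2K″))·g′(û) − g″(û)/(2K″^{3/2}) ],

with A = κ̂₄/8 − 5κ̂₃²/24, κ̂ⱼ the standardized cumulants at û, and
g(u) = 1/(2 sinh(u/2)) the lattice kernel whose derivatives replace the
1/u-kernel terms of the continuous-case formula. (The textbook
continuous second-order bracket does **not** apply verbatim to the
lattice correction; the kernel-derivative form above is derived by
Watson expansion of the regular part of the inversion integral and was
validated against the exact oracle: worst relative error ≈ 2e−5 over
200 random 20-term models at every k with tail ≥ 1e−10, versus ≈ 3e−2
for the first-order form.)

Numerical edges: terms with p = 0 or n = 0 are dropped; p = 1 terms
accumulate a deterministic offset; k at the top of the support uses the
closed form Πpᵢⁿⁱ; |û| < 1e−4 (the mean) switches to a
skewness-corrected normal (Edgeworth) limit where Lugannani–Rice is
indeterminate; the second-order bracket is skipped for |w| < 0.2, where
its pieces cancel catastrophically in doubles while contributing
negligibly. All tail arithmetic is carried in signed log space, so
−log10 p is reported faithfully beyond float underflow (p < 1e−308).

Known limitation: for very small stochastic totals (N ≲ 10, e.g. a
single Binomial(3, p) term) no asymptotic order is accurate near the
mode — errors of a few percent occur. The `auto` dispatch always uses
the exact path there; the saddlepoint path is only reached for
N > 2000, far inside its asymptotic regime.

## Cell-type weighting, clustering, uniqueness

The relatedness weight is weight_ij = 1 − (O/Pᵢ)(O/Pⱼ). "Overlap of
peaks" and "sum of peaks" admit several definitions; we take O as the
number of intersecting peak *pairs*
between the merged sets (the only symmetric choice consistent with
dividing one numerator by both peak counts) and Pᵢ as the peak *count*,
keeping both ratios dimensionless. Since one merged peak can intersect
several peaks of the other set, O may exceed a peak count; the weight
is then clamped into [0, 1] with a logged warning. Identical sets give
0, disjoint sets 1, the diagonal is forced to 0. Rows of the weight
matrix are clustered with SciPy's agglomerative linkage (average/UPGMA
by default, CLI-selectable) on Euclidean row distances; ties break
deterministically by lowest index. The dendrogram is exported as an
image and as Newick text carrying merge heights.

The uniqueness filter computes, for every peak of every cell type, its
occupancy: the number of distinct cell types (its own included) with
≥ 1 bp intersection. Peaks with occupancy above the cutoff are removed
from every set; a cutoff of 3 keeps peaks found in three or fewer cell
types. Occupancy uses the same ≥ 1 bp intersection rule as the weight
numerator. Locus sets can be filtered to a minimum size (inclusive ≥,
so a cutoff of 200 keeps sets with exactly 200 loci).

## Multiple testing

The n × m raw p-values are corrected as one family: Bonferroni
(p·nm, capped at 1) by default — matching the conservative reading of
"survives correction" — or Benjamini–Hochberg step-up via statsmodels.
Cells with adjusted p below α (default 0.05) are flagged in the CSVs
(`survives_correction`) and outlined in the heatmap.

## Synthetic data

`rlea.fixtures` generates everything the tests and the acceptance
script consume. Defaults: a 2 × 10 Mb genome; 3 cell types × 200 peaks
of 5 kb (5% coverage per cell type, in the range of real open-chromatin
fractions); 1000 SNV loci per set, a locus count typical of the
well-powered GWAS traits the method targets and large enough that the
discrete overlap count has fine granularity. Peaks occupy slots on a
2×peak-length grid, private to each cell type, so within- and
cross-type overlaps are impossible except for an optional shared block
copied identically into the first k cell types — giving exactly known
occupancies for uniqueness-filter tests. Loci are uniform over the
genome (null) or forced with probability `enrichment_fraction` to be
uniform within a target cell type's peaks; an `indel_fraction` of loci
get a configurable multi-bp length. All draws come from NumPy's PCG64
seeded from the spec, with integer placement arithmetic, so fixtures
are bit-stable across platforms.

What this emulates — and not: the generator reproduces the statistical
structure the model assumes (uniform null placement, fixed peak
geometry). It does not mimic real ATAC-seq peak-length or GC
distributions, LD between loci, or chromosome-scale covariates, so
passing calibration here validates the statistic's internal
consistency, not robustness to those real-data features.

Because the overlap count is integer-valued, null p-values are
uniform only up to discreteness: the rejection rate at α = 0.05 sits
slightly below 0.05 (≈ 0.03–0.05 depending on the peak-set
realization) and the KS distance from uniform is ≈ 0.04–0.06. This is
the ordinary conservatism of a discrete test, shrinking as locus
counts grow.

## Problem sizes in the test suite

The suite's statistical checks use the defaults above: 200 × 20-term
models for the oracle sweep, 1000 replicates for calibration, 25
replicates per effect size (0 → 0.8) for the power curve, and a
3 × 2 pipeline fixture — about half a minute end to end. The window-
size stability check compares 10 kb vs 100 kb tilings on the null
fixture and bounds the median |Δlog₁₀ p| by 0.5 as a regression
property.
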