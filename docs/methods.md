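# Methods

This note documents the models, parameter choices, and numerical
decisions behind `wfkit`, and what the synthetic-data generators do and
do not emulate.

## Coordinate conventions

All genomic coordinates are 1-based and fully closed, so
`length = end − start + 1`. This matches how genome browsers print
intervals: the full-length promoter chr18:72,542,815–72,544,612 has
1,798 bases and rounds (half-up, one decimal) to 1.8 kb, and the
cCRE-truncated promoter has 1,180 bases (1.2 kb). BED files are 0-based
half-open on disk; conversion is exact and covered by round-trip tests.

## Promoter delineation

The promoter is carved out of a cross-species conserved block in three
steps:

1. **ORF excision.** Any open reading frame overlapping the block that
   could interfere with a downstream reporter is removed, together with
   an explicit spacer (`buffer_bp`) on both flanks. The largest
   remaining sub-interval is the promoter; ties break toward the gene's
   5′ side. The published boundaries reproduce with the observed 175 bp
   spacer between the ORF end and the promoter start — the exact rule
   that produced that spacer is not derivable from coordinates alone,
   so it is an explicit parameter rather than a guess.
2. **cCRE truncation.** The promoter is kept from its 5′ end (gene
   orientation) through the cCRE edge nearer the gene body. The gene is
   taken as minus-strand: that is the only orientation under which the
   printed truncation arithmetic yields 1.2 kb.
3. **Length accounting** in kb, rounded half-up to one decimal.

ORF scanning reports every ATG to its first in-frame stop (so nested
ORFs sharing a stop are all reported); codons containing N neither
start nor stop an ORF and break any ORF spanning them. The
conserved-block finder is a k-mer–seeded, ungapped-extension local
aligner (word size 11, match +1, mismatch −2, x-drop 20, greedy
non-overlapping selection on the query by score). It is built to
recover long high-identity homologous blocks, not to replicate any
particular local-alignment tool's scores.

## Alignment and identity statistics

Two or three sequences are aligned progressively: the closest pair
first (by quick pairwise identity), then the remaining sequence aligned
to the more similar member of that pair and merged through it as an
anchor, emitting anchor-relative insertions deterministically. Pairwise
steps are global affine-gap alignments (Needleman–Wunsch).

Default scores are match +1, mismatch −1, gap open −8, gap extend −1.
The stiff open penalty is deliberate: at ~50% identity a permissive
open penalty (e.g. −4) lets the dynamic program pair random matches
through compensating gaps, inflating the estimated identity by up to
4 percentage points on 1.8 kb synthetic pairs; with −8 the bias
measured against generator ground truth is below 1 point across 20
seeds. An externally produced alignment can be supplied as gapped
FASTA, and all statistics operate on it identically.

Identity uses the both-non-gap column denominator; columns containing N
count as mismatch. Coverage of species S is the fraction of reference
(human) positions aligned to a non-gap in S. Per-column flags
(match / mismatch / gap / ref-gap) back the identity-track plot.

## TFBS conservation

JASPAR count matrices become log₂-odds PWMs with a pseudocount of 0.8
distributed by the background (uniform by default). The relative score
of a window is `(score − min) / (max − min)`, so the best possible
k-mer scores exactly 1; both strands are scanned (minus-strand hits are
scored against the reverse-complemented matrix and reported in forward
coordinates), windows containing non-ACGT characters are skipped, and
overlapping hits are all retained. The default hit threshold is a
relative score of 0.85 and is configurable; the downstream conservation
procedure does not depend on it.

Each hit is mapped through the alignment position-by-position; the
orthologous characters are compared case-insensitively, with alignment
gaps and N counting as mismatch, giving `similarity = matches / site
length`. Minus-strand sites are reverse-complemented on both sides
before comparison (this preserves the match count; it mirrors the
strand-aware extraction a practitioner would do). With threshold
τ = 0.70 — a value **at** the boundary counts as conserved — the joint
(tree shrew, mouse) similarities decide the four conservation classes.

## Imaging arm

Channels are binary 3D grids (z, y, x) with anisotropic voxel size,
default 0.06 × 0.06 × 0.3 μm (x, y, z). Preprocessing mirrors the named
2D slice-wise cleanup operations: binarize, fill holes (background not
connected to the slice border), distance-transform watershed with
ridge-line removal (splits touching blobs), one iteration of
8-neighborhood erosion, and a 3×3 median. They apply in the order
given.

An apposition is a connected component of `bouton AND dendrite`;
component connectivity defaults to 26 (3D diagonal). Volumes are voxel
count × voxel volume; components below the volume cutoff (default
0.0218 μm³, boundary kept) are discarded as false positives. Components
are assigned to a lamina by centroid depth; depth is the y axis.
Dendrite traces are SWC polylines whose radius column is half the
caliber; per-lamina length clips each segment to the lamina with
proportional splitting at boundary crossings, and caliber averages
point diameters within the lamina.

Per-lamina metrics: bouton density = 100 × count / ROI volume (μm³);
apposition frequency = 100 × count / dendrite length (μm); relative
density index = 100 × nVGluT2 / (nVGluT1 + nVGluT2), computed
separately for dendrite-apposed counts and overall bouton counts.
Apposition frequency is per 100 μm of dendrite length (not per volume);
bouton counting for densities applies the same volume filter as
appositions.

## Cutoff calibration

Prediction accuracy (PSD95⁺ share of surviving appositions) and
true-positive retention (PSD95⁺ share kept) are evaluated at 21 evenly
spaced cutoffs over [0, 0.5] μm³. Grid points whose survivor set is
empty contribute no accuracy value and are dropped from the fit, not
imputed. Each curve is fitted with an ordinary least-squares line
(consistent with reporting a single R² per curve; the regression family
is otherwise an open choice), and the calibrated cutoff is the
two-line intersection, clipped to the range. Parallel lines raise a
"no crossing" error. The exact published cutoff value depends on the
raw apposition volume distribution, which is not reproducible from
summary statistics; the calibration is therefore validated by its
statistical properties — retention starts at exactly 100 and is
monotone non-increasing, both metrics stay in [0, 100], and on
two-population synthetic benchmarks the crossing falls between the
false-positive and true-positive volume medians in ≥ 18/20 seeds.

## Synthetic data: what it emulates, and what it does not

**Promoter trios.** A uniform-random human sequence (default 1,800 bp,
matching the promoter length) with planted motif sites; derived species
apply i.i.d. substitutions at rate 1 − identity (defaults 0.76 and
0.53 for the two species) and geometric-length indels at 0.01 per site
(mean length 2) — a modest indel load typical of noncoding alignments
at these divergences. Planted "intact" sites are protected from all
mutation; "scrambled" sites are permuted, choosing a permutation with
at most 50% residual fixed-point similarity so the planted
non-conserved status cannot be defeated by a low-complexity shuffle.
The registry records realized identities (the fraction of retained
positions left unsubstituted), which is what a correct alignment should
report as both-non-gap identity. The generator does not emulate real
promoter base composition, CpG structure, locally varying conservation,
or motif turnover — so passing recovery tests demonstrates the
statistics and classing are correct, not that the aligner matches any
particular tool on real promoters.

**PSD95 benchmarks.** Apposition volumes are lognormal within class
(coefficient of variation 0.5) with class means 0.8647 μm³ (PSD95⁺) and
0.0881 μm³ (PSD95⁻) — the two observed populations, roughly 10× apart —
and Bernoulli class labels at the observed 83.6% colocalization
fraction, at the observed sample size n = 438. Only means are reported
for the real populations, so the lognormal shape and CV are modeling
choices; conclusions drawn from the benchmark are therefore limited to
properties robust to the within-class distribution shape.

**Label volumes.** A straight dendrite tube (radius 1 μm) along x at
mid-depth; ellipsoidal boutons (semi-axes 0.25 × 0.25 × 0.45 μm)
placed by a Poisson process at per-lamina densities with random
sequential placement at ≥ 1.5 μm center separation (so every bouton
labels as exactly one 26-connected component and the same-channel
non-overlap constraint holds); appositions as ellipsoids
(0.35 × 0.35 × 0.45 μm) centered on the dendrite surface at Poisson
per-length frequencies, with PSD95 co-labels on a Bernoulli
true-positive fraction of VGluT2 appositions. Background boutons keep
clear of the dendrite, so planted appositions are the only
bouton–dendrite contacts. Default planted rates are the observed
sublayer values (VGluT1 densities 1/3/7 and VGluT2 8/6/6 per 100 μm³
dorsal→ventral; VGluT1 apposition frequencies 1.57/8.76/11.05 and
VGluT2 18/18/19 per 100 μm). The generator does not emulate optics
(PSF, noise, bleed-through), curved or branching dendrites, bouton
shape diversity, or segmentation error — volumes are born binary, as
the quantification stage consumes them after upstream segmentation.

## Problem sizes in tests and the reproduction script

Recovery experiments are sized so the Poisson/binomial sampling error
of the mean sits well inside the 10% recovery tolerance: the benchmark
recovery uses 20 seeded sets of n = 438 (99% sampling half-width ≈ 1.0
percentage point); density recovery uses five 30 × 30 × 15 μm volumes
at 7 boutons/100 μm³ (≈ 4,700 boutons; sampling error ≈ 1.5%);
frequency recovery uses five 800 μm dendrites at 18 appositions/100 μm
(≈ 720 appositions; sampling error ≈ 3.7%). The test suite uses
slightly smaller volumes for speed, with the same logic.

## Degenerate inputs and tie-breaking

Empty sequences, out-of-range positions, unknown species/steps, shape
or voxel-size mismatches, zero denominators, negative cutoffs, and
single-class benchmarks raise immediately with the offending item
named. Gap columns have no inverse coordinate (an error, not 0).
Boundary rules: a component exactly at the volume cutoff is kept; a
similarity exactly at τ is conserved; a cCRE coincident with the
promoter's terminal base truncates nothing. Progressive-alignment ties
(equal-scoring alignments) resolve to the first alignment enumerated by
the pairwise aligner, making runs reproducible; the choice among
co-optimal alignments is otherwise arbitrary.

## Known limitations

* The progressive aligner is adequate for the identity statistics but
  is not an iterative-refinement MSA tool; on real low-identity
  promoters an external alignment may be preferable (and can be
  supplied as gapped FASTA).
* Conserved-block search is ungapped; long homologous blocks
  interrupted by large indels will be reported as multiple blocks.
* Lamina assignment is by centroid depth only; components straddling a
  boundary are not split.
* The straight-tube dendrite model understates path-length per volume
  relative to real tortuous dendrites; frequency recovery is exact for
  the planted geometry but untested on curved traces beyond the
  SWC-clipping unit tests.
* `simulate_label_volumes` at the full default field of view
  (250 × 250 × 50 μm at 0.06 × 0.06 × 0.3 μm voxels) allocates
  multi-gigabyte grids; recovery experiments use smaller fields with
  identical statistics.
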