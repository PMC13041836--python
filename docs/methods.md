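# Methods

`mitoquant` re-implements, as an open and deterministic pipeline, the
image- and trace-quantification procedures used in mitochondrial
quality-control studies of cultured cells: tandem-reporter mitolysosome
counting and mitophagy flux, depolarized-mitochondria classification,
lysosome radial-distribution statistics, nuclear-translocation intensity,
STED cristae-density line profiles, and mito-stress-test respirometry.
The original analyses of this kind are performed interactively in
commercial software (high-content analysis suites, machine-learning pixel
classifiers); here every hidden choice — thresholds, cutoffs, percentiles,
gate bounds — is either an explicit formula or a logged derived value, so a
run is reproducible from its provenance log alone.

## Image model and core operators

Images are multi-channel Z-stacks indexed `(z, channel, y, x)` with an
isotropic in-plane pixel size in micrometres (a required acquisition input:
it cannot be recovered from pixel data) and a role map naming each channel
(`dapi`, `gfp`, `mcherry`, `mtg`, `tmre`, `lamp1`, ...). Counting and
morphology channels are maximum-projected over Z; intensity-quantification
channels (TMRE, DQ-BSA) are sum-projected, so total signal is preserved.

The object-detection recipe shared by all puncta assays is:

1. **white top-hat** with a disk structuring element (default radius 5 px)
   to suppress broad background while keeping features smaller than the
   disk.  Boundary handling clamps to the edge value, which makes the
   opening pointwise ≤ the image and the top-hat everywhere ≥ 0;
2. **Otsu threshold**, applied with strict `>` so a zero threshold on an
   integer image cannot flood the foreground.  The chosen threshold is
   written to the provenance log;
3. **connected components** (8-connectivity, raster-scan label order) or,
   for merged puncta, a **distance-transform watershed** whose seeds are
   local maxima of the Euclidean distance transform separated by at least
   3 px.  The watershed labels partition the input mask exactly: any mask
   component left without a seed becomes its own object.

Per-object measurements (area in µm², centroid, per-channel mean/summed
intensity, border contact) are accumulated over the object's pixels; an
object belongs to the cell whose label lies under its centroid.

## Cell-by-cell segmentation

Nuclei come from the DAPI channel: Otsu threshold, hole filling, removal of
objects below a minimum area (default 10 µm²).  An empty (noise-only) field
has no meaningful Otsu split; the threshold's separability — Otsu's own
effectiveness metric, between-class over total variance — is checked
against a floor (default 0.7, chosen between the ≈0.65 of pure
Poisson+read-noise background and the ≳0.9 of fields with real nuclei), and
a field below it yields zero nuclei rather than percolated noise objects.

Cells are a nucleus-seeded watershed of the cytoplasm channel after a
Gaussian blur (default σ = 8 px): the cytoplasm mask is the Otsu foreground
of the blurred channel united with the nuclei, each cell inherits its seed
nucleus label, and cytoplasm unreachable from any seed stays background.
With a constant (signal-free) cytoplasm channel the cells degenerate to the
nuclei — the defensible limit of the recipe.

Two exclusions follow. Cells with any border pixel are excluded (not fully
depicted in the field of view); exclusion is bookkeeping on label ids, so
it is idempotent and never rewrites masks.  Optionally, cells are gated on
per-cell mean reporter intensity to keep only the medium-expression
population: quantile bounds (default 10th–90th percentile of the field's
distribution, linear interpolation, recorded per field in the provenance
log) with a strict rule — a cell is dropped only if its mean lies strictly
outside the band, so an all-equal field keeps every cell.

## Assay statistics

**Mitolysosomes.** In the tandem mCherry–GFP reporter, GFP is quenched in
acidic lysosomes, so mitochondria inside lysosomes appear as red-only
puncta.  An mCherry object counts as a mitolysosome iff none of its pixels
coincides with or is 8-adjacent to the GFP mask.  "Touching" (overlap or
8-adjacency) is a single predicate used symmetrically everywhere:
mitolysosome counting *excludes* touching objects, mitophagosome counting
(LC3 vesicles at mitochondria) *includes* them.

**Mitophagy flux** is the ratio of the mean per-cell mitolysosome count
with lysosomal protease inhibitors (leupeptin/pepstatin A, which block
degradation and let mitolysosomes accumulate) to the mean without.  Cells
are not paired across wells, so the ratio of per-condition means is used,
never a mean of per-cell ratios; the ratio is undefined (flagged) when the
uninhibited mean is zero.

**Depolarized mitochondria.** Mass objects come from the potential-
independent MTG channel (top-hat → Otsu → components); the potential
readout is the summed TMRE projection.  An object is an *individualized
small* mitochondrion iff its area is < 1 µm²; it is *depolarized* iff
additionally its mean TMRE falls below a background-derived cutoff:
mean + k·SD (default k = 3) of TMRE over non-mitochondrial pixels within
retained cells.  Because the cutoff is an affine function of the same
image, both counts are exactly invariant under a uniform additive TMRE
offset, and trivially invariant under object relabeling.

**Lysosome distribution.** Each vesicle's distance is from its centroid to
the nearest pixel of its own cell's nucleus (µm).  The peripheral threshold
is the 75th percentile (linear interpolation) of a declared reference
condition's distances — normally the control arm, applied to every arm so
the statistic is comparable — or of the analyzed field itself when no
reference is given.  A vesicle is peripheral iff strictly beyond the
threshold; per-cell counts are normalized by the cell's mitochondrial-mask
area.  Note an arithmetic fine point: under linear interpolation the
self-referenced rule can mark up to ⌈0.25·(n−1)⌉ of n vesicles — "a quarter
up to one vesicle", marginally above 25 % for some n; the tests assert this
exact bound.

**Intensity statistics.** Degradative activity (DQ-BSA) is the mean summed
projection over the LAMP1 mask; nuclear translocation is the mean marker
intensity over the nucleus mask per retained cell, with the cytosolic
reference taken over cell-minus-nucleus pixels.

**Cristae density.** A 1-D line profile across a mitochondrion (STED
acquisition sampling, 30 nm) is reduced to peaks per µm of line.  Manual
peak counting is formalized as prominence-based detection: local maxima
with prominence ≥ 20 % of the profile's dynamic range (flat profiles have
zero peaks by convention) and pairwise separation ≥ 60 nm (two acquisition
pixels), ties resolved toward the lower index.  Both parameters are
exposed; density = peak count / profile length.

**Respirometry.** Mito-stress-test traces (basal → oligomycin → FCCP →
rotenone+antimycin A; the two sequential FCCP additions are one phase) are
summarized as: last basal point, minimum of the oligomycin phase, maximum
of the FCCP phase, mean of the rotenone/AA phase (= non-mitochondrial
respiration).  All parameters are corrected by subtracting the
rotenone/AA-insensitive rate.  `basal` is assembled as
`atp_linked + proton_leak` (with `atp_linked = basal_raw − oligo_raw`,
`proton_leak = oligo_raw − nonmito`) so the identities
`basal = atp_linked + proton_leak` and `reserve = maximal − basal` hold
bit-exactly, not merely to rounding; negative corrected rates are reported
as computed with a quality flag.  The OXPHOS ATP production rate converts
the oligomycin-sensitive OCR with 2 O per O₂ and a P/O ratio of 2.75
(both configurable).

## Synthetic data and what it does (not) show

Every stage is validated against simulated fields whose target quantities
are planted and recorded as ground truth.  The simulator reproduces the
*statistical* structure of the assays, not their texture: cells are
jittered disks on a grid (defaults: 16 cells per 420×420 px field at
0.3 µm/px, cell radius 9 µm, nucleus 2.5 µm), the mitochondrial network is
a dilated random walk (5 segments, 0.45 µm tubule width), mitolysosomes and
vesicles are Gaussian spots (Poisson-distributed counts, default rate 6 per
cell), and the camera model is Poisson shot noise on the signal plus
additive Gaussian read noise (SD 2).  Default intensity levels are set so
that Otsu thresholding recovers essentially all planted foreground — the
high-SNR regime in which the published procedures are applied.

Generators are pure functions of (parameters, seed): identical seeds give
bit-identical stacks, and raising the noise level changes pixels but never
the ground truth.  Planted objects keep safety margins (puncta ≥ 4 px from
the network so a detected spot can never become 8-adjacent to the detected
network; the nuclear marker plants levels net of the camera background so
the measured nuclear/cytosolic ratio equals the planted fold; objects stay
within 0.8 of the cell radius so they always land inside the detected
cell).  Per-cell Poisson puncta counts are capped at a geometric capacity
(16) so a field always remains placeable; if retries are ever exhausted
anyway, the cell simply stops accepting objects.  In both cases the ground
truth records what was actually planted, so recovery comparisons stay
exact; only the flux-*parameter* comparison carries the cap's truncation
bias (≈0.7 % on the inhibitor-arm mean at the default rates).  The fixed
per-cell counts of the membrane-potential generator are placed with hard
margins instead, and raise an error if they cannot be honoured.

Consequently, passing recovery tests show that the *rules* (counting,
classification, distances, ratios) are implemented correctly and are
unbiased under a realistic camera-noise model.  They do not show robustness
to out-of-focus light, texture, segmentation ambiguity between touching
cells, or staining variability in real micrographs — on real data the
interactive choices these pipelines replace remain the dominant source of
variation, which is why every derived threshold is logged.

## Problem sizes and numerical choices

Validation workloads mirror the study design at laboratory scale: puncta
recovery on ~100 cells (7 fields); flux on five replicates of ~200 analyzed
cells per arm (16 fields per arm, after the 10–90 % reporter gate);
depolarization on ~64 cells; distribution contrasts on five
reference/test field pairs; nuclear fold on ~112 cells; cristae on a
noiseless comb (25 nm sampling, where count/length is exactly 4 /µm) plus
20 noisy replicates at 30 nm; respirometry identities on 1000 random
traces.  `scripts/acceptance.py` recomputes all of these from scratch from
a single seed.

Deterministic tie-breaks throughout: strict `>` at thresholds; raster-scan
label order; watershed seeds from a deterministic peak search; centroid →
cell assignment by rounding to the nearest pixel.  Degenerate inputs are
defined rather than special-cased: empty masks give NaN means with a flag,
flat profiles give zero peaks, a full-coverage mitochondrial mask (no
background pixels) is an error.

## Known limitations

- Strictly 2-D after projection; no volumetric segmentation, deconvolution
  or PSF modelling.
- The classical pipeline replaces, but does not imitate, the interactive
  and machine-learning segmentations used in the original workflows; no
  attempt is made to match any tool bit-for-bit.
- ECAR is parsed and summarized per phase but not decomposed into a
  glycolytic ATP rate.
- Statistical comparison between biological conditions is out of scope;
  per-cell and summary tables are emitted for external statistics.
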