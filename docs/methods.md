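# Methods

This note documents the models, conventions and design choices behind
each module, in the order data flows through the pipeline.

## Barcode codebooks (`pfish.codebook`)

Guides are encoded as constant-weight binary codewords over a
`n_rounds × n_channels` bit layout (bit *b* ↦ round `b // n_channels`,
channel `b % n_channels`, row-major by round). Constraints:

* Hamming weight exactly 4; pairwise Hamming distance ≥ 4. Weight-4 /
  distance-4 codes correct any single bit error: a corrupted read of
  weight 3, 4 or 5 is within distance 1 of exactly one codeword.
  Two-error reads are equidistant from ≥ 2 codewords and are discarded.
* No codeword may place all 4 on-bits in one color channel (channel-wide
  background or bleed-through would mimic the barcode), and no round may
  have all of its channels on (a bright aggregate in one round would).

**Search strategy.** All admissible weight-4 vectors are enumerated
(1,290 of the C(15,4) = 1,365 for the 15-bit reference layout), shuffled
with a seeded generator, and accepted greedily at distance ≥ 4. A single
greedy pass is shuffle-dependent — over 200 shuffles it yields between 74
and 86 codes in 15 bits — so the generator spawns deterministic restart
seeds from the user seed (up to 200 passes) and keeps the first pass
reaching the requested count. This makes the standard request of 78–82
codes in 15 bits reliable for any seed while remaining fully
deterministic. The generator guarantees only what it returns and reports
the best achieved count on failure; it makes no claim to the
coding-theory maximum (a Steiner S(3,4,15) quadruple system attains 140
codes in 15 bits, but maximal constant-weight code construction is out of
scope).

Blanks are the last accepted codewords: they obey identical constraints,
so their decode frequency is an unbiased proxy for the per-barcode false
call rate.

## Decoding (`pfish.decode`)

Order of operations per bit image, matching the conventional band-pass
spot-enhancement chain:

1. divide by the per-channel background image (flat-field; the image must
   be strictly positive — no silent epsilon),
2. Gaussian enhance with σ = 2 px, subtract the σ = 12 px Gaussian blur
   of the same divided image ("size" of a Gaussian filter is read as its
   standard deviation, the conventional single-parameter meaning; kernels
   truncated at 4σ),
3. max-project the 7 z-planes, clip at 0,
4. binarize at an absolute threshold, label with 8-connectivity, and
   remove components with area < 7 px, area > 450 px, or eccentricity
   > 0.8.

The binarization threshold is an explicit parameter (defaulting to
mean + 3 σ of the preprocessed image) because the appropriate value
depends on spot brightness and density; for resolving spots ~10 px apart
the threshold should sit high enough that blob radii stay below half the
spot separation, or adjacent blobs merge into undecodable candidates.

Candidate spots are connected components of the logical OR of all
retained per-bit masks (the alternative reading — max-projecting the
intensity images and re-detecting — gives the same candidates at
practical thresholds; the mask union is the one implemented). Bit *b* of
a candidate is on iff some retained object in bit image *b* has its
centroid within 5 px (Euclidean) of the candidate centroid. Identity
assignment uses single-error codebook matching. Coordinates are 0-based
`(x right, y down)` with the half-open pixel convention; centroids are
unweighted.

**Intensity QC.** Spots are split into 2 clusters by k-means (fixed seed,
10 restarts) on z-scored (mean on-bit intensity, std of intensity across
on-bits); the cluster with the higher blank fraction is rejected, with a
tie broken toward rejecting the dimmer cluster. The reference analysis
identified the misidentification cloud by eye on the same scatter; the
k-means split automates that judgement deterministically. With no decoded
blanks or a degenerate feature cloud, all spots pass and a warning is
emitted.

**Error rate.** `rate = (n_blank / B) / ((n_total − n_blank) / R)`,
reported as a percentage, with `R` real-guide (targeting + control)
barcodes and `B` blanks. With the production composition R = 74, B = 4
this normalization reproduces both published worked examples exactly
(14,864 / 22 → 2.74 %; 13,216 / 5 → 0.70 %), which no simpler ratio of
the printed counts does; the constants are therefore inferred rather than
quoted, and are taken from the codebook at run time.

Registration across rounds is integer-pixel translation from the
cross-correlation peak of per-round fiducial images against round 0 —
deliberately minimal, since bead-based drift correction pipelines exist
elsewhere and the simulator only produces rigid offsets.

## Segmentation and tables (`pfish.cells`)

* **Watershed route** (dense cultures): elevation = −(Gaussian-blurred 2D
  transcript histogram), flooded from nucleus centroids, masked below a
  density floor of 5 % of the smoothed maximum (the floor decides where
  cells end; exposed in the API). Nuclei are Otsu-thresholded, hole-filled
  components ≥ 20 px.
* **Dilated-nuclei route** (sparser cultures, tissue): threshold DAPI,
  label, expand each label isotropically by a distance-transform
  tie-break so labels never overwrite each other.
* **Cross-modality registration**: least-squares 2×3 affine on ≥ 3
  non-collinear landmark pairs; exact on consistent systems.
* **Neighbor graph**: cells *i*, *j* are contact neighbors iff the
  Euclidean-disc dilation of *i*'s mask (distance transform ≤ d, "in all
  directions") overlaps *j*'s mask. Presets: 50 px (MERFISH-scale
  monolayer), 10 px (RNAscope), 30 px (tumor sections). Density classes:
  ≤ 2 neighbors low, ≥ 3 high.
* **Count/design assembly**: pixel lookup of each transcript / qc-passing
  guide spot; out-of-mask points are only counted as unassigned. A cell
  is a control iff it carries ≥ 1 decoded guide, all control-class.
  Cells with > 1 distinct targeting guide are excluded from effect
  inference by default (multiplicity-of-infection doublets would mix
  effects); a keep-all mode exists.
* **QC presets**: cell-total bounds are inclusive on the keep side
  (the published phrasing "less than 70 or more than 2300" removes
  strictly outside values): THP1 70–2300 counts; astrocyte 200–1900
  counts and genes ≥ 0.5 counts/cell; tumor genes ≥ 0.3 counts/cell,
  cells 40–800 counts and 2,000–30,000 px area. Gene filters are applied
  before cell-total filters (gene means computed over all incoming
  cells), so totals reflect the retained panel.

## Effect inference (`pfish.effects`)

The estimator is the shrinkage-free "naive" log-ratio:
`LFC[p, g] = ln((mean_p + ε) / (mean_ctrl + ε))` with ε = 0.01 added to
the group means. The pseudocount choice is ours (the source analysis does
not state one): it guards `ln 0` for silent genes while perturbing
well-expressed genes by < 1 %. ε = 0 is allowed when all means are
positive, in which case swapping perturbed/control labels negates every
LFC exactly. Optional per-10k normalization rescales each cell to 10,000
total counts first.

Significance: the cell → assignment labels (perturbation indicators and
control flags together) are permuted jointly across genes — one shuffle
per permutation, as in permuting "the perturbation assignment" — and
`p = (1 + #{|LFC_perm| ≥ |LFC_obs|}) / (n_perm + 1)` (two-sided, add-one,
never exactly 0). BH is applied pooled over the whole
perturbation × gene matrix (matrix-wide q values), and q < 0.1 is the
significance call. Perturbations with no cells get NaN p/q rather than a
spurious floor value.

Density-stratified mode reruns the full pipeline independently per
stratum against same-stratum controls. Intercellular mode restricts to
control-guide receiver cells (or a caller-designated receiver set):
"exposed to P" = ≥ 1 contact neighbor carrying P, non-exclusively — a
receiver touching carriers of P and Q contributes to both exposure
groups, so co-exposure confounding is possible and visible in the
estimates; the reference group is receivers whose neighbors carry no
known perturbation (control guides or no decoded guide are allowed).
Permutation shuffles receiver labels the same way.

An external factorize-recover estimator can be plugged in through the
`ExternalEffectEstimator` protocol (counts + design in, LFC and q tables
out); it is intentionally not re-implemented.

## Calcium phenotyping (`pfish.calcium`)

Traces are per-frame mean intensity over each registered cell mask with
the per-trace minimum of a 10-frame rolling median subtracted; no
amplitude normalization (absolute response height is informative). Peaks:
minimum height 15, prominence 6, spacing 15 frames (the higher peak wins
a spacing conflict). Seven features per cell, with 1-based frame
conventions: peak count; mean prominence; first step (max of frames 5–15
minus min of frames 1–10); first response time (1-based frame of the
first peak, 200 — the video length — when none); average peak delay (read
as the mean inter-peak interval; 0 for a single peak and the trace length
for none — the definition is not fully specified upstream, so this
reading is documented rather than inferred); AUC (trapezoidal, negative
lobes clipped so the area is comparable to transient mass — the baseline
convention is likewise ours); and an active flag (≥ 1 peak).

Features are z-scored and clustered with k-means (k = 6, 10 restarts,
fixed seed). Cluster naming is best-effort: the six canonical archetype
waveforms ("large peak", "inactive", "large early transient",
"small peak", "step", "delayed") are featurized, projected into the
data's z-score coordinates, and Hungarian-matched to the centroids; raw
labels are always retained.

Guide enrichment per cluster uses one-sided hypergeometric tails on raw
cell counts: `p_enrich = P(X ≥ x)` (the upper tail `1 − F(x−1; M, K, N)`)
and `p_deplete = P(X ≤ x)`, reported as two one-sided values rather than
one two-sided test, since enrichment and depletion are interpreted
separately. The enrichment LFC is `ln((x/N) / (K_ctrl/N_ctrl))` against
the control cells' distribution over clusters; clusters with no control
cells are flagged and carry no LFC. Cluster expression signatures are
means of per-gene z-scores of total-normalized counts, with per-gene
one-way ANOVA across clusters on raw expression.

## Panel selection (`pfish.panel`)

PCA (full SVD) is run once on the raw counts matrix — correlations also
use raw counts, for consistency with that choice. The panel is seeded
with the 2 eligible genes most correlated with PC1's scores (the
reference procedure does not state a starting set), then grows 2 genes
per iteration: regress all PC score vectors on the panel-restricted
matrix (least squares with intercept), find the PC with the lowest R²,
and add the eligible genes with the highest absolute Pearson correlation
to that PC's residual. Eligibility: per-gene FPKM ≤ 30, total panel FPKM
≤ 2,000 (genes that would break the total cap are skipped). Explained
variance per PC is non-decreasing across iterations (nested least
squares); the loop stops at the requested size, when the panel spans the
PCA space, or — with a warning and a partial panel — when the caps bind.

## The simulator (`pfish.simulate`)

The simulator emulates the features the pipeline is sensitive to, with
ground truth returned for every stage:

* **Imaging**: Gaussian spots (σ = 1.5 px, amplitude 400 over background
  100 with 15 % jitter) rendered in exactly the on-bits of each spot's
  barcode after per-bit dropout/flip corruption; identical spots in all 7
  z-planes with an amplitude falloff toward the stack ends (the decoder
  max-projects, so z structure only needs to exercise the projection); a
  multiplicative left-to-right illumination ramp shared with the returned
  background images, so flat-fielding cancels it exactly; Poisson
  spurious single-bit spots; shared fiducial beads per round. Planted
  spots carry only real-guide barcodes — blanks appear in decodes only
  through errors.
* **Screen**: cells are a jittered grid whose spacing shrinks
  left → right (sparse isolated cells on one side, contact clusters on
  the other, emulating the spontaneous density variation of cultured
  monolayers), rendered as discs into a label mask. Counts are negative
  binomial (var = μ + αμ², default α = 0.1 — counts are overdispersed
  relative to Poisson and the upstream analyses state no noise model)
  with `log μ = log baseline + intrinsic LFC + density modifier +
  Σ neighbor effects`; all planted effects are additive on the natural-log
  scale to match the LFC arithmetic, the density modifier applies only to
  the configured stratum, and a neighbor effect applies once per distinct
  perturbed-neighbor identity using the same dilation-contact rule the
  analysis uses. Control cells carry zero intrinsic effect.
* **Calcium**: traces drawn from the six archetype waveforms (the same
  canonical definitions used for cluster naming) with onset jitter (σ = 3
  frames), 10 % amplitude jitter, and i.i.d. Gaussian noise (σ = 2) at
  200 frames / 2 Hz.

Everything is deterministic under the config seed.

**What the simulator does not capture** — and hence what passing tests do
not certify about real data: optical PSF structure beyond an isotropic
Gaussian, camera noise statistics, chromatic aberration and sub-pixel
drift, segmentation errors on irregular morphologies, guide-assignment
errors correlated with expression, batch/field effects, and biological
covariance between genes (counts are independent across genes given the
planted effects). Recovery numbers on simulated screens are therefore
upper bounds on real-data performance at matched cell numbers.

## Problem sizes used in the test suite

The acceptance-style tests run at deliberately compact sizes chosen to
make their statistical targets meaningful while keeping the suite quick:
decoder exactness on 200-spot fields at ≥ 10 px separation (with an
explicit binarization threshold of 0.35 preprocessed units, chosen well
below the dimmest simulated spot peak — see the thresholding note above);
permutation-uniformity on 500 null tests × 1,000 permutations;
planted-effect recovery at 30 perturbations × 130 genes × 50
cells/perturbation with 500 controls and 2,000 permutations;
density/neighbor recovery of ln 2 effects at ~200–250 cells per arm;
calcium recovery on 600-cell mixtures.
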