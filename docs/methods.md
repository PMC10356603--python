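# Methods

This note documents the models, algorithms and numerical choices behind
`wmfish`, what the synthetic-data generator does and does not emulate, and
the known limits of each stage.

## Coordinate and data conventions

Coordinates are 0-based pixel indices in (y, x) order with pixel centers at
integer coordinates; these conventions hold in every table, mask and label
map the package reads or writes. CSVs are UTF-8, comma-separated, with a
header row and `.` decimal. Label maps use 0 for wall/background and
consecutive integers 1..n for cells; spots on label 0 are retained in the
spot table with `cell_id = -1` and excluded from all per-cell counts.
Every output table carries a 12-hex-digit hash of the analysis parameters
(output paths excluded), so a changed parameter changes the hash and
re-runs with identical parameters are byte-identical.

## Synthetic microscopy generator

The generator emulates the statistical structure of whole-mount smFISH
images of cleared plant tissue, not their optics.

**Tissue.** Cells are the Voronoi regions of seed points sampled by dart
throwing with a minimum mutual separation (0.55·√(mean cell area)); this
keeps cells from degenerating under wall dilation. Walls are the
inter-region boundaries dilated to `wall_width` (default 3 px) plus a frame
of the same width, so border cells are closed. The wall channel is
`background_level` everywhere and `background_level + wall_amplitude` on
wall pixels (defaults 10 and 100 intensity units). A tessellation is
accepted only if all n cells survive as single 4-connected components;
otherwise seeds are redrawn (deterministically from the same stream).

**Spots.** Per-cell molecule counts follow a configurable law: `fixed k`,
`Poisson(λ)`, or negative binomial parameterized as a Gamma–Poisson mixture
with mean m and dispersion r (variance m + m²/r). The negative-binomial
option exists because the per-cell count distribution family in real
tissue is not established; observed per-cell counts span roughly 1 to >50.
Spot centers are uniform over the cell interior at continuous (sub-pixel)
coordinates — a pixel is drawn uniformly and jittered by U(−0.49, 0.49) so
the center stays within that pixel — and each spot is rendered as an
isotropic 2D Gaussian of peak `spot_amplitude` (default 50) and width
`psf_sigma_xy` (default 1.5 px), sampled at pixel centers over a ±5σ
window. At σ ≥ 1.5 the discrete sum matches the analytic integral
A·2πσ² to well under 1%.

**Protein channel.** Three patterns: a filled disc at each cell's deepest
interior point (nucleus), an annulus of width 3 px around that disc
(nuclear envelope; 3 px matches the apparent width of an envelope marker
at ~0.1 µm/px confocal sampling), or a uniform cell fill at α·N_c
(reporter proportional to transcript count, α default 10). Per-cell
intensities for the first two are Normal(80, 20) clipped at 0. The
structure's support is the ground-truth mask.

**Degradation.** I.i.d. Gaussian noise (default σ 5, i.e. signal-to-noise
10 against the default spot amplitude) plus large smooth autofluorescent
blobs (Gaussians of σ 30 px, amplitude 30), clipped at 0. Blobs emulate
the out-of-focus tissue autofluorescence that plagues plant smFISH.

**Reproducibility.** One dataset seed; each channel draws from a fixed
offset of it, so toggling a channel does not perturb the others. Identical
configs give bit-identical images and truth tables.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: realistic PSFs (no Airy rings, no axial
asymmetry, no chromatic shift), channel bleed-through, uneven illumination,
probe-binding chemistry, transcription-site foci containing many molecules,
cell-type-dependent morphology, or 3D cell shape (stacks are generated as
independent planes). Results on real tissue additionally depend on
staining and clearing quality, which have no synthetic counterpart.

## Cell segmentation

Classical marker-controlled watershed, chosen over learned models because
wall-stained tissue is ridge-like and well-posed for it and because the
package ships no training data or weights. The wall channel is smoothed
(Gaussian, `smoothing_sigma` = 2 px); markers are the h-minima of the
smoothed landscape at depth `marker_h` = 5 intensity units (deep enough to
ignore smoothed noise at the default noise level, shallow enough to seed
every cell); basins are filled by watershed with 4-connectivity.

Two post-steps matter:

- **Ridge exclusion.** The watershed line is conceptual (1 px), but the
  physical wall has width. Pixels bright in a lightly smoothed wall image
  (`ridge_sigma` = 1 px, Otsu threshold) are assigned label 0, so wall
  pixels belong to no cell and spots on walls stay unassigned.
- **Fragment merging.** Spurious double markers split a cell into basins
  that touch directly; real cells are always separated by the excluded
  ridge band. Directly touching labels are therefore merged (union–find
  over the adjacency graph). This also enforces the invariant that no two
  labels touch without a 0-pixel between them.

Labels below `min_cell_area` (default 100 px²) are dropped; optional
`clear_border` removes frame-touching cells (whether partial border cells
should be quantified is a per-study decision, so both behaviors exist).
Constant images return a single label with a warning. 3D stacks are
segmented per slice with independent label maps; cross-slice cell identity
is deliberately not established.

Validation on synthetic tissue: with no noise, all 50 cells are recovered
one-to-one at IoU ≥ 0.9; at noise equal to 10% of the wall amplitude,
≥ 90% (in practice 100%) at IoU ≥ 0.7. The `match_labels` oracle pairs
predicted and true cells greedily by descending IoU, one-to-one; empty
predictions score precision 0 by convention.

## Spot detection

**Band-pass.** Scale-normalized Laplacian of Gaussian, sign-flipped so
spots are positive peaks: response = −σ²·∇²G_σ ∗ I, with σ = `psf_sigma_xy`.
The truncated discrete kernel has a tiny nonzero sum; that DC gain is
subtracted so a constant image gives exactly zero response. A matched
Gaussian blob of width σ_s under filter σ_f responds with peak
2A·σ_f²σ_s²/(σ_f²+σ_s²)², so a blob 10× the PSF width at equal height
responds at under 10% of a matched spot — this is what makes the caller
robust to autofluorescence.

**Candidates.** Strict local maxima (8-neighborhood, response > 0), then
greedy suppression by descending response to pairwise Euclidean distance
≥ `min_separation` (default 2 px; two PSFs closer than that are optically
one blob anyway). Ties break by (y, x) order; the result is deterministic
and matches an exhaustive O(n²) scan on small images.

**Automatic threshold.** The count-vs-threshold curve is computed on a
log-spaced grid of `n_threshold_grid` = 60 points. Only candidates above a
robust noise floor (2 × 1.4826 × MAD of the band-pass response) enter the
curve, and the grid is anchored at that floor: below it every noise
maximum survives and the curve is trivially flat, which would defeat any
flatness criterion. The plateau is the longest contiguous run with
|Δlog₁₀ count| < 0.02 per step; the selected threshold is the run's
midpoint. The reported plateau span is additionally trimmed to the range
where counts stay within ±5% of the midpoint count, because per-step
flatness alone tolerates slow cumulative drift over a long run. If no run
of ≥ 3 grid points exists, the curve is featureless (no noise/signal
separation) and selection falls back to Otsu on the response distribution,
flagged low-confidence. On a 500-spot scenario at SNR 10 the selected
threshold recovers the count within ±5% and the count varies ≤ 10% across
the reported plateau.

**Fits.** Each surviving candidate gets a least-squares fit of
A·exp(−r²/2s²) + B in a (2·`fit_radius`+1)² window (default 7×7);
Levenberg–Marquardt with an analytic Jacobian, initialized at the
candidate pixel with s = psf_sigma. A fit is rejected when it fails, when
the recovered width leaves [0.25σ, 4σ], when the center drifts more than
`fit_radius`, or when R² < `fit_quality_min` (default 0.5) — the last gate
is what removes noise candidates that survive a low threshold (pure noise
windows fit a Gaussian poorly). Amplitudes are background-subtracted from
the fit, robust to autofluorescence gradients. Fitted centers are
deduplicated once more at `min_separation`. Foci brighter than 5× the
median amplitude are logged (possible multi-molecule transcription-site
foci) but counted as one spot each; molecule-number decomposition is out
of scope.

Accuracy on synthetic truth: noise-free sub-pixel error ≤ 0.05 px
(median), ≤ 0.2 px at SNR 10; per-cell counts at Poisson(20), SNR 10
recover with MAE ≤ 1 and Pearson r ≥ 0.95; an RNase-like null (zero true
spots, blobs and noise on) yields ≤ 0.3 false spots per cell (in practice
~0). Stacks are detected per plane with cross-z deduplication (adjacent
planes, same (y, x) within `min_separation`, brightest plane kept) so a
molecule spanning slices is counted once.

A physical caveat the recovery numbers depend on: two molecules closer
than about 2σ are one diffraction-limited blob, so per-cell recovery
degrades with spot density. The validation scenarios use cell areas around
20,000 px² (realistic for root cells at ~0.1 µm/px); at several-fold
higher densities the undercount from merged spots dominates the error
budget regardless of the caller.

## Per-cell quantification

Spot→cell assignment takes the label under the rounded spot center — the
conventional, order-independent rule for sub-resolution objects. Counts
conserve: assigned + unassigned = detected, always. Intensities are means
and totals over each label's support; optional background correction
subtracts the median of label-0 pixels and floors the corrected per-cell
results at 0 (subtracting before summing, rather than clipping pixels,
avoids an E[max(noise,0)] ≈ 0.8σ-per-pixel bias proportional to cell
area). The log ratio uses natural log with pseudocount ε = 1 intensity
unit (16-bit scale), keeping empty cells finite and the ratio antisymmetric
under channel swap; cells with both intensities zero get exactly 0. The
RNA intensity entering the ratio is the raw channel mean by default (a
spot-reconstructed alternative would be circular with the counts).

Heatmaps paint each cell with a colormap at its value; walls are black,
cells with missing values neutral gray (logged); the colormap name and
range are emitted as JSON metadata so values can be recovered from the
render up to colormap quantization.

`verify_count_intensity_correlation` is the sanity check used before
trusting intensity-based readouts: the least-squares line and Pearson R² of
per-cell intensity vs count. On noise-free fixed-amplitude data the
per-cell total obeys I = N_c·(A·2πσ²) + background·area to within 2%
(median). With noise, the background-corrected total tracks the detected
count at R² ≥ 0.9 when counts span a realistic dynamic range
(negative-binomial, roughly 1–50 per cell); over a narrow count range
(e.g. fixed Poisson(20), cv 0.22) the correlation is intrinsically limited
by measurement noise — a property of the experiment, not the code. Large
autofluorescent blobs destroy raw intensity–count correlation entirely,
which is precisely why the pipeline counts spots instead of integrating
intensity.

## Colocalization

The protein structure is segmented by smoothing (σ = 0.5 px — wide enough
to suppress pixel noise, narrow enough not to inflate a 3-px envelope),
thresholding (Otsu within the cell area by default; percentile and fixed
alternatives), removing components below `min_mask_area`, and restricting
to cell pixels. A spot is colocalized when the pixel under its rounded
center is mask, or when its sub-pixel center is within `tolerance_radius`
(default 1 px ≈ localization precision) of a mask pixel, measured on the
Euclidean distance transform interpolated at the spot center. This
object-based count-in-structure statistic was chosen over pixelwise
intensity correlation because the question is "how many molecules are at
the structure", not "do the channels covary".

Per cell, F_c = K_c/N_c; cells with no spots are excluded from group
summaries (logged). F_c is monotone in the tolerance radius. A
uniform-placement null utility re-places N_c points uniformly per cell and
reports the chance-level fraction (≈ per-cell mask-area fraction at zero
tolerance, verified unbiased within 3 s.e. over 200 cells); enrichment
over this null is the recommended effect measure when no control
transcript is available.

On the two-population validation scenario (97 cells at true p = 0.45, 141
cells at p = 0.29, mirroring an envelope-targeted vs a cytoplasmic
transcript), recovered group means land within ±0.05 of truth and Welch's
test separates the groups at p < 0.001. The residual ~0.02 downward bias
at high p comes from two physical effects: Otsu segmentation slightly
erodes the mask edge, and colocalized spots concentrated in the ring are
more likely to merge optically.

## Statistics

Cells are the statistical unit, as in per-cell imaging studies; n_images
is always reported next to n_cells so nesting (pseudo-replication) stays
visible, but no mixed-model correction is imposed. Quantiles use linear
interpolation; box whiskers are Q1 − 1.58·IQR and Q3 + 1.58·IQR clipped to
the data range; KDE bandwidth follows Silverman's rule. Input order does
not affect summaries (values are sorted first).

Pearson r uses the exact t transform for its p-value. The two-sample test
is Welch's by default (per-cell variances differ across genes and
conditions); the pooled variant is available via `equal_var=True`. One-way
ANOVA is the classical F test; pairwise comparisons use Tukey's HSD via
the studentized range distribution. One-sided Tukey p-values halve the
tail in the caller-specified direction (and report 1 − p/2 against it);
the direction must be supplied explicitly because it is experimental
context, not a formula. In the two-group limit Tukey's p equals the pooled
t-test p (q = √2·|t|), which the tests verify against a direct-formula
oracle; the global ANOVA type-I error is calibrated at 5% ± 1.5% over
1,000 null replicates. No multiple-testing control beyond Tukey is
applied.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use: 100 cells on 1448² px for
count recovery; 100 cells on 724² for the RNase null; 97/141 cells on
1448²/1736² for colocalization; 50 cells on 512² for segmentation; 20
cells on 448² for coherence; 500 spots on 800² for threshold stability;
100 isolated spots for localization; 1,000 replicates at n = 10 × 3 groups
for ANOVA calibration; 200 cells on 1024² for the colocalization null.
These sizes give each scenario enough statistical resolution for its
acceptance band while keeping a full run in the low minutes on one CPU.

## Known limitations

- Per-slice 2D quantification: no 3D cell reconstruction, no cell-volume
  normalization of counts; a molecule's z-extent is handled only by
  cross-plane deduplication.
- Bright multi-molecule foci count as one spot; absolute counts
  underestimate nascent transcription sites.
- The watershed assumes ridge-like walls; tissue with weak or broken wall
  staining will need the marker depth and smoothing tuned, and may favor a
  learned segmenter outside this package's scope.
- The plateau threshold assumes some separation between noise and signal
  responses; at SNR ≲ 3 the fallback path (Otsu, low-confidence flag)
  triggers and counts should be treated with caution.
- Group tests treat cells as independent; cells within a root/image are
  correlated, so p-values on heavily nested designs are optimistic.
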