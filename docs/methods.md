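# Methods

This note documents the models and procedures ciliadyn implements, the
parameters that matter and their defaults, the synthetic-data model used to
validate them, and the numerical choices made where the design was open.

## Coordinate, unit and angle conventions

Images are stored `(channel, z, y, x)`, 0-based, pixel-center, x rightward
and y downward. All lengths are micrometres, times seconds, angles degrees
in [0, 360). Angles are measured counterclockwise from +x in a y-up
mathematical frame; the flip from image storage to the mathematical frame
happens exactly once, when a stored base→tip pair is converted to an angle
(`polarity.vector_angle_image`). Angles are treated as directional (full
360°), not axial: rootlet and basal-body displacement vectors have a
defined head.

The camera pixel size is deliberately never defaulted: it must come from
TIFF resolution metadata or be passed explicitly, since every length the
pipeline reports scales with it.

## Cilium detection and length measurement

The per-field procedure is: z maximum projection of the centrosome channel;
spot detection; an 11 × 11 µm peri-centrosomal crop of the projected
axoneme channel; proximal-cluster seeding; contrast-guarded region growing;
skeleton length.

Parameters (all in `imgio.Config`, defaults chosen once against the
synthetic model below and exposed for per-microscope calibration):

| parameter | default | role |
|---|---|---|
| `spot_sigma_px` | 2 px | DoG band-pass scale ≈ spot radius |
| `min_peak_snr` | 5 | peak threshold in robust sd units (median + k·1.4826·MAD of the DoG image) |
| `min_separation_px` | 5 px | non-maximum suppression radius; brighter spot wins, ties to smaller (y, x) |
| `crop_side_um` | 11 µm | crop side, forced to an odd pixel count so the spot is the exact centre pixel |
| `seed_quantile` | 0.99 | crop-intensity quantile for the proximal-cluster threshold |
| `min_seed_px` | 4 px | minimum seed component area |
| `contrast_stop_ratio` | 1.5 | growth admits border pixels with intensity ≥ ratio × local background median |
| `min_cilium_length_um` | 1 µm | ciliation call |

Notes on the less obvious choices:

* **Growth stop criterion.** "Contrast" is defined as pixel intensity
  relative to the median of crop pixels outside the current mask dilated by
  2 px, re-estimated every iteration; growth continues while admitted
  pixels keep contrast ≥ `contrast_stop_ratio` and stops when no 8-connected
  border pixel qualifies (or after `max_grow_iterations`). The returned
  mask always contains the seed.
* **Length.** The mask is thinned to a 1-px skeleton; length is the longest
  geodesic (shortest-path) distance between any two skeleton pixels with
  step costs 1 (axial) and √2 (diagonal), times the pixel size. An empty
  mask scores 0. This is exact (all-pairs Dijkstra), affordable because
  masks live in ≤ ~45 px crops.
* **Scale invariance, not shift invariance.** The quantile seed threshold
  and the ratio growth criterion make the ciliation call invariant under
  positive rescaling of intensities (a·I, a > 0); an additive offset b
  shifts the effective growth threshold by b(ratio−1) and is not exactly
  neutral. Offset-corrected input (standard for fluorescence) is assumed.
* One cilium per centrosome; overlapping crops are processed independently,
  with no deduplication — the procedure is per-centrosome, not per-cell.

Time courses pool replicate fields per condition × timepoint: mean and
s.e.m. (sample sd/√n; reported missing for n = 1) of %ciliated, and a
two-sided Welch (unequal-variance) t-test of each condition against the
named control at each timepoint, skipped with a warning when either side
has a single replicate.

## Circular statistics for polarity

For angles θᵢ, with C = mean cos θ and S = mean sin θ, R = √(C² + S²):

* circular mean = atan2(S, C), flagged undefined when R < 10⁻¹²
  (e.g. antipodal pairs);
* CSD = √(−2 ln R), converted to degrees — the Mardia/Fisher circular
  standard deviation, not the angular deviation √(2(1−R)); R → 0 gives +∞;
* normalization: θ′ = (θ − circular mean + 90°) mod 360, so every group's
  display distribution is centred at 90°. The "average angle" subtracted is
  the *circular* mean: an arithmetic mean of angles is ill-defined under
  wraparound, and only the circular mean makes the re-centred mean exactly
  90° for every group.

Rotational polarity groups vectors per cell (cells with one vector are
excluded with a warning); a condition is mean ± s.d. of per-cell CSDs.
Translational polarity computes one BBOV per cell — from the cell polygon's
uniform-area (shoelace) centroid to the unweighted pixel centroid of the
basal-body patch — and groups BBOVs per field of view; a condition is
mean ± s.d. of per-field CSDs. The BB patch is the largest 8-connected
component above a local-mean adaptive threshold (window 51 px, offset 0 by
default; both exposed) inside the traced ROI. Intensity weighting of the
patch centroid is deliberately not used.

Conditions are compared with a two-sided Mann–Whitney U test on the
per-group CSDs: the exact permutation distribution when min(n₁, n₂) ≤ 8
and the pooled sample is tie-free, otherwise the normal approximation with
tie and continuity corrections (delegated to scipy; an independent
full-enumeration oracle in the test suite checks every tie-free rank
arrangement up to 6 per group). Rose-plot histograms use 24 equal bins over
[0, 360), left-closed, so a boundary angle falls in the right-hand bin.

## Bead flow

Linking is greedy mutual-nearest-neighbour between consecutive frames
within `max_disp_um`, closest pairs first; unmatched detections start new
tracks, and a bead that disappears ends its track (a later reappearance is
a new id). Velocity is *path length / elapsed time* — not net displacement
over time — so that velocity and tortuosity (path/chord) stay independent
readouts of speed and directionality; this choice is recorded in the output
metadata of the CLI. Tracks with net displacement below
`min_net_disp_um` (default 0.1 µm) are excluded as non-motile, since the
chord ratio diverges for closed loops. The default frame interval is
1/37 s; acquisition descriptions vary between 37 and 30 frames per second,
so the interval is always an explicit parameter and never inferred.

## Interaction-screen filter

A prey is a hit when its luminescence intensity ratio is ≥ 3 (inclusive) in
*both* biological replicates. Computation of the ratio itself (the assay's
internal normalization) is out of scope — the table is input. Rows with a
NaN ratio are rejected with a warning; raising the threshold can only
remove hits (monotonicity, property-tested). No multiple-testing machinery
is applied.

## Synthetic-data model

`synthdata` exists so that every stage can be validated by parameter
recovery without any external download.

**Fields.** Centrosome positions are uniform with a minimum pairwise
separation equal to the crop side (11 µm) so crops never collide
(`crowded=True` disables this for stress tests); exactly
round(fraction × n) of them are ciliated. Each axoneme is a polyline of
exact arc length (uniform in 2–6 µm by default) built from 0.1 µm steps
whose heading drifts by at most `cilium_curvature` (0.3 rad/µm) per µm,
rasterized 1 px wide, dilated to ~3 px and lightly blurred (σ 0.7 px) —
thin curved filaments without modelling full optics. Spots are Gaussian
(σ 2 px, amplitude 300). Signal spreads over z (10 planes by default) with
a Gaussian axial profile; each plane receives Poisson noise on
signal + background (background 20 counts) plus Gaussian read noise
(sd 2) — the standard fluorescence camera model. These intensities define
the "moderate SNR" regime all recovery statements refer to: axoneme pixels
sit ≈ 5× above background, i.e. ≈ 8 shot-noise sd.

**What the generator does not emulate:** out-of-focal-plane axoneme
geometry, PSF physics and deconvolution artefacts, photobleaching,
cell-to-cell intensity variation, cytoplasmic background structure, and
touching/overlapping cilia (unless `crowded`). Passing recovery tests
therefore demonstrates correctness of the measurement logic under the
stated noise model, not robustness to every real-microscope artefact; on
real data the Config thresholds are the calibration surface.

**Vectors, tracks, screens.** Orientation vectors draw per-cell mean
directions (global mean + normal spread), then von Mises angles at
concentration κ (κ = 0 is uniform); bases sit on a jittered grid with unit
tips, stored in image coordinates so a CSV round trip reproduces the drawn
angles exactly. Bead tracks are fixed-heading drift (speed × interval per
frame) plus isotropic Gaussian jitter. Screen tables draw exactly
`n_true_hits` preys from a hit range lying entirely ≥ 3 and the rest from a
null range entirely < 3. All generators are pure functions of
(parameters, seed).

## Validation problem sizes

The recovery suite runs fields of 100 centrosomes (768² px at 0.25 µm/px,
10 z-planes) for detection (fractions 0.2/0.5/0.8, 5 seeds) and length
recovery (200 straight cilia), and a 40-field disassembly series
(two conditions × five timepoints × four replicate fields of 60
centrosomes) for the end-to-end time course; circular statistics are
checked at n = 10⁴ against the von Mises closed form
CSD = √(−2 ln(I₁(κ)/I₀(κ))), and tortuosity on 10⁴ random walks. These
sizes give per-field binomial noise of ~2–5 percentage points, well inside
the ±5-point recovery target, while keeping the whole suite at desk scale.
Observed performance under the default model: detection error ≤ ~2
percentage points per field, length mean absolute error ≈ 0.35–0.4 µm
(dominated by skeleton end-trimming vs the 3-px filament width at
0.25 µm/px).

## Known limitations

* Detection operates on z-projections; axonemes rising steeply out of
  plane are foreshortened (2D length is a lower bound).
* A cilium whose tip leaves the 11 µm crop is truncated at the crop edge;
  with 2–6 µm cilia this affects only the longest, most eccentric ones.
* The ratio-based growth criterion assumes offset-free intensities (see
  above); acquisitions with a large camera offset should be
  background-subtracted first.
* The Mann–Whitney exact branch requires a tie-free pooled sample; heavily
  discretized CSDs fall back to the corrected normal approximation.
* Track linking is greedy frame-to-frame; it does not bridge detection
  gaps and will fragment tracks under heavy dropout.
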