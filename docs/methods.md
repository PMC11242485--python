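# Methods

`goldx` removes gold fiducial markers from cryo-electron-tomography tilt
series before reconstruction. Gold beads (5–15 nm) are added to vitrified
samples as alignment fiducials; their extreme electron density makes them by
far the highest-contrast objects in the images, and because reconstructions
are computed from an incomplete ±60° projection set, each bead seeds
non-local missing-wedge streaks that corrupt nearby densities. Masking the
beads with uniform disks removes the bead but introduces a new high-contrast
texture border, which streaks in turn. The approach here is to detect each
bead in every 2D tilt image independently, segment its exact shape, expand
the mask over the bright defocus halo, and replace the masked pixels with a
patch of real background from the same image, rescaled so its first two
moments match the immediate surroundings. Everything happens in 2D on the
tilt images; reconstruction is out of scope.

## Detection: reduced template

A bead in a defocused bright-field image is a dark disk surrounded by a
bright first defocus fringe. The detector represents this structure as a
*reduced template*: a point set rather than a dense image — a full disk of
inner points of radius `r_in` (the bead) and a thin ring of outer points at
the halo radius, with an excluded gap annulus between them that absorbs
bead-to-bead size and shape variation. Scaling is fixed by the two required
physical inputs:

    r_in = scale * (bead_diameter_nm * 10 / pixel_size_A) / 2

with ring geometry `r_gap = 1.3 r_in`, thickness `max(1, round(0.2 r_in))`,
and nominal outer extent `r_out = 1.6 r_in`. These ratios put the ring just
outside a typical first fringe at the pixel sizes this tool targets
(≈2–5 Å/px); they are exposed for tuning but are not per-dataset knobs.
Template weights are signs only (−1 inner, +1 outer); the score
normalization makes graded weights redundant. Beads whose radius falls below
1.5 px are rejected: a bead spanning fewer than 3 pixels has no interior /
ring structure to detect.

The score at each position is the outer-minus-inner mean contrast divided by
the local standard deviation over the template support, floored at
`1e-6 ×` the global image SD. Local normalization is what makes one
threshold work from 0° to 60° tilt, where absolute contrast drops roughly
with `cos θ`. The map is computed by FFT correlation after subtracting the
image mean; the score is invariant to intensity offsets and positive gain
(both hold to rounding). Border positions
where the template exits the image are set to the valid minimum and excluded
from statistics.

The score map is thresholded at `mean + 5 SD` of its valid values. The
threshold is expressed in score-map SDs so it transfers across datasets; 5
is conservative enough that bead-free noise images essentially never fire
(the suite requires ≤ 0.05 detections per blank 512×512 image; the measured
rate is 0). The binary map is eroded with a radius-1 discrete disk — the
smallest element that deletes single-pixel spurious peaks without shrinking
true components below detectability. Each surviving 8-connected component
yields one marker at its score maximum (ties to the smallest `(y, x)`);
8-connectivity avoids splitting the diagonal pixelation of round peaks, and
the maximum is preferred over the centroid because post-erosion residues can
be crescent-shaped. Markers are labeled 1..N by decreasing score.

## Segmentation: marker-based watershed

Markers seed a watershed flood of the intensity landscape itself (dark beads
are basins), not of a gradient image — gradients on noisy cryo data would
not recover the bead's "exact shape". The surface is first blurred with a
Gaussian of scale `r_in / 8` (skipped for beads under 4 px radius). A
heavier blur was evaluated and rejected: at `r_in / 4` the smoothed halo
crest — the ridge that bounds each basin — moves visibly outward and every
mask inflates (mean IoU against true footprints drops from 0.80 to 0.70 on
the synthetic fixtures).

The background seed is constructed from image statistics alone, keeping the
step parameter-free: a pixel seeds the background catchment if it is (a) not
bead-dark — within 2 robust SDs (1.4826×MAD) of the smoothed median — and
(b) farther than `2 r_out` from every marker and from every certainly-dark
core pixel (4 robust SDs below the median). Rule (a) deliberately places
seeds inside ordinary dark texture patches; requiring seeds to be brighter
than the median was evaluated and rejected because a dark low-frequency
blob adjacent to a bead then contains no seed and drains wholesale into the
bead's basin. Rule (b)'s core-anchored exclusion protects the dim rim of a
long bead aggregate whose only marker is far away. A single marker on a
touching cluster floods the entire connected dark region, so aggregated
fiducials are segmented as long as one border bead is detected. Marker
pixels are seeded last, so every marker always owns its label; a marker
landing on background-like brightness is reported as a warning rather than
silently dropped.

Masks are then dilated by a discrete disk to cover the halo; the default
radius `max(3, round(r_gap − r_in) + 2)` is generous by design so the whole
fringe is included. Contested pixels between nearby masks go to the nearest
original region (ties to the lower label), so dilated regions remain
disjoint labels rather than merging into one replacement unit.

## Replacement: statistics-matched background patches

One featureless square block is selected per tilt image: 50 random mask-free
positions are drawn (rejection-sampled against the dilated masks) and the
one with the lowest RMS deviation about its mean wins. Per-tilt selection —
rather than one global block — follows the contrast drift across the
series. The automatic side length is 8 bead footprints (`8 × 2 r_out`,
floored at 64 px, capped at half the smaller image dimension) so that
patches drawn from it are mutually uncorrelated; when no mask-free square of
that size exists (a real possibility on small, bead-crowded images) the side
shrinks in ×0.8 steps, never below two footprints or the largest region's
bounding box, and each shrink is recorded in the run report. An explicitly
requested side is never shrunk — it errors instead, naming the tilt.

Each fiducial gets its own patch: one of the 8 dihedral transforms of the
block, chosen uniformly, then a uniformly random window of the region's
bounding-box size. The patch is rescaled affinely,

    out = (patch − mean(patch)) * target_rms / rms(patch) + target_mean,

to the mean and RMS deviation of the ring of background pixels within 3 px
of the dilated mask (excluding all masks, clipped at borders; if the ring is
empty the block's own statistics are the fallback). "RMS deviation" is the
population SD throughout, for both flatness ranking and rescaling. The
match is exact to rounding (`1e-6` relative is asserted). Finally the
patch is written into the mask pixels only: every pixel outside the dilated
masks is bit-identical to the input, which the tests assert by array
equality. A flat patch (RMS < 1e-12) cannot reach a nonzero target RMS and
is inserted as a constant with a warning.

Randomness discipline: one master seed; the background draw for tilt `t`
uses substream `(seed, t, 0)` and the patch for fiducial `k` of tilt `t`
uses `(seed, t, 1, k)` (numpy `SeedSequence`). Results are therefore
bit-reproducible and independent of the order in which tilts are processed.

## Synthetic data

The generator renders the features the pipeline contracts on and nothing
more. Background: white Gaussian noise of SD `noise_sd` plus a smooth random
field (Gaussian-filtered noise, correlation length one tenth of the image)
scaled to `texture_amplitude` noise-SD units — weak texture as on ice/thin
carbon. Each bead: an intensity deficit `depth · exp(−(r/r0)⁴)` (a quartic
super-Gaussian: flat core, fast edge) plus a bright ring
`halo · exp(−((r − 1.3 r0)/(0.25 r0))²)`. Both amplitudes are in noise-SD
units and are multiplied by `cos θ` per tilt to model contrast loss at high
tilt. Geometry: tilt axis along y, so a bead at `(x, y, z)` (pixels,
relative to the volume center) projects to column `x cos θ + z sin θ`.

Defaults are the study conditions used throughout the tests: 512×512 images
at 4.59 Å/px with 10 nm beads (r0 ≈ 10.9 px), depth 10, halo 3, texture 0.5,
and, for multi-tilt fixtures, 9 tilts from −60° to +60°. Depth 10 reflects
the reality that beads are by far the strongest-contrast objects in such
images; texture 0.5 makes the background weakly structured without creating
bead-like features.

Ground-truth masks are the bead's *imaged footprint*: the disk on which the
rendered deficit exceeds one noise SD, radius `r0 · ln(depth·cosθ)^{1/4}`
(≈ 1.23 r0 at the defaults). This, rather than the disk of nominal radius
`r0`, is the correct segmentation target: the quartic profile is visibly
dark well beyond `r0`, and a watershed bounded by the halo ridge at
≈ 1.3 r0 recovers precisely that footprint. Against the nominal disk the
geometric ceiling on IoU would be ≈ (1/1.3)² ≈ 0.6 no matter how good the
segmentation — a property of the mask definition, not of the method.

What the generator does **not** model: CTF oscillations, projection
thickness, bead elongation or overlap changes at high tilt, membranes/VLPs
or other strong biological features, detector artifacts, and alignment
errors. Passing the suite therefore demonstrates the detection, shape
segmentation, locality, statistics-matching and reproducibility contracts —
not performance on crowded cellular scenes, where the threshold, scale
factor and dilation radius exist to be tuned (typically on the zero and
maximal tilt only, two or three iterations).

## Numerical choices and degenerate inputs

* Score map: float64 FFT correlation; variance clamped at 0; local SD
  floored at `1e-6 ×` global SD; a constant image yields an all-zero map.
* Thresholding uses a strict inequality, so a degenerate constant score map
  produces no detections.
* Erosion/dilation disks are Euclidean (`dy² + dx² ≤ r²`); erosion treats
  out-of-image pixels as background.
* All tie-breaks are deterministic: lexicographic `(y, x)` within a
  component, lower label for contested dilation pixels, first-drawn
  candidate for equal background RMSD.
* Cleaned stacks are written as 32-bit float MRC2014 regardless of input
  mode, to avoid quantizing rescaled patches; pixel size is carried in the
  header.
* Problem sizes in the test suite and acceptance script (20 scenes per
  detection condition, 100 blank images, 9-tilt × 12-bead erasure scenes)
  keep full runs in the minutes range on one CPU while leaving every rate
  estimated from hundreds of events.

## Known limitations

* Detection assumes round beads with halos; rod-shaped contamination or
  ice crystals may be missed (by design — they are not fiducials).
* Very low-contrast beads at high tilt in thick samples may require raising
  `scale_factor` or lowering `threshold_sd`; the defaults favor zero false
  positives over perfect recall.
* Each tilt is processed independently (the tool is tracking-free); a bead
  missed on one tilt is simply left in place on that tilt.
* Dilated masks of adjacent beads stay separate labels; merged replacement
  of near-touching halos is a possible variant not implemented.
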