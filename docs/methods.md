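# Methods

## Array model

A membrane is a `n_block_rows × n_block_cols` lattice of 3×3 blocks with
center-to-center pitch `block_pitch` (default 36 px) and within-block spot
pitch `spot_pitch` (default 12 px). Position 0 of every block is the central
ink guide dot (radius 6 px); the 8 peripheral positions hold protein spots
(radius 4 px). Each block carries 4 clones spotted in duplicate; the default
pairing puts a clone's two replicates point-symmetric about the block center
(position *p* pairs with *9 − p*), the convention of classical filter
arrays, and is configurable through `duplicate_map`. The full-size default
design is 50×40 blocks = 8000 distinct clones, the scale of a commercial
high-density expression filter (>7000 distinct proteins). Membrane
dimensions, pitches and radii are free parameters of this implementation,
not properties of any particular commercial filter; the defaults were chosen
so that spots are well separated (spot radius < half the spot pitch) yet the
full membrane stays a few megapixels.

Pixel coordinates are 0-based `(row, col)`, origin top-left; block indices
are 1-based.

## Synthetic scans

`simulate_image` renders one probe channel as
`background_level + gradient·(row, col) + N(0, pixel_noise_sd²)` per pixel,
plus uniform disks: guide dots at a fixed amplitude of 5× the background
level (so they are detectable regardless of probe binding), and each
replicate spot of a clone at `strength × f`, with `f` lognormal with mean 1
and coefficient of variation `spot_cv`. A multiplicative lognormal is used
because scanned chemiluminescence/fluorescence spot intensities are
nonnegative and right-skewed. Deposits listed in `failed_spots` are
suppressed — the mechanism behind clones "detected only once" in duplex —
and `artifact_spots` add channel-specific smears at arbitrary positions.
Defaults: background 100, gradient 0.02 units/px per axis, pixel noise SD 4,
spot CV 0.1. The demo scenario uses binder strength 24 (≈6× the pixel noise
SD, i.e. a clearly detectable binder), and the recovery study uses strength
5× the pixel noise SD, the weakest signal class the hit caller is expected
to recover reliably.

An optional affine transform is applied to all spot centers at render time
to emulate scanned translation/rotation/scale; disk radii are not scaled
(scale perturbations studied are within ±2%, below the pixel grid's
resolution of a radius change). The generator does not model optical
point-spread functions, membrane warping beyond affine, saturation clipping
or multi-channel color — so passing recovery tests demonstrate correctness
of the geometry, statistics and filtering logic, not robustness to optics
effects absent from the model. Images are deterministic given (design,
truth, noise model, channel): the RNG is seeded from the noise seed plus a
CRC of the channel label, so the two channels of one membrane get
independent but reproducible noise.

## Grid registration

Guide dots are segmented by thresholding at `median + k·(1.4826·MAD)` of the
whole image (k = 5) and labelling connected components; components with area
within [0.5, 2]× the nominal dot area are kept — protein spots (radius 4 vs
dot radius 6) fall below the lower bound — and each contributes its
background-subtracted intensity-weighted centroid. Fewer than 3 dots is a
registration failure.

The fit is a 6-parameter affine (flat-scanned membranes show translation,
rotation and mild scale only; affine keeps the least-squares problem
closed-form). Correspondence is established in two rounds: (1) the rotation
angle and lattice pitch are estimated from nearest-neighbour displacement
statistics (angles folded to [−45°, 45°)), dots are de-rotated and rounded
to lattice indices anchored at the grid median — the median anchor keeps a
few displaced dots from shifting the whole indexing; (2) after a first fit,
every dot is re-matched to its nearest predicted lattice node (ties: nearest
wins). Both rounds end with an iteratively reweighted least-squares fit
using Tukey's biweight (c = 4.685σ, σ the MAD of residual norms floored at
0.5 px so sub-pixel inlier scatter does not shrink the rejection window to
nothing); dots ending with weight ≈ 0 are excluded from `n_dots_used` and
the reported residual RMS. Collinear dot sets (e.g. a single block row)
raise a degenerate-fit error rather than returning an unusable transform.

## Spot quantification

For each located clone spot: `raw` is the median of pixels within the spot
radius of the (affine-mapped) center; the background annulus spans
[radius + 2, radius + 6] px, excluding pixels inside any other spot or guide
dot disk; `background` is the annulus median and `spread` 1.4826×MAD floored
at 1e-6 intensity units (the floor keeps z finite on noiseless synthetic
images). Median/MAD statistics were chosen over mean/SD because single
smears or dust specks are common on filter membranes. The z-score
`(raw − background)/spread` is invariant to adding a constant to the image
and to positive rescaling.

Fewer than 20 usable annulus pixels triggers a `low_pixel_count` flag and a
fallback to the global background (median/MAD of all non-spot pixels). A
spot whose disk is ≥10% at the image's representable maximum (known only
for integer scans) is flagged `saturated`; a spot center outside the image
is flagged `out_of_bounds` and not measured. No inter-spot, print-tip or
block normalisation is applied: ranking is raw intensity over local
background only.

## Hit calling

Per clone, the replicate z-scores are averaged (mean, not max or min: max
would let one bright smear defeat the duplicate rule, min discards ranking
information). Any flagged or absent replicate counts as missing; a clone
with no usable replicate gets a NaN score and can never be a hit. The
filters:

* **replicate consistency** — both replicates present and each z ≥ z_min
  (default 3, ≈3σ over local background; exposed as a config/CLI
  parameter). Detection is per spot, so a clone seen at only one of its two
  spots is omitted regardless of how bright that one spot is.
* **dual-format intersection** — only clones in both channels' hit lists
  survive; the cross-channel score is the mean of the two per-channel
  combined scores.

Lists are sorted by combined score descending with ties broken
lexicographically on clone id, making output byte-stable across reruns.

## Problem sizes and numerical choices

The packaged demo scenario uses a 10×10-block membrane (400 clones, 372²-px
images); the registration study uses 10 such membranes with random poses
(rotation ≤ 3°, scale 0.98–1.02, shift ≤ 30 px) and 5% of guide dots
displaced by 20 px; the recovery study uses 20 8×8-block membranes with 12
binders each, one failed null-clone deposit and one artifact smear per
array. These sizes give stable recovery statistics (240 binder decisions,
~4900 null decisions) while the whole acceptance computation stays under
ten seconds on one core.

Known limitations: no non-rigid dewarping, no spatial smoothing or
batch/array normalisation, no p-value machinery (the pipeline ranks, it
does not test), and clone-id→protein annotation is outside the pipeline.
The phage-titer utility implements the standard spectrophotometric formula
`(A269 − A320) × 6·10¹⁶ / genome_length` particles/mL; the genome length is
an explicit input since phagemid particles package vector-dependent genomes.
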