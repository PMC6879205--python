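# Methods

This note records the models, parameter choices and numerical decisions
behind `ribbonquant`, and what its synthetic phantoms do and do not emulate.

## Punctum segmentation (`puncta`)

Pipeline per channel: per-slice rolling-ball background subtraction →
(PSD channel only) difference-of-Gaussians band-pass → per-stack min–max
normalization → threshold → seeded 3D watershed → per-label measurement.

**Rolling ball.** The background of each (y, x) slice is the grayscale
opening with a ball structuring element (`skimage.restoration.rolling_ball`).
The radius is not dictated by the original workflow; the default is 50 px,
large relative to puncta (≤ ~10 px across) so punctum intensity is preserved
(verified to 5% against the explicit opening on test blobs). For radii ≥ 16
on slices larger than ~16× the shrink factor the image is downscaled by
`radius // 8`, the ball rolled on the shrunken image, and the background
bilinearly upsampled — the standard large-radius speed-up; the background is
smooth at that scale, so the approximation error is far below the shot noise
of any real acquisition. Small images always use the exact algorithm.

**Band-pass.** The 6–20 px band is realized as a difference of Gaussians
with σ = size/2.355 (FWHM convention). The response to a Gaussian blob of
lateral σ_b has the closed form amp·[σ_b²/(σ_b²+σ_s²) − σ_b²/(σ_b²+σ_l²)],
which the tests use as the oracle. Only the band edges are fixed by the
source workflow; the kernel shape (FFT vs DoG) is a package choice.

**Threshold.** Default Otsu on the normalized stack (parameter-free,
scale-invariant); an absolute threshold in (0, 1) on the normalized copy is
available — 0.5 equals the half-max isophote for a single blob and is what
the area round-trip tests use. Normalization is per stack, not per slice,
so axial intensity profiles stay comparable.

**Watershed.** Local maxima of the smoothed normalized stack seed a
watershed on the inverted intensity restricted to the binary mask. The
suppression radius around maxima (`maxima_min_distance`, default 5 lateral
px ≈ 0.25 µm) is enforced in *physical* units: the voxel footprint is scaled
per axis (a 0.3 µm z-step counts 6× a 0.05 µm lateral pixel), otherwise
axially adjacent puncta are spuriously merged. Degenerate plateaus with no
detectable maxima fall back to plain connected components.

**Measurement.** Projected area is each 3D label's max-projection footprint
(per label, so objects overlapping only in projection keep separate
footprints) times the pixel area; integrated intensity is summed over that
footprint on the max projection of the background-subtracted, *non*-normalized
stack; centroids are unweighted voxel centroids scaled by the anisotropic
voxel size (0-based indices). The minimum-area filter (ribbon 0.08 µm²,
PSD 0.04 µm²) is inclusive at the boundary and is skipped for extrasynaptic
counting.

## Pairing (`pairing`)

Candidates are all (ribbon, PSD) pairs with 3D centroid distance ≤ the
radius-sum threshold computed from the two projected areas; matching is
greedy in ascending distance, ties broken by (ribbon id, PSD id), strictly
one-to-one — when several PSDs are reachable the nearest wins, reflecting
the idea that a ribbon has a single postsynaptic partner. Distances are 3D
physical µm while radii come from 2D projected areas; this deliberate
mixture mirrors the quantification convention being reproduced.
`proximity_summary` uses a strict `<` cutoff and reports the percent rounded
to the nearest integer plus the median of the within-cutoff subset.

## Trace analysis (`traces`)

**Registration.** Frame drift is estimated as integer-pixel translation by
FFT cross-correlation against the first frame (rotation is out of scope;
the fixtures contain none). Constant frames tie-break to zero shift.

**Evoked.** F₀ = mean over the pre-stimulus window; the peak is taken over
the whole post-baseline record (stimulus and recovery), the more
conservative of the two possible readings. Activity thresholds are strict
(`>`), so a peak exactly at 0.25 / 0.05 is inactive.

**Bleach correction.** A·exp(−t/τ)+C is fitted with up to three rounds of
masking points more than 2 robust SD (1.4826·MAD) above the fit, so positive
transients do not bias the decay estimate; the trace is divided by the fit
normalized to t = 0, which preserves ΔF/F₀ ratios. If the fit degenerates
the correction is a flagged no-op, never a silent one. Flat traces change
by < 1%.

**Spontaneous.** F₀ is the 15th-percentile *value* of the trace (linear
interpolation); the alternative reading — mean of the lowest 15% of samples —
is available via `baseline_mode="mean_lowest"`. ΔF/F₀ below the 10% noise
floor is zeroed before both the magnitude integral and peak detection. The
magnitude divisor is the recording's frame count (300 for 900 s at 0.33 Hz),
generalizing the fixed 300. Peaks are local maxima of the thresholded trace
with ≥ 3 frames separation and prominence ≥ the noise threshold — at the
0.33/0.2 Hz rates used, one count per physiological event.

**4PL fit.** IC₅₀ is fitted in log space (always positive); initial values
come from the responses at the dose extremes and the positive dose nearest
the midpoint crossing. Dose 0 is handled by the closed-form top limit. Flat
response sets and non-convergence are reported as failed fits with messages.

## Synthetic phantoms (`synthdata`)

**Images.** Puncta are anisotropic 3D Gaussians; the lateral σ is calibrated
so the half-max projected footprint equals the sampled true area
(σ = √(A / 2π ln 2)), and σ_z = 3 σ_lateral approximates the axial elongation
of a high-NA confocal volume. Default sampling is 0.05 µm lateral / 0.3 µm
axial; the acquisition pixel pitch was not recorded in the source workflow,
so this Airyscan-like value is a package default, chosen so the 6–20 px
band-pass brackets the rendered punctum sizes, and is configurable.
Ribbon–PSD gaps are Gaussian (0.15 ± 0.05 µm); the paired count is exactly
round(paired_fraction × n). Centers are placed by rejection sampling with a
minimum separation of 1 µm measured in resolution units (axial distance
divided by the elongation factor), i.e. phantom puncta are optically
resolvable — two real ribbons stacked 1 µm apart along the optical axis
would merge into one blob for *any* segmentation, which is a property of the
optics, not of the algorithm under test. Background is a constant plus a
planar gradient; shot noise is Poisson at the configured gain (peak
intensity 100 at unit gain ⇒ peak SNR 10) applied before Gaussian read
noise. Channel 3 duplicates each ribbon blob scaled by
`channel3_coefficient`.

Not emulated: PSF convolution and Airyscan reconstruction, cell bodies and
membranes, autofluorescence structure, axial background gradients, punctum
shape irregularity. Passing recovery tests therefore demonstrates the
correctness of the segmentation/pairing logic under realistic geometry and
detector noise — not robustness to optical aberrations or labeling
variability in real tissue.

**Traces.** Events are difference-of-exponentials kernels normalized to
peak 1: rise 0.06 s / decay 3 s for the fast cytosolic channel (return to
baseline ≈ 12 s), rise 0.6 s / decay 75 s for the mitochondrial channel
(return over minutes). Evoked traces trigger one kernel per stimulus window
at the channel's plateau amplitude. Spontaneous recordings (900 s at 0.33 or
0.2 Hz) draw a master Poisson train per cell (default 0.02 events/s); each
event enters both channels with probability `coupling`, otherwise one
channel at random; explicit `event_times` can be planted for exact recovery
tests. Bleaching multiplies the whole trace by exp(−t/τ); Gaussian noise is
added last. The generators are bit-reproducible for a given spec and seed.

## Problem sizes

The recovery phantom is one 24 × 256 × 256 stack (12.8 µm field) holding 50
synapses and 10 isolated ribbons — comparable to one neuromast's synapse
complement at the study ages; dose–response recovery uses the five
experimental doses with 20 noisy replicates; spontaneous/bleach recovery use
single 300-frame (900 s) traces. These sizes make the full validation run
in seconds while keeping every rate and threshold at its analysis-scale
value.

## Known limitations

* Areas measured with the default Otsu threshold are isophote areas at the
  Otsu level, not half-max areas; they are internally consistent (the same
  convention feeds the pairing threshold) but not comparable across stacks
  with very different dynamic range.
* The bleach model is mono-exponential; double-exponential bleaching will
  leave a small residual drift.
* Registration is integer-pixel translation only.
* `pair_synapses` is O(n_ribbons × n_PSDs); fine for hundreds of puncta per
  field, not for millions.
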