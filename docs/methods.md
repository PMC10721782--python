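# Methods

This note records the models, conventions and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Vessel diameter morphometry

**Model.** A meningeal lymphatic vessel in a single-channel immunofluorescence
image is treated as a bright tube over a darker background. The pipeline is
Otsu binarization → morphological cleanup → skeletonization → branch
decomposition → tangent estimation → perpendicular-chord measurement.

**Otsu convention.** The threshold maximizes inter-class variance over a
256-bin histogram spanning the image's intensity range. On a plateau of
maximizing cut points the plateau *midpoint* is returned (symmetric and
deterministic; relevant for two-valued images). Foreground is *strictly
greater* than the threshold. Tests verify equality with a brute-force per-cut
scan that recomputes class means directly from the raw pixel partition.

**Cleanup.** Closing with a disk (default radius 2 px), removal of connected
components below 64 px, hole filling; 8-connectivity throughout 2D. All three
steps are idempotent, so cleaning a clean mask is a no-op. No background
subtraction or other preprocessing is applied before Otsu by default.

**Centerline.** Lee thinning is used rather than Zhang–Suen: the latter
provably collapses an exactly diagonal band to a single pixel, which a
45°-oriented tube triggers. The skeleton is decomposed into branches between
endpoints and junctions. Adjacent junction pixels are clustered
(8-connected), micro-branches of ≤ 3 px inside one cluster are discarded, and
each cluster reports a single junction coordinate. Spur pruning is adaptive
by default: spurs shorter than 1.5× the median vessel radius (distance
transform sampled on the skeleton, floor 5 px) are removed iteratively.
Rationale: skeletons of blunt tube ends sprout corner spurs of roughly one
vessel radius, so a fixed small cutoff systematically under-prunes wide
vessels (empirically a −5% diameter bias at 30 px width). A fixed `prune_px`
remains available.

**Tangents.** At each centerline point the tangent is the principal direction
(SVD) of the centered points within ±5 px of arclength, sign-oriented along
increasing arclength; endpoints fall back to one-sided windows.

**Chords.** From each sampling position (every 1 px of arclength, excluding
3 px around branch ends where tangents are ill-defined) two rays are cast
along ±normal. The mask is treated as a continuous {0,1} field sampled by
bilinear interpolation at 0.1-px steps; the boundary is the first 0.5
crossing, refined linearly between bracketing samples. This makes diameters
continuous under sub-pixel rotation. A ray that fails to exit within
`max_chord_px` (default 100) drops the sample; dropped samples are counted.

**What recovery tests show.** On synthetic tubes with 10%-of-contrast noise
and a 0.5-px PSF, the pooled mean diameter is recovered within 1% for true
widths 5–30 px at rotations 0–45°, with ≤ 0.35 px spread across rotations.
Noise is essential to this accuracy at lattice-commensurate angles (0°, 45°):
it dithers the rasterization staircase so the along-tube mean becomes
unbiased. Per-chord samples retain ±0.5 px quantization; profile shape claims
(e.g. linearity of a taper) therefore hold for locally averaged profiles
(10-px arclength bins), which is also the quantity a morphometrist reads.

**Averaging convention.** Whether a study's "average diameter" pools all chord
samples or averages per-vessel means is a real degree of freedom; the summary
reports the pooled statistics and the per-branch means side by side.

## Plaque quantification

Detection is global thresholding (whole-volume Otsu, or a fixed value)
followed by 26-connected labeling and a minimum-size filter (default 5
voxels); centroids are intensity-weighted. Global rather than per-slice Otsu
assumes illumination-corrected cleared-tissue volumes; a per-slice option is
not provided.

**Known Otsu limitation.** When plaque voxels fall below roughly 1% of the
volume, the inter-class variance of a cut *inside the background noise*
exceeds that of the plaque/background cut and the threshold collapses into
the noise. This is a property of Otsu's objective, not of this
implementation. Low-burden studies should use the fixed-threshold detector
(the equivalent of a manually set surface threshold in commercial tools);
the Monte-Carlo reduction-rate validation does exactly that, thresholding at
the midpoint of the known background and plaque intensities.

Region assignment takes the atlas label at the rounded centroid voxel —
cheap and deterministic; plaques straddling a boundary are attributed to one
region. Background-centroid plaques are retained but excluded from region
tables. Densities: `count_density` (plaques/mm³) and `volume_fraction`
(dimensionless); volume fraction is the conventional plaque-burden headline.
Merged coarse regions (e.g. hippocampus from CA1+CA2+CA3+DG) recompute
densities from pooled counts and volumes, never by averaging subregion
densities.

The reduction rate is defined on group means, `100×(1−mean_t/mean_c)`, with
a two-sided Welch t-test; the mean of per-animal ratios is reported alongside
when group sizes match. A zero control mean is an error (undefined
reduction).

## Behavior

RI = T_novel/(T_novel+T_familiar); undefined when both times are zero.
Platform entry is the first *sample* strictly inside the platform circle (no
segment interpolation), matching ≥10 Hz tracking output; latency is capped
at the trial duration (default 60 s) and flagged. In probe trials the
platform region is the former platform location. Speed is path length over
elapsed time; no smoothing is applied by default (an optional moving-average
helper exists).

## Session kinetics

The standard dosing session is 17 min irradiation, 5 min pause, repeated to
three irradiations: 61 min total; fluence (16/32/64 J/cm²) is carried as
metadata and not enforced. Temperature baselines are the mean of the 60 s
preceding the first irradiation (configurable). The maximum rise is taken
over the whole session, the mean rise over irradiation segments only — the
alternative (whole-session mean) can be obtained by passing custom segment
annotations. Rises above +0.5 °C — the conventional threshold for
irreversible cortical thermal damage — are flagged, without modifying data.
An optional moving-average window (off by default) is recommended before the
maximum for noisy loggers: the raw max of a ~3000-sample trace sits ~3.4
noise SDs above the true plateau (extreme-value bias), an +18% artifact at
the 0.37 °C dose for a 0.02 °C-SD logger. The acceptance script uses a 10-s
window at 0.01 °C noise and recovers programmed rises within 3%.

Tracer drainage (e.g. Evans blue in deep cervical lymph nodes) is the mean
ROI intensity minus the mean background-ROI intensity per timepoint, clamped
at zero — hence invariant to adding a constant to the image. Optional
max-normalization supports cross-animal comparison at fixed timepoints.

## Statistics

Mean ± sample SD (n−1); Welch t-test by default (pooled optional), two-sided;
classic one-way ANOVA as omnibus only (no post-hoc test). Stars use strict
cutoffs: * < 0.05, ** < 0.01, *** < 0.001. Reported p values are uncorrected;
Holm correction is available but off by default, mirroring common practice in
the source literature for multi-region panels. Tests verify the pooled-t
closed form, p against trapezoid integration of the hand-written t density,
the F = t² identity for two groups, and 5% null calibration over 10⁴
simulated replicates.

## Synthetic data

Every generator is a pure function of (parameters, seed) and attaches a
`SyntheticTruth` sidecar; recovery tests read truth only from the sidecar.

* **Vessels** — a straight tube of given width profile rendered analytically
  in the rotated frame, Gaussian PSF, additive Gaussian noise. The midline is
  offset 0.15 px from the pixel lattice: exact lattice alignment is a
  measure-zero configuration in real acquisitions and maximizes rasterization
  quantization at 0°/45° (an artifact of the synthetic geometry, not of the
  estimator).
* **Plaque volumes** — non-overlapping bright spheres (radius uniform in
  2–5 voxels; the size distribution of real plaques is not modeled) placed
  uniformly inside each region until the target volume fraction is met. A
  candidate sphere is placed only while that keeps the running total within
  half its own volume of the target, so quantization error is symmetric —
  a systematic overshoot would bias between-group ratios at small region
  sizes. Placed spheres keep > 1 voxel separation so they remain separate
  26-connected components. Plaque amplitude is SNR × noise SD over a flat
  background (default SNR 10, background 100, noise SD 10). Truth records
  *realized* fractions, centers and radii.
* **Group studies** — per-animal burden drawn lognormally (positive support,
  parameterized by mean and CV; defaults: base fraction 0.02, CV 0.15,
  n = 5+5, effect 0.39). The default study volume is 64×128×128 voxels; the
  200-replicate Monte-Carlo validation uses 24×48×48 single-region volumes so
  the full generate→detect→density→reduction chain runs in seconds, a size at
  which the estimate is still within 1 point of nominal.
* **Trajectories** — correlated random walk with persistence, wall
  reflection, and a goal-bias blend toward the platform (bias 1 = beeline,
  0 = blind search); speed constant at 18 cm/s, dt 0.1 s. No thigmotaxis or
  floating behavior is modeled.
* **Exploration** — total time split by a Beta draw centered at the
  programmed preference with concentration κ = 20 (SD ≈ 0.11 at preference
  0.5, comparable to between-animal spread in published recognition tests).
* **Temperature** — first-order exponential approach to baseline+rise during
  irradiation and back to baseline during pauses (default time constant
  60 s), plus Gaussian logger noise. No biophysical heat transport.

What passing recovery tests on these generators shows is that the estimators
are unbiased and correctly calibrated *under the stated forward models*;
real images add uneven illumination, anisotropic PSFs, vessel curvature and
branching geometry, plaque shape irregularity, and registration error, none
of which are emulated.

## Degenerate inputs and tie-breaks

Constant images have no Otsu threshold (error). Empty masks, single-pixel
skeletons, tubes shorter than twice the junction-exclusion margin, empty
profiles, both-zero exploration times, zero control means, out-of-band
temperatures ([20, 45] °C), and p values outside [0, 1] all raise typed
errors rather than returning silent sentinels. Ties: Otsu plateaus take the
midpoint; region assignment rounds half away from zero via standard
`round()`; star thresholds are strict inequalities.
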