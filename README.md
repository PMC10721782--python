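# lymphomorph

Quantification pipelines for studies of transcranial photobiomodulation (PBM)
in amyloid-overproducing (5xFAD) mice: meningeal-lymphatic-vessel (MLV)
diameter morphometry from fluorescence images, 3D amyloid-β plaque density
per brain region from cleared-tissue light-sheet volumes, behavioral readouts
(novel-object recognition, Morris water maze), thermocouple and
tracer-drainage kinetics during treatment sessions, and the group statistics
tying them together. A synthetic-data module generates every input with known
ground truth, so each stage is validated by parameter recovery without any
raw microscopy data.

## Who this is for

Imaging and behavior labs quantifying lymphatic-drainage interventions in
mouse models of Alzheimer's disease — or anyone who needs a transparent,
scriptable replacement for the ad-hoc mix of FIJI macros and commercial
surface-rendering tools these analyses usually run on.

## The core measurements

**Vessel diameter.** A single-channel fluorescence image of immunostained
meninges is binarized with Otsu's method (threshold `t*` maximizes the
inter-class variance σ²_b(t) = ω₀ω₁(μ₀−μ₁)² over a 256-bin histogram),
cleaned morphologically, and skeletonized into a centerline. At every
arclength position `s` the local tangent **T**(s) is estimated by PCA over a
sliding window, and the diameter is the chord cast along the perpendicular
**N**(s) to the sub-pixel 0.5-crossing of the bilinearly interpolated mask on
both sides:

    d(s) = r₊(s) + r₋(s),   r±(s) = min { r > 0 : M(x(s) ± r·N(s)) < ½ }

Diameters are converted to µm through the pixel spacing and summarized as a
pooled mean/median/SD plus per-branch means.

**Plaque density.** Bright 26-connected components above a global (Otsu or
fixed) threshold, filtered by a minimum voxel count, are mapped onto an
aligned atlas label volume by their intensity-weighted centroid. Per region
the package reports the count density (plaques/mm³) and the volume fraction
(plaque volume / region volume); the treatment effect is the reduction rate

    R = 100 × (1 − mean(treated) / mean(control))  [%]

with a two-sided Welch t-test attached.

**Behavior and kinetics.** Recognition index RI = T_novel/(T_novel+T_familiar)
(chance 0.5); escape latency to a circular platform region capped at the
1-minute trial; path length and mean swim speed; maximum/mean cortical
temperature rise over a pre-session baseline for the standard
17-5-17-5-17-minute irradiation schedule (61 min total); and
background-subtracted tracer-intensity time courses in a lymph-node ROI.

## Worked example

Simulate a vessel image with a known 7-px-wide tube and measure it back at a
pixel spacing of 1.4 µm (true diameter 9.8 µm):

```sh
$ lymphomorph simulate vessels --seed 3 --out v
wrote synthetic vessels dataset to v
$ lymphomorph vessels --input v/vessel.tif --spacing-um 1.4 \
      --out-profile profile.csv --out-summary summary.csv
1 branch(es), 190 chords, mean diameter 9.81 um
$ head -3 summary.csv
statistic,mean_um,median_um,sd_um,n
pooled,9.807368421052628,9.8,0.10156667501540154,190.0
branch_0_mean,9.807368421052628,,,
```

The recovered mean (9.81 µm) is within 0.1% of the generator's truth despite
10%-of-contrast noise. The same pattern works for the other stages, e.g. a
temperature trace programmed with a 1.52 °C irradiation plateau:

```sh
$ lymphomorph simulate thermo --seed 2 --out th
$ lymphomorph thermo --trace th/trace.csv --out th.csv
 max_rise_C  mean_rise_C  exceeds_0p5C
   1.582762     1.430685          True
```

(the unsmoothed maximum carries the extreme-value bias of the logger noise;
see `docs/methods.md`), and a full two-group plaque study via
`lymphomorph simulate study`, `lymphomorph plaques` per animal and
`lymphomorph compare` across groups — that chain prints per-region reduction
rates with significance stars.

The Python API mirrors the CLI one-to-one; see the module docstrings under
`src/lymphomorph/`.

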