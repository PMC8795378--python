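# Methods

## Problem and approach

Dense algal cultures self-shade: cells near the illuminated surface absorb
light before it reaches the interior, so growth stalls as biomass
accumulates ("mutual shading").  `phycolight` models this with two coupled
data-driven surrogates over a 2-D *light distribution pattern* (LDP) — an
18-row x 40-column grid of 8-bit grayscale values (GSV, 0–255) in which
rows run along the light path (row 0 nearest the source) and gray value is
a linear proxy for local irradiance:

1. **LDP model (LDPM).**  One RBF support-vector regressor per pixel maps
   (incident intensity I, cell concentration C) to that pixel's gray
   value: 720 independent models behind one standardized feature space.
2. **Growth-rate model (GRM).**  An RBF support-vector regressor maps an
   LDP feature vector — the 720 gray values scaled to [0, 1] plus mean
   gray and dark-area fraction — to the instantaneous growth rate
   (OD730 h^-1).

A forward-Euler loop couples them: OD fixes C (0.39 g DCW/L per OD730
unit), the LDPM predicts the current light field, the GRM converts it to a
rate, and OD advances one step.  On top of the loop sit semi-continuous
cultivation (SAC: harvest every 24 h, reset to a fixed inoculum OD),
fed-batch control runs, and an inoculum optimizer that scans candidate
starting ODs for the most productive cycle.

The *dark-area fraction* — the fraction of LDP pixels strictly below
25.5 gray (10 % of the 8-bit maximum) — is the summary shading statistic.
Growth peaks when dark area reaches roughly 43 % and collapses near a 65 %
plateau; those two anchors parameterize the reference growth law below.

## Synthetic data generator

Camera photographs of illuminated cultures are replaced by a forward
optical model with exactly known ground truth:

* **Depth attenuation** is Beer–Lambert: `I(z) = I0 exp(-k C z)` with
  extinction `k` in (g/L)^-1 m^-1.  Two-source vessels superpose the front
  field and its row-reversed mirror; saturation happens only at the
  camera stage, where it physically lives.
* **Camera response** is linear with additive Gaussian noise, rounded and
  clipped to [0, 255]: `gsv = clip(slope*I + intercept + N(0, sd))`.
  Default noise is 3 gray units — small against the 0–255 signal but
  enough to make fits realistic.  A Gaussian blur across columns
  (sigma 1.5 px) stands in for lateral scattering.
* **Reference growth law** (the simulation oracle):
  `rate = mu_max * OD * f(mean irradiance) * g(dark fraction)` with a
  Monod-type light response `f(Ī) = Ī/(Ī + K)` and a shading penalty `g`
  equal to 1 below the dark-area onset (0.431), falling linearly to 0 at
  the plateau (0.65).  The law is evaluated on a *continuous* depth
  profile (2048 samples along the light path) rather than the 18-row
  grid: the pixel-count statistic jumps in steps of 1/18 whenever a whole
  row crosses the threshold, which would make the reference law
  discontinuous in OD; the continuous profile is the physical quantity
  the LDP statistic discretizes.  The truth integrator is forward Euler
  sampled at `dt = 0.5 h` with four internal substeps, so reported
  samples carry negligible integration error and finite differences of
  the curve recover the rate law to ~0.02 %.

### Parameter choices (units, defaults, rationale)

| parameter | default | rationale |
|---|---|---|
| extinction `k` (PBR) | 155 (g/L)^-1 m^-1 | chosen so the dark fraction at the documented optimal inoculum (OD730 2.3 ≈ 0.90 g/L) under double-574 µmol light is ≈ 0.43, the dark-area level at which growth peaks |
| extinction `k` (pond) | 50 (g/L)^-1 m^-1 | effective attenuation of a mixed 20-cm raceway chosen so 0.4 g/L under 1500 µmol midday light also sits at ≈ 0.43 dark fraction |
| camera slope | 0.3 (PBR) / 0.15 (pond) gray per µmol m^-2 s^-1 | keeps the working intensity range (≤ 800 per source indoors, ≤ 1500 outdoors) on the 8-bit scale with saturation only at low-concentration hot spots |
| `mu_max` | 0.10 h^-1 | fast-growing thermophilic cyanobacterium; with light limitation this yields initial SAC paces of ~1 g/L/day order |
| half-saturation `K` | 120 µmol m^-2 s^-1 | typical sub-saturating response for high-light-adapted strains |
| dark onset / plateau | 0.431 / 0.65 | the empirically observed peak and collapse of growth against dark area |
| noise sd | 3 gray | small relative to signal |
| LDP grid | 18 x 40 | the standard compressed pattern size |

The presets reproduce the documented *dark-fraction anchors* at the
documented optimal concentrations; they do not reproduce the experimental
productivity magnitudes (~2 g/L/day sustained SAC), and the generator's
own cycle-productivity optimum consequently sits below the experimental
inoculum optimum (near OD ~0.8–1.0 for the PBR preset rather than 2.3).
What the tests certify is therefore *methodological*: the surrogates
recover whatever rate law the generator encodes, and the optimizer
recovers the generator's own optimum — not the lab values.

### What the generator does not emulate

Camera placement, exposure control and raw resolution before compression;
radiative transfer beyond single-scattering blur; photo-adaptation lag
after light changes; nutrient or temperature effects (feeding is assumed
to keep nutrients non-limiting).  Passing tests show the pipeline is
self-consistent under Beer–Lambert optics with a smooth rate law, not
that it would reach the same accuracy on photographs.

## Model fitting

* **Standardization.**  LDPM features (I, C) and GRM features are
  standardized; labels are z-scored (per pixel for the LDPM), making the
  regularization/epsilon grids scale-free and the solver well
  conditioned.  The per-pixel label scale folds back into the stored dual
  coefficients, so prediction is a single kernel vector against the
  training set for all 720 pixels.
* **Kernel width.**  Both models can sharpen the RBF kernel relative to
  the common `1/(d * var)` heuristic via a `gamma_multiplier`: the LDPM
  fixes it at 4 (the fields are steep in the concentration direction);
  the GRM cross-validates it over {1, 4, 16, 64} because its
  722-dimensional features lie on an intrinsically 2-dimensional
  manifold — distance compression favours sharp kernels for the real
  rate surface but wide ones for globally smooth targets.
* **Hyperparameters.**  A small grid over (C, epsilon[, gamma]) is
  selected by seeded 3-fold cross-validation — once on a fixed 12-pixel
  subsample for the LDPM (per-pixel grids would multiply cost 720-fold
  for no gain on these smooth fields), and on the full pair set for the
  GRM.
* **Splits.**  Random record-level 80/20 train/test, seed-fixed.
* **Evaluation.**  R^2 = 1 - SSE/SST about the test mean; pooled over all
  (record, pixel) pairs for the overall score, per pixel across test
  records for the pixel map.  Zero-variance pixels are excluded from the
  map (undefined) but their residuals stay in the pooled score.
* **GRM training data.**  Reference growth curves are integrated across
  six inoculum ODs and the preset's light programs, sampled hourly as a
  plate reader would, and differentiated with central differences
  (second-order one-sided at the ends).  Features come from
  LDPM-*predicted* patterns so the GRM trains on the same surrogate
  it will see in simulation; a switch allows raw generator LDPs for
  ablation.
* **Rates are floored at zero** at prediction time and flooring events
  counted; under the modelled conditions cultures do not shrink.

## Simulation and optimization

Forward Euler with `dt = 1 h` by default; the surrogate rate field is
data-driven and slightly rough, so higher-order integration would add
nothing assertable.  On the double-574 24-h benchmark, halving `dt`
moves the final OD by ~0.2 %.  SAC cycles are independent given the same
daily schedule; cycle productivity is `(OD_end - OD_reset) * 0.39 *
(24 / interval)` g/L/day and cumulative yield sums per-cycle
productivities over their lengths.  The optimizer evaluates one cycle per
candidate OD, sorts candidates ascending, and breaks exact ties toward
the lower OD (a leaner inoculum is cheaper to maintain).  Persistent
domain extrapolation (queries outside the trained intensity/concentration
box) is flagged on every simulation step rather than raised.

## Benchmark problem sizes

The fidelity benchmark trains on a 20 x 20 (intensity x concentration)
grid — 400 patterns, 320 train / 80 test — for the photobioreactor
preset, and 14 x 14 for the pond preset; GRM corpora are ~600 pairs from
24 curves.  These sizes give held-out scores comfortably above the 0.99
bars while keeping a full pipeline build under about a minute.

## Numerical conventions and edge cases

* Dark-threshold comparison is strict (`gsv < 25.5`).
* Compression to 18 x 40 is the arithmetic block mean (exact
  area-weighted mean for non-divisible sizes); it preserves uniform
  values and is idempotent.
* Saturated readings (gsv = 255) are excluded from GSV/irradiance
  calibration fits; clipping breaks linearity.  Integer rounding keeps
  noise-free calibration R^2 marginally below exactly 1 (> 0.999).
* Training records are sorted by condition before fitting, so training
  is exactly invariant to record order.
* Model archives are a JSON metadata header plus an `npz` array store;
  predictions are computed from the stored arrays with the package's own
  kernel math, so a reloaded model reproduces outputs bit-for-bit.
* The residual mass fraction of the cell composition (1 - 0.905) is
  counted at water density in the composite-density estimate; solids
  content uses a 1000 g/L slurry basis.
* The per-OD normalization of product productivity uses the
  time-averaged culture OD.

## Known limitations

The surrogates are only trusted inside the trained condition box (the
concentration ceiling is ~3.9 g/L for the PBR preset); beyond it
predictions carry an extrapolation flag but are not refused.  The GRM
inherits any bias of the LDPM it was trained against.  Changing-light
adaptation lag is deliberately not modelled, so simulated trajectories
under stepped programs are expected to lead measured ones.  All growth
magnitudes are generator conventions, not calibrated predictions for any
real strain.
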