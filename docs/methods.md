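# Methods

This note records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Model and assumptions

The background velocity offset in 2D cine phase-contrast imaging is treated
as a smooth, *static* field B(x, y) added to every velocity map of the
retro-gated cine series. Staticness over the cardiac cycle is the key
assumption: it holds for retrospective gating, where the sequence runs
continuously, and fails for older prospective gating, where the offset
varies with time after the trigger — per-phase offset models are therefore
out of scope here.

B is estimated in two steps:

* **Stationary tissue** is identified pixelwise by low temporal variance of
  velocity over the cycle. Genuinely moving structures (heart, vessels,
  veins with slow flow) have high variance; so do air pixels, whose phase is
  noise-dominated. The stationarity percentile (default 0.15 of eligible
  pixels) is taken *after* removing (a) pixels inside manually traced
  phase-encode wraparound regions, whose phase belongs to folded-in tissue,
  and (b) pixels with variance below `variance_exclusion_threshold`
  (default 1e-6), which are constant-filled reconstruction artefacts (e.g.
  gradient-distortion-correction fill-in at FOV edges). Note the threshold
  is stored on the variance scale even though the quantity is often quoted
  in cm/s; thresholding the SD or the variance selects identical pixels
  under any monotone transform of the ordering, so only this absolute
  exclusion constant is affected by the convention, and it is a config
  parameter.
* **A polynomial surface** of total degree 1–3 is fitted to the
  time-averaged velocity on the mask by unweighted least squares and
  subtracted from all phases. First order is the default: the dominant
  offset component is linear across the FOV, and higher orders amplify
  sensitivity to noise, mask errors and missed wraparound. Some systems
  (typically with imperfect Maxwell-term correction, which is spatially
  second-order) need a second-order surface; the per-system selector picks
  the lowest order whose RMS residual beats the 0.6 cm/s target.

### Phantom reference and accuracy gate

The paired stationary-phantom acquisition (identical protocol) measures the
offset directly and serves as ground truth *when the system is thermally
stable*. Stability is checked by comparing the in-vivo and phantom mean
velocity in a thorax-wall ROI, each averaged over its own cardiac phases:
disagreement beyond `gate_threshold` (0.6 cm/s, **inclusive** — "within
0.6" is read as ≤) excludes the study from validation statistics. The
phantom may be triggered at a different simulated heart rate; all phantom
quantities are averaged over its own phases, so no temporal resampling is
needed.

### Sign convention and flow quantities

All reported offsets are multiplied by `flow_sign` so that positive always
means cardiac-output overestimation, independent of the stored
through-plane direction. Volume flow is ROI mean velocity × ROI area
(cm/s·cm² = ml/s), integrated by the rectangle rule with uniform phase
duration RR/N (retrospective cine reconstructs uniformly spaced phases; the
quadrature is a package choice, not prescribed). The relative
cardiac-output error of an offset o is 100·o·A·RR/SV with the
*uncorrected* stroke volume as denominator — the "initial measurement" a
site would have reported. The vessel ROI is the end-diastolic contour
copied to all phases; vessel motion over the cycle is neglected.

## Numerical choices

* **Rasterization** uses the pixel-center rule, boundary inclusive
  (shapely `covers`); no partial-volume weighting at ROI edges. ROI area is
  pixel count × pixel area.
* **Mask tie-breaks**: pixels are ordered by (variance, row-major index)
  with a stable sort, so percentile cuts are deterministic under ties.
* **Erosion** uses the 3×3 (8-connected) structuring element with the image
  border treated as outside, so border pixels always erode away. The
  initial percentile is tuned by bisection on [p, min(3p, 0.9)], at most 50
  iterations, stopping when the final-mask fraction is within
  `mask_fraction_tolerance` (0.0025) of the target; failure to bracket the
  target raises an error carrying the best achieved fraction rather than
  silently returning an off-target mask.
* **Fitting**: pixel coordinates are affinely mapped to [−1, 1]² over the
  full FOV before building monomials (conditioning only; the evaluated
  field is parameterization-independent). The least-squares solution uses
  an orthogonal-decomposition solver; a design condition number above 1e8
  raises a degeneracy error naming the deficient monomial directions
  instead of returning an unstable fit. Monomials x^i y^j, i+j ≤ order, are
  ordered by total degree then by i.
* **Statistics**: SD uses the n−1 denominator; RMS satisfies
  rms² = mean² + (n−1)/n·sd² exactly. The paired t-test is run on both
  signed and absolute offsets (the pairing target is ambiguous in common
  usage; signed is primary). The F-test is the two-sided variance-ratio
  test. Degenerate inputs (zero-variance differences, < 2 pairs) report
  NaN, never a fabricated value. The temporal variance map uses the
  population (divide-by-N) convention; the choice cannot affect the
  percentile ordering.

## The synthetic-data generator

`pcflow.synth` generates the validation substrate: a 128×128 grid of
1.5 mm pixels, 30 cardiac phases, V_enc 150 cm/s, heart rate 60 — typical
clinical values. Anterior and posterior stationary-tissue bands flank a
central air/lung region with a circular vessel (radius 1.5 cm) carrying a
rectified-sinusoid systolic pulse plus a small diastolic tail (closed-form
stroke volume, sampled at phase midpoints; the default peak of 45 cm/s is
an ROI-*mean* systolic velocity giving ≈ 90 ml stroke volume, ≈ 5.4 l/min).
The planted offset field is a polynomial (order ≤ 3) in the same normalized
coordinates the fitting module uses. Noise is Gaussian per pixel and phase
in tissue (SD 0.3 cm/s) and vessel (1.0 cm/s), and uniform with SD V_enc/3
in air (noise-dominated phase). The regional noise levels are package
choices — in-vivo SNR varies widely and is not prescribed — and all
validation properties are expressed relative to the configured noise, not
absolute levels. Tissue noise SD grows smoothly (factor 1 + d) with
distance d from the band center, emulating the spatial structure that coil
sensitivity and tissue heterogeneity give real variance maps; without it
the lowest-variance percentile would be a spatially random subset of
tissue, which erosion would annihilate. A configurable zero-filled border
emulates constant-filled reconstruction pixels.

The phantom shares the geometry, carries the same offset field (plus an
optional uniform instability, emulating thermal drift between the two
acquisitions) and tissue-level noise inside a footprint covering the vessel
and the anterior wall — but not the posterior band, mirroring a practical
phantom smaller than a thorax.

Cohort profiles draw per-study fields whose vessel-ROI mean is
Normal(0, 1.5²) cm/s — the spread the phantom reference attributes to
uncorrected clinical acquisitions — with tilt terms of SD 0.8 cm/s per
normalized unit. A "second-order system" profile uses curvature terms of
SD 4 cm/s, large enough that a plane fit reliably leaves an RMS residual
above the 0.6 cm/s target while a second-order fit removes it; an unstable
profile shifts the phantom field by ±1–2 cm/s in a configurable fraction
of studies, which the accuracy gate must catch.

**What passing tests do not show.** The generator plants ideal polynomial
fields and draws independent pixel noise; it does not simulate eddy-current
physics, ghosting artefacts (which can leak past the temporal-variance
test at the chest wall), respiratory motion, metallic implants, or offset
fields outside the polynomial model space. Residuals after correction are
therefore at the *noise floor* here, whereas in vivo they are limited by
model mismatch (reported residual spreads on real multi-system data are a
few tenths of cm/s). The validation demonstrates the correctness of the
algorithmic chain and its statistical behaviour under the stated
conditions, not clinical accuracy.

## Problem sizes used in validation

Unit and acceptance tests run the full-size default geometry where the
claim concerns the reference conditions (the 100-study parameter-recovery
cohort; pipeline closure), and a scaled 64×64/10-phase variant
(`compact_config`) for Monte-Carlo exercises that repeat the pipeline
hundreds of times (order-selection replicates, Qp/Qs pairs) — the scaled
layout preserves all geometric proportions. The acceptance script analyzes
a 60-study, three-system cohort at full size plus 20 shunt-free Qp/Qs
pairs.

## Known limitations

* Per-phase (prospectively gated) offset variation is not modelled.
* Wraparound regions must be supplied as ROIs; there is no automatic
  detection, matching the manual tracing the method expects.
* No robust/regularized fitting; a mask contaminated by moving structures
  biases the surface (the package reports mask fraction and residual RMS so
  such cases can be inspected, but does not auto-detect them).
* The DICOM adapter handles generic magnitude/phase cine pairs with
  rescale-to-radians or explicit scaling; vendor private tags are not
  interpreted.
* The alternative 8–10% stationarity percentile useful for oversized FOVs
  is exposed as a parameter, not auto-selected.
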