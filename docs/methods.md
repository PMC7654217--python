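# Methods

This note documents the models and procedures `cordmotor` implements,
the choices made where the design was genuinely open, and what the
synthetic-data layer does and does not emulate.

## Spared-tissue quantification

**Model.** A chronic intramedullary spinal cord lesion is represented by
two binary 3-D masks on a common template-space voxel grid: a cord mask
(which contains the lesion, since the lesion is inside the cord) and a
lesion mask. The axial extent of damage is summarised by projecting the
lesion along the superior–inferior axis into one composite axial image:
pixel (x, y) is lesioned iff any voxel (x, y, z) is lesioned. The
projection is a binary union, not a fractional occupancy along the
projection axis — the composite image answers "was this part of the
cross-section damaged at any level", which is the quantity the
regional scores need.

For a region with per-pixel nonnegative weights w, the spared
percentage is

    spared = 100 · Σ_{non-lesioned pixels} w / Σ_all w.

Five outcomes are produced per study: total cord (scored against the
whole axial cord mask) and the anterior, posterior, left-lateral and
right-lateral white-matter regions. Atlases carry per-pixel weights so
a probabilistic tract atlas can be consumed directly; binary masks are
the special case w ∈ {0, 1}. Whether a probabilistic atlas should be
weighted or binarised at 0.5 before scoring is a user choice (both are
representable; weighted is the default form), and "total cord" is the
whole cross-section (grey plus white matter) rather than the union of
the four white-matter regions — both conventions are defensible and the
atlas construction makes either available.

**Slicewise alignment.** Real template registration (nonlinear,
slicewise) belongs to dedicated registration tooling and is assumed
done upstream; inputs are template-space masks. For phantom work the
package provides a deliberately simple per-slice stand-in: translate
the cord centroid onto the template centroid and match the cord area
with an isotropic scale s = √(A_template/A_subject), nearest-neighbour
resampling, identity (logged) on empty slices. It recovers exactly the
transforms the phantom generator plants and is not suitable for
clinical images.

**Degenerate inputs.** A region with zero total weight has no defined
spared fraction and raises; an empty lesion projects to an all-zero
image and yields 100% spared everywhere.

## Synthetic phantoms and the enumeration oracle

Phantom cords are elliptical cylinders on a voxel grid (default radii
(10, 8) voxels, mimicking the roughly elliptical cervical cross-
section); lesions are unions of axis-aligned boxes and per-slice
ellipses, rejected with a diagnostic if they reach outside the cord.
These primitives have exactly enumerable projected footprints, which is
why they were chosen; lesion morphology across real cohorts is not
characterised, so the shape family is a free modelling choice.

The ground-truth spared profile is computed by direct pixel enumeration
with plain Python loops (`oracle_spared_profile`), independent of the
vectorised quantification path, so each can check the other. On binary
atlases the two agree bit-for-bit (both reduce to integer counts); on
weighted atlases to ≤ 1e-9 relative (floating-point summation order
differs).

The sector atlas divides the cord annulus into four 90° bins centred on
the axis directions (+y anterior, −y posterior, +x left, −x right),
using the radii-normalised angle so elliptical cords keep four
comparable sectors. Bins are half-open, which makes a 90° rotation of a
circular atlas map the sector pixel sets onto each other exactly (on
even grids, where no pixel sits at the exact centre). The optional
radial weighting ramps linearly from 1 at the centre to 0 at the cord
boundary, emulating the soft edges of probabilistic tract maps.

## EMG processing

Signals are 2 kHz multichannel EMG in mV. The chain:

1. **Band-pass 30–1,000 Hz**, 4th-order Butterworth applied
   forward–backward (zero phase). The filter design is a standard EMG
   choice with a testable frequency response; at fs = 2,000 Hz the
   1,000 Hz edge sits on Nyquist and is clipped to 0.99·Nyquist with a
   warning.
2. **ΔRMS**: RMS over the attempt window minus RMS over a resting
   background window immediately preceding it (default duration 1 s).
   Negative values are meaningful (volitional suppression of a muscle)
   and are never clamped.
3. **Recruitment normalization**: single epidural stimuli at 2 Hz are
   delivered in blocks of five per intensity; the evoked response is
   max − min of the signal in a 5–95 ms post-stimulus window (the
   window is configurable; it must close before the next stimulus).
   Peak-to-peak values are averaged within each intensity and the
   largest mean across intensities, max_p2p, is the per-muscle
   normalization constant: activation = ΔRMS / max_p2p. Channels whose
   max_p2p is at or below a floor (default 1e-6 mV) cannot be
   normalized; they are excluded and logged, never silently zeroed.

Whole-window RMS is used for the attempt (no sub-windowing).
Normalization is scale-equivariant: rescaling a channel rescales ΔRMS
and max_p2p identically and leaves the activation unchanged (bit-exact
for power-of-two factors, to rounding otherwise).

The synthetic generator builds sessions as Gaussian background noise +
a rectangular-envelope 150 Hz sine burst in the attempt window + a
biphasic evoked pulse train (positive then negative half-sine lobes,
amplitudes 0.6/0.4 of the target p2p, 4/6 ms) whose p2p follows a
logistic recruitment curve plateau/(1 + e^{−slope·(I−threshold)}).
Lobe lengths are even so one sample lands on each lobe peak and the
noiseless p2p equals the lobe sum exactly. Closed-form truths:
ΔRMS = √(sd² + A²/2) − sd per channel and p2p(I) = the sigmoid value.
What this does **not** emulate: real motor-unit interference patterns,
movement artifact, stimulation artifact bleed-through, electrode
impedance drift, or rise/fall dynamics of voluntary bursts — passing
tests show the measurement chain is correct, not that it is robust to
those confounds.

## Co-contraction (JPD quadrants)

For two muscles' nonnegative amplitude envelopes during one attempt
(the envelope estimator is a declared stand-in: moving RMS of the
rectified signal, 50 ms window), each time sample is one point in the
joint amplitude plane. A muscle is "active" at a sample iff its
amplitude is strictly above 10% of that muscle's own maximum during the
attempt. The four areas — isolated A, isolated B, co-contraction high
(both active), co-contraction low (neither) — are reported as
percentages of all samples and always sum to 100.

Choices: the threshold is per-muscle (axis-aligned rectangular regions
in the density plot require per-axis thresholds); a single joint
maximum is available behind `joint_threshold=True`. Samples exactly at
threshold count as inactive, which makes the degenerate case fall out
naturally: when neither muscle shows any activation (both maxima at or
below a 1e-9 floor in normalized units; no numeric criterion exists in
the source procedure, so the floor is configurable) the attempt is
100% co-contraction at the low level of activation.

## Association statistics

The cohort table has one row per subject: five MRI percent variables
and motor outcome columns tagged `continuous`, `count` or `binary`.
The ledger:

1. **Zero-variance pruning** — constant columns are dropped and logged.
2. **Spearman screen** — rank correlation (average ranks on ties),
   two-sided p; a pair is "correlated" when |ρ| ≥ 0.4 and p < 0.05.
   No cutoff for "weakly correlated" exists in the source procedure;
   ρ_min = 0.4 is a declared, configurable choice recorded in the
   report provenance.
3. **Shadow-feature importance (Boruta scheme)** — per motor outcome,
   each of n_iter = 100 iterations appends freshly permuted shadow
   copies of every predictor, fits a random forest (100 trees,
   classifier for binary outcomes), and scores a hit for each real
   predictor whose impurity importance exceeds the maximum shadow
   importance; hits are tested against Binomial(n_iter, ½), two-sided
   at α = 0.01: significantly many → confirmed, significantly few →
   rejected, else tentative. Two defaults protect small designs:
   `min_samples_leaf = 5` (fully grown trees fit residual noise in deep
   splits, which lets a real column's fixed chance arrangement beat
   freshly permuted shadows persistently) and `shadow_copies = 3` (the
   max-shadow bar is the max of 15 draws rather than 5). Known
   limitation: at intermediate sample sizes (n ≈ 50–200) a feature
   whose chance association with the outcome sits at an extreme
   percentile of the permutation distribution is persistent sample
   structure, and any max-shadow selector will occasionally confirm
   it; at the 13-subject scale this pipeline targets the null
   false-confirmation rate is small.
4. **Retention** — an MRI variable is kept iff correlated-or-confirmed
   for ≥ 1 motor outcome; a motor outcome is kept iff ≥ 1 MRI variable
   is correlated or confirmed for it.
5. **Family-dispatched GLMs** — Poisson for counts, logistic for
   binaries, OLS otherwise; coefficients are per 1 percentage point of
   spared tissue. Rank deficiency and perfect separation are flagged on
   the result, not raised. Univariable fits are computed for every
   (MRI, motor) pair and kept, unfiltered, in the report.
6. **Multivariable + bagging** — per retained motor outcome, the MRI
   variables with univariable p < α are combined into one joint model,
   then refitted on B = 1,000 bootstrap copies of the rows (family kept
   under bagging). Degenerate resamples (collapsed predictor, rank
   deficiency, failed ML fit) are redrawn and counted; > 10·B
   consecutive redraws aborts. The ensemble mean is the adjusted
   estimate, the ensemble SD its SE, and p is the two-sided normal
   approximation on mean/SD (how the source procedure derived its
   bagged p-values is not stated; this is the package's choice). With
   B = 1 the SE and p are reported as NaN.
7. **Report** — significant rows at α = 0.05 (α is configurable; no
   stated level exists in the source, and borderline p-values around
   0.015 were treated as significant there, consistent with 0.05).
   No multiple-testing correction is applied by default, mirroring the
   correlational scope; Benjamini–Hochberg is available behind
   `bh_correction=True`. The provenance block records every threshold,
   size and seed. Listwise deletion handles missing values.

The synthetic cohort generator plants effects through the canonical
links (identity/log/logit) with MRI variables uniform on [0, 100]. The
default continuous noise (sd = 1.0) puts a slope of −0.02 per percent
at the edge of detectability at n = 13 (analytic slope SE ≈ 0.01),
which is the regime the pipeline is meant for. What the generator does
not emulate: correlated MRI predictors (real regional spared fractions
are strongly dependent), non-Gaussian measurement error, and
missingness patterns.

## Numerical and testing conventions

- All generators take one integer seed; per-channel/per-column
  sub-streams are derived deterministically, so adding a channel or
  column never perturbs the others. Reports are bit-reproducible under
  a fixed seed and configuration.
- Exactness claims in tests use power-of-two scale factors, under which
  binary floating point scaling is lossless; arbitrary positive factors
  hold to rounding.
- HDF5 fixtures are written with `track_times=False` and NIfTI
  uncompressed, so identical content produces identical bytes.
- Monte-Carlo suite sizes (50 phantom seeds, 100 envelope pairs, 100
  selector seeds, 50 bagging replicates, 200 null cohorts) were chosen
  as the smallest sizes at which the binomial/Monte-Carlo tolerances
  asserted in the tests are meaningful.

## Known limitations

- The slicewise alignment is a phantom-testing stand-in, not a
  registration method.
- Vertebral-level localisation, lesion segmentation and clinical reads
  are out of scope; masks are assumed given.
- The JPD envelope estimator and the evoked-response window are
  declared stand-ins where the source procedure left parameters
  unstated; both are configurable.
- The association pipeline is correlational; no causal claims, mixed
  models or cross-validation.
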