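# Methods

## The CN-correlation model

Each tracked cell contributes one observation per acquisition interval
(nominally 1 min): the cell centroid displacement magnitude CCD = ‖Δc‖ and
the signed scalar projection NCD_∥ = Δn·Δc/‖Δc‖ of the nuclear displacement
onto the cell's direction.  The pair is read in polar coordinates with
θ = atan2(CCD, NCD_∥).  This axis convention is forced by three facts about
the activity geometry: nucleus-led detachment steps (NCD_∥ > CCD) must land
below 45°, cell-led steps (CCD > NCD_∥ > 0) between 45° and 90°, and pure
protrusion with a stationary nucleus exactly at 90°.  Since CCD ≥ 0, θ is
confined to [0°, 180°]; rearward nuclear motion (NCD_∥ < 0) gives θ > 90°.

Intervals whose CCD falls below 10⁻⁶ µm have no usable direction for the
projection; they are excluded from pair extraction and tallied in the
validation report rather than silently dropped.

Profiles pool the pairs of many movies (by default 25 movies sampled without
replacement, seeded).  Diagrams use 36 fixed bins of 5° ([0,5), …, [175,180];
a value at a bin edge goes to the upper bin, 180° to the last).  Pooling is
per cell, with movie/cell provenance retained on every pair.

## Nonparametric profile comparison

*Occurrence diagrams* are compared bin-by-bin with an exact sign test: the
k₁+k₂ events pooled in a bin are split Binomial(k₁+k₂, n₁/(n₁+n₂)) under the
null; the two-sided p-value doubles the smaller tail and caps at 1.  This
generalizes the classical equal-n sign test to unequal profile sizes.

*CCD diagrams* are compared with the Lepage location–scale statistic
L = z_W² + z_A², combining the standardized Wilcoxon rank-sum and
Ansari–Bradley statistics on the raw per-bin CCD samples.  Ties are handled
with mid-ranks; null moments use the finite-population subset-sampling
formulas on the observed score vector (E₀ = n₁·mean(a),
Var₀ = n₁n₂·popvar(a)/(N−1)), which reduce to the classical tie-corrected
even/odd-N closed forms and remain exact under arbitrary ties.  The null is
χ² with 2 df asymptotically; a seeded label-permutation p-value (default
10 000 shuffles, vectorized) is used when either group has fewer than 10
observations, or on request.  Bins with fewer than 2 values in either group
are flagged, never dropped.  No multiple-testing correction is applied by
default because per-bin p-values are conventionally read against the 0.05
line; Benjamini–Hochberg is available behind a flag.

## Mixture deconvolution (UNM)

The angle sample of a profile — not its binned histogram, which is merely
the visualization of the same sample — is deconvolved by EM into k Gaussian
components; k is chosen by AIC = 2(3k−1) − 2ℓ over k = 1..8.  EM controls:
relative log-likelihood tolerance 10⁻⁸, max 2000 iterations, 10 seeded
restarts with means initialized at sample quantiles (restarts run a capped
exploratory EM of 300 iterations; the best candidate is refined to full
tolerance).  k = 1 uses the closed-form mean and population SD.  Components
are always reported sorted by mean, which resolves label switching.

Two safeguards address the unboundedness of the mixture likelihood:

- **SD floors.**  Absolute floors of 0.5° (angle fits) and 0.01 µm (CCD
  fits), plus a resolution limit of 10% of the sample SD: structure narrower
  than a tenth of the data spread is below what the deconvolution targets,
  and clamping it removes most of the likelihood advantage of spurious
  narrow components.
- **Degeneracy screen.**  A fitted candidate is treated as a spurious
  likelihood spike when a component SD sits at the absolute floor, the
  within-model ratio min(sd)/max(sd) drops below 0.15, or a component claims
  fewer than 3 observations.  Model selection prefers clean candidates and
  falls back to the full set only if none exists.

Without these safeguards, AIC — which is known to be liberal for mixture
order — latches onto narrow chance clusters (weight ≈ 1%, SD ≈ 1°) and
inflates k; with them, order selection on well-separated mixtures is correct
in ≳80% of replicates and residual errors in the extreme component means are
dominated by ordinary sampling noise.  Angles are fitted as linear values on
[0, 180]: CCD ≥ 0 confines the data to a half-plane and no realistic profile
places mass near both edges simultaneously, so circular methods are
unnecessary; this is a documented limitation for hypothetical edge-heavy
profiles.

Signature angles are the component means of the selected model.  Each is
labeled by the activity zone containing it, using a non-overlapping
partition of [0, 180]: initial detachment [0, 30), detachment [30, 60),
protrusion [60, 105), large-angle protrusion [105, 130), contraction
[130, 180].  The observed activity zones overlap (detachment spans roughly
20–70°, sampling 60–120°), so labeling uses this partition instead: its
boundaries match the detachment-zone upper edge (60°) and the contraction
onset (130°), and the protrusion band extends past 90° — pure protrusion is
centered at 90°, so its upper edge sits at the midpoint (105°) between the
canonical protrusion (~80°) and side-protrusion (~128°) signature angles.
Angles on a boundary or outside the range resolve to the nearest zone
center.  The *detachment zone* used for motility is [0°, μ + 2σ] of the
detachment-labeled component (largest weight if several).

## Motility metrics

- **CMPI** — accumulated NCD_∥ over detachment-zone pairs.  The default
  normalization divides by the total pair count of the profile (a
  per-observed-minute rate), making CMPI comparable across profiles of
  different sizes; `sum` and `per_cell_hour` normalizations are available.
  Inside a detachment zone that tops out below 90°, NCD_∥ is positive by
  construction.
- **MSD** — overlapping windows, per-cell averages weighted equally (long
  tracks must not dominate the ensemble), lags up to one third of the
  shortest track.
- **PRW fit** — least squares of the 2-D Fürth form
  MSD(τ) = 4D[τ − P(1 − e^{−τ/P})], log-parameterized so D, P > 0, with
  S = √(2D/P).  Residuals are relative (scaled by the observed MSD): the
  sampling error of an overlapping-window MSD grows roughly in proportion to
  its value, and absolute residuals would let the noisy long lags dominate
  and leave P poorly constrained.  On noiseless model curves the fit is an
  identity map on (D, P) to numerical tolerance.
- **Directionality (D/T)** — net displacement over path length per
  overlapping 10-min window (stride one frame), averaged per cell then
  across cells; zero-path windows are skipped.
- **Velocity** — path length per minute over overlapping one-hour windows,
  averaged the same way.

## The synthetic-data generator

The simulator emulates what the analysis consumes: coupled 1-min-interval
centroid series composed of labeled activity episodes.  Five default
activities sit at the centers of the observed polar-angle zones
(θ means 45°, 75°, 90°, 110°, 150°; SDs 9–10°), with log-normal pole
distances whose medians decrease from detachment (1.0 µm) through the
protrusions (0.55/0.45 µm) to sampling (0.25 µm) and contraction (0.22 µm),
encoding the observation that detachment events lie farthest from the pole.
Episode durations are geometric (means 2–4 min); on leaving an episode the
next activity is drawn with probability ∝ weight/duration, which makes the
configured weights the exact stationary per-interval occupancy.  Default
occupancy (0.25, 0.25, 0.20, 0.15, 0.15) gives a detachment-rich,
fibroblast-like pattern; 25 movies × 61 frames reproduce the canonical
n = 1500 profile size.

Tracks are laid out with a persistent heading (von Mises turn angles,
concentration 4 by default); the cell steps by CCD along the heading, the
nucleus by NCD_∥ along the heading plus independent perpendicular Gaussian
noise (SD 0.15 µm).  Because the perpendicular nuclear component is noise by
construction, pair extraction recovers the generated (CCD, NCD_∥) exactly
(to ~10⁻¹¹ µm accumulated rounding); this is the pipeline's primary oracle.
What the generator does *not* emulate: segmentation error, drift, intensity-
weighted centroids, frame drops, biophysical (Rho-GTPase-level) dynamics,
or any coupling between nuclear perpendicular motion and activity — so
passing tests demonstrate the correctness of the computations, not robustness
to real microscopy artifacts.

A separate persistent-random-walk generator (Ornstein–Uhlenbeck velocity,
stationary speed S, relaxation time P, integrated on a 0.1-min substep grid)
provides exact-model tracks for MSD/PRW validation.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed; CLI runs log their seed and
config hash.  The test suite and the acceptance script use desk-scale sizes:
profiles of n = 1500 (25 movies × 60 intervals), extraction fidelity checked
on 10 000 intervals, test calibration on 2000 null replicates (50
observations per group, 500 permutations each), mixture-order recovery on 50
replicates of n = 1500 with 10-SD component spacing, and PRW recovery on 25
tracks of 61 frames.  The signature-recovery benchmark (means 17/44/80/
128/153, SD 8°, weights 0.10/0.25/0.45/0.10/0.10, n = 1500) is stochastic:
the extreme component means are recovered within ±3° in roughly 9 of 10
seeds, with misses dominated by sampling noise in the 10%-weight tail
components rather than by fitting failures.

## Known limitations

- Angles are modeled as linear, not circular (see above).
- The sign-test construction for occurrence diagrams is one reasonable
  reading of "sign test" for binned count data; it is exact for equal
  profile sizes and generalizes via the binomial split.
- CMPI's normalization is a package choice (per observed interval); the raw
  accumulated sum is available when absolute displacement is wanted.
- The MSD/PRW fit assumes homogeneous motility across cells of a condition;
  per-cell fits are out of scope.
- Mask centroids are unweighted; intensity-weighted centroiding of raw
  images is deliberately not implemented (tracking is upstream of this
  package).
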