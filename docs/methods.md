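# Methods

## Scope

The package reimplements a classical feature-engineering pipeline for
recognizing nine everyday activities from a pocketed smartphone
(accelerometer, magnetometer, gyroscope, barometer, light, GPS) and a
wrist-worn watch (accelerometer only), plus indoor/outdoor detection by
GPS–light fusion. Since no field recordings are distributed with this
setting, a synthetic-data generator defines the study conditions; all
tests and the acceptance script run against it.

## Synthetic signal model

Each activity bout is parameterized by an `ActivityProfile`:

| parameter | meaning | defaults (walking / running / cycling / stairs) |
|---|---|---|
| `gait_frequency_hz` | fundamental cadence; 0 for static postures | 2.0 / 2.8 / 1.5 / 1.8–1.9 Hz |
| `dynamic_amplitude_ms2` | peak dynamic acceleration | 3 / 8 / 2.5 / 3–3.5 m/s² |
| `gravity_axis_angle_deg` | device +Y axis vs gravity for the posture | standing 10°, sitting 70°, cycling 75°, walking 15° |
| `altitude_rate_m_per_s` | signed vertical rate | elevators ±1.0, stairs ±0.5 m/s |
| `lux_mean`, `gps_visible`, `sat_count_mean`, `sat_snr_mean` | environment cues | indoor 200 lx / no fixes; outdoor 10,000 lx, 9 satellites, SNR 35 dB |

The accelerometer is a gravity vector (9.81 m/s² tilted by the posture
angle in the X–Y plane) plus a gait waveform — fundamental and two
harmonics with amplitude ratios 1 : 0.4 : 0.15, weighted (0.4, 1.0, 0.3)
across axes — plus white Gaussian noise (SD 0.08 m/s² phone, 0.1 m/s²
watch). The waveform is the simplest signal with a realistic spectral
spread; no biomechanical model is attempted. The magnetometer sees a 50 µT
field inclined 30° from the gravity axis with a rocking oscillation
proportional to the dynamic amplitude; the gyroscope carries only the
oscillation. Pressure follows the international barometric formula
(sea-level reference 1013.25 hPa) along the integrated altitude track —
trapezoidal rate for elevators (3-s ramps), constant rate plus a 3-cm gait
bounce for stairs — with 0.02 hPa noise, a figure typical of phone-grade
barometers. A widely quoted rule of thumb equates a 1-unit pressure change
with 8.4 m of altitude; that factor is correct per hPa (≈11.2 m per mmHg),
and the package uses the full standard-atmosphere formula everywhere
rather than any linearized constant.

Sampling is irregular by construction: nominal per-sensor rates (phone
90/25/27/5/5 Hz, watch 15 Hz, GPS 1 Hz) with uniform ±5% timestamp jitter,
to exercise the interpolation stage. Two details matter for correctness at
boundaries: every sensor emits a final sample at the session end (so the
resampling grid covers the last window), and internal bout boundaries are
bracketed by samples 1 ms apart on either side (so the linear interpolant
cannot smear a step — e.g. the indoor→outdoor lux jump — across two
annotated segments). The watch accelerometer emits *no* samples during
sedentary bouts (sitting, standing, elevators), emulating a battery-saving
shutdown; hold-last-value filling reconstructs those spans downstream. A
session that *begins* sedentary has no last value to hold; such leading
watch segments are skipped with a log message.

Determinism: all randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns per device and sensor, so identical
seeds give bit-identical streams.

### What the generator does not emulate

No magnetic disturbances, GPS multipath, sensor bias/drift, inter-subject
gait variability, misannotation, or device orientation changes within a
bout. Classes are therefore close to separable, and cohort classification
rates near 99% are a *generator contract* (the pipeline recovers what was
put in), not a prediction of field accuracy. The meaningful synthetic
readouts are orderings and invariances: fused ≈ accelerometer >
magnetometer > gyroscope ≫ pressure, unbalanced > balanced, permuted
labels at chance, and closed-form oracle agreement.

## Pipeline numerics

* **Resampling** is linear interpolation onto a fixed grid starting at the
  first raw timestamp (inertial 100 Hz, pressure/light 10 Hz); exact on
  affine signals, no extrapolation. Hold-last-value filling applies only to
  gaps longer than 2,000 ms (one window) — shorter gaps are plausible
  jitter and are left to interpolation.
* **Filters** are 4th-order Butterworth biquad cascades applied
  forward–backward (`sosfiltfilt`), i.e. zero phase, so filtered samples
  stay aligned with window boundaries. Whether a causal or zero-phase
  realization is "correct" is underdetermined for this design; zero phase
  was chosen for window alignment and is measured, not assumed: the
  acceptance checks probe gains at DC, 0.3, 2, 15 Hz and on a 0.5 hPa/h
  drift. Filtering is done per annotated segment with reflect padding so
  posture transitions do not bleed across labels.
* **Windows** are non-overlapping 2-s slices (no overlap keeps CV
  instances independent); the trailing remainder is discarded; a window is
  dropped (and counted) if any required sensor slice is incomplete.
* **Features.** Activity counts use the classical actigraphy definition,
  the rectified integral of the band-passed signal. Coefficients of
  variation are computed on the rectified signal (the band-passed mean is
  ~0, which would make the plain CV unstable); a rectified mean at machine
  zero returns 0. Spectral features use an unwindowed periodogram of the
  200-sample window (0.5 Hz bins, so on-bin tones are exact); all-zero
  windows return zero power and, by convention, zero frequency. Step
  counts are local maxima above 0.5× the window RMS with ≥0.25 s
  separation (max credible cadence 4 Hz). The displacement feature
  detrends and double-integrates each axis trapezoidally and combines
  per-axis peak displacements as a Euclidean norm — per-axis integration
  is what makes the closed form a·sin(2πft) → a/(2πf)² hold. Altitude
  features invert the barometric formula on *raw* pressure (absolute
  differences need the absolute signal; the high-passed variant is
  diagnostic only). Device angles come from the low-passed gravity/field
  vector; vectors below 0.1 of the expected magnitude flag the angle
  missing (NaN), which the modeling stage imputes as 0 inside the CV
  pipeline.
* **Watch schema.** The 17 watch attributes are the accelerometer subset:
  counts ×3, RMS count ×1, peak frequency ×3, max power ×3, peak power ×1,
  primary frequency ×1, step count ×3, uncorrected + corrected angle. The
  multiplicities are a design choice consistent with the 53-attribute
  phone schema's accelerometer rows.
* **GPS/light.** Bearings average circularly (vector mean); a window with
  no fixes reports satellite count 0 and SNR 0 — absence of lock *is* the
  indoor cue — with the remaining fields missing and imputed 0. The light
  low-pass cutoff is 0.5 Hz (a smoothing choice; only the ordering of
  raw/low-passed means matters downstream).
* **Balancing** subsamples every class without replacement to the minimum
  class count (no augmentation), seeded.
* **Models.** "C4.5" and "CART" are realized as scikit-learn decision
  trees with entropy and Gini splits respectively; naive Bayes is
  Gaussian; the MLP has one hidden layer of half the feature count; the
  SVM uses an RBF kernel with default regularization. Hyperparameters
  beyond these are library defaults, recorded in the config. Evaluation is
  stratified 10-fold CV (folds shrink to the smallest class where needed),
  the standard choice at this cohort size; a single fixed train/test split
  would be noisier and harder to reproduce.
  Reports aggregate out-of-fold predictions; the overall true-positive
  rate is 100·trace(confusion)/total.
* **PCA** standardizes columns to zero mean and unit variance, then keeps
  the smallest k whose cumulative explained variance reaches 95%. The
  equal-eigenvalue case (isotropic noise) correctly forces k = dimension.

## Problem sizes

The default virtual cohort is ten subjects × a 477-s scripted protocol
covering all nine activities (≈2,380 phone windows, ≈2,370 watch windows);
the transition walk is 300 s indoor + 300 s outdoor (300 geo windows).
These sizes give stable cross-validated estimates while keeping the full
test suite and the acceptance script fast on a single CPU.

## Known limitations

* ARFF support is a minimal dialect (numeric + nominal attributes, `?`
  missing values) sufficient for round-tripping this package's tables.
* The indoor/outdoor experiment evaluates window classification only; no
  change-point localization of the transition time.
* No per-user calibration, no sliding-window smoothing, no energy-aware
  tiered classification — all deliberate non-goals of this reference
  implementation.
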