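# actifuse

Multi-sensor human activity recognition with everyday smart devices — a
smartphone in a pants pocket and an accelerometer-only smartwatch on the
wrist — packaged as a fully synthetic, fully reproducible analysis
pipeline.

The pipeline targets nine everyday activities (walking, running, cycling,
standing, sitting, elevator ascent/descent, stair ascent/descent) plus a
separate indoor/outdoor detection task driven by the phone's GPS and
ambient-light sensors. Because no deposited field recordings exist for this
setting, the package ships a seeded generator of physically plausible
multi-rate sensor streams with ground-truth annotations; every downstream
stage is developed and validated against it.

## Who it is for

Researchers in mobile health / wearable sensing who want a transparent,
tested reference implementation of the classical feature-engineering HAR
stack: multi-rate ingestion, gravity/gait-band filtering, fixed windowing,
actigraphy-style features, classical classifiers, and GPS+light fusion —
with every numeric constant in one config object.

## The processing model

1. **Ingestion.** Irregular timestamped streams per sensor (phone
   accelerometer ≈ 90 Hz, magnetometer ≈ 25 Hz, gyroscope ≈ 27 Hz,
   pressure ≈ 5 Hz; watch accelerometer ≈ 15 Hz). Watch power-downs during
   sedentary bouts are bridged by hold-last-value filling; all streams are
   linearly interpolated to fixed rates (inertial 100 Hz; pressure and
   light 10 Hz). GPS fixes are never interpolated.
2. **Filter bank** (4th-order Butterworth, zero phase): static/gravity
   component below 0.6 Hz; dynamic gait band 0.6–7.5 Hz (accelerometer,
   magnetometer, gyroscope alike); pressure high-passed above 0.1 Hz to
   remove weather drift.
3. **Windowing.** Accepted annotated segments are cut into non-overlapping
   2-s windows.
4. **Features.** 53 phone attributes per window — activity counts
   (rectified integral ∑|x|·Δt), RMS counts, device angles from the gravity
   vector, coefficients of variation, periodogram max power / peak
   frequency / peak power / primary frequency, cyclical-peak step counts,
   double-integration displacement, and barometric altitude
   difference/slope via the international barometric formula — and the
   17-attribute watch accelerometry subset.
5. **Datasets & models.** Per-sensor column subsets, balanced (equal
   instances per class) and unbalanced variants, CSV/ARFF export; five
   classifiers (information-gain and Gini trees, Gaussian naive Bayes,
   one-hidden-layer MLP, RBF SVM) under stratified 10-fold CV; optional PCA
   projection keeping 95% of the standardized variance.
6. **Indoor/outdoor.** Per-window GPS features (circular-mean bearing,
   speed, altitude, satellite count, satellite SNR — absence of fixes reads
   as zero visibility) and light features (raw/low-passed mean lux, mean
   lux differential), evaluated GPS-only, light-only and fused.

## Worked example

```python
from actifuse import (simulate_cohort, build_dataset, train_eval,
                      simulate_transition_walk)
from actifuse.pipeline import cohort_feature_tables
from actifuse.features_geo import build_geo_table, detect_environment

tables = cohort_feature_tables(simulate_cohort(10, seed=0))
fused = build_dataset(tables["phone"], "phone", "fused")
report = train_eval(fused, "c45", folds=10, seed=0)
print(len(fused), report.overall_tp_pct)

walk = simulate_transition_walk(300.0, 300.0, seed=0)
geo = build_geo_table(walk.light, walk.gps, walk.segments)
env = detect_environment(geo, "nb")
print({k: r.overall_tp_pct for k, r in env.items()})
```

prints

```
2380 99.41176470588235
{'gps': 100.0, 'light': 100.0, 'fused': 100.0}
```

i.e. 2,380 phone windows from ten virtual subjects, of which the
information-gain tree recovers 99.4% out-of-fold (the synthetic activities
are nearly separable by design — the generator contract, not a field
result), and a perfect indoor/outdoor split: indoors the receiver holds no
satellites and lux sits ~50× below daylight, so either cue suffices and the
fusion never does worse.

The same computations run as numbered drivers:

```bash
python analysis/01_simulate_cohort.py      # raw recordings -> scratch/
python analysis/02_extract_features.py     # windows -> feature tables
python analysis/03_build_datasets.py       # subsets + balanced variants
python analysis/04_evaluate_classifiers.py # full 80-combination matrix
python analysis/05_indoor_outdoor.py       # GPS/light/fused detection
```

with compact result tables under `results/`. There is also a `actifuse`
CLI (`simulate`, `extract-features`, `build-datasets`, `evaluate`,
`detect-environment`, `report`) driven by one YAML config.

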