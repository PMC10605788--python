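# gaitsurf

Classification of walking-surface conditions from multi-sensor IMU gait
data with a 25-layer 1D convolutional network.

## The problem

Free-living fall-risk assessment interprets gait markers recorded by
wearable inertial sensors, but those markers confound biology with
environment: higher step-to-step variability can mean elevated fall risk
— or simply grass underfoot. Recognizing the walking surface from the
same IMU streams makes such assessments environment-aware.

`gaitsurf` implements a complete pipeline for this task: nine surface
conditions (paved flat-even `FE`, stairs up/down `StrU`/`StrD`, slopes
up/down `SlpU`/`SlpD`, grass `GR`, banked left/right `BnkL`/`BnkR`,
cobblestone `CS`), six sensor sites (wrist, both thighs, both shanks,
trunk), and 22 channels per sensor at 100 Hz grouped into seven signal
families (Acc, FreeAcc, Gyr, Mag, VelInc, orientation-increment
quaternion, yaw/pitch/roll). Because the cohort design is what matters
for the methodology, the package ships a synthetic multi-sensor gait
simulator that reproduces the study design (30 participants × 9 surfaces
× 6 trials, trial durations ≈ 16.4 ± 4.2 s, occasional fully missing
sensor recordings), so every stage is exercisable without downloading
data.

## Method

1. **Preprocessing** — second-order low-pass Butterworth smoothing
   (6 Hz cut-off, zero-phase), nearest-preceding-value repair of missing
   samples (subsequent value for leading runs), complete removal of
   trials whose required sensor stream is fully missing.
2. **Fusion and segmentation** — selected signal groups from selected
   sensor sites are stacked column-wise and cut into non-overlapping
   windows of L ∈ {100, …, 500} samples; each window is one input matrix
   (e.g. shank-pair Acc at L = 400 gives 400 × 6).
3. **Classifier** — a 25-layer 1D CNN: five blocks of
   Conv(k=3, s=1) → ReLU → BatchNorm → MaxPool(3, 3) with filter schedule
   64-64-128-128-128 and dropout 0.5 after the last three pools, then
   Flatten → Dense(9, softmax). Implemented on a small vectorized NumPy
   backend (`gaitsurf.nn`) with Adam, early stopping on validation
   accuracy (patience 25, best-weights restore) and
   reduce-LR-on-plateau (patience 10, factor 0.1).
4. **Evaluation** — trial-stratified 6-fold cross-validation (one trial
   per participant-surface pair per fold; folds never split a trial's
   windows), per-fold min-max scaling fitted on training folds only, and
   aggregated-prediction metrics: per-class and weighted precision /
   recall / F1 plus accuracy from the 9 × 9 confusion matrix.
5. **Experiment harnesses** — greedy forward selection over signal
   groups, rank-and-add selection over sensor sites, and a window-length
   sweep, each scored by cross-validated accuracy through an injectable
   evaluator.

## Worked example

```python
import gaitsurf as g

# a small, strongly separable synthetic cohort: 6 participants x 9
# surfaces x 2 trials, 100 Hz, six sensors
cfg = g.separable_config(n_participants=6, trials_per_condition=2, seed=1)
cohort = g.filter_dataset(g.simulate_cohort(cfg))

config = g.TrainConfig(epochs=20, patience_stop=8, patience_lr=3, seed=1)
result = g.cross_validate(
    cohort,
    groups=["Mag", "FreeAcc", "YPR", "Acc", "VelInc"],
    sensors=[g.Site.shankL, g.Site.shankR],
    window_length=100,
    train_config=config,
)
report = g.evaluate_predictions(result.y_true, result.y_pred)
print(f"aggregated CV accuracy: {report.accuracy:.3f}")
print(f"weighted F1:            {report.weighted_f1:.3f}")
```

Output on this cohort:

```
aggregated CV accuracy: 0.981
weighted F1:            0.981
```

meaning 98.1 % of the ~1650 windows across all six test-fold rotations
were assigned the correct surface; the weighted F1 averages per-class F1
with actual-class counts as weights. The same run with the wrist sensor
alone reaches only ≈ 0.68 — the simulator, like real gait, concentrates
surface information in the lower limbs.

More narrative walkthroughs live in `examples/` (simulation, filtering
and scaling, model inspection, cross-validation, greedy selection), and
a thin CLI wraps the same library calls:

```bash
gaitsurf simulate --preset separable --participants 2 --trials 1 --seed 3 --out runs/demo-data
gaitsurf run --data-dir runs/demo-data --groups Mag,Acc --sensors shankL,shankR -L 100 --epochs 5
```

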