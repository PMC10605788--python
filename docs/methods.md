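# Methods

This note documents the models, conventions, and numerical choices
behind `gaitsurf`, and what its synthetic experiments do and do not
demonstrate.

## Task and data model

The pipeline classifies nine walking-surface conditions from windows of
multi-sensor IMU gait data. A *trial* is one straight-walking recording:
per sensor site (wrist, thighR, thighL, shankR, shankL, trunk) a matrix
of 22 channels at 100 Hz — 3-axis acceleration (`Acc`), gravity-free
acceleration (`FreeAcc`), rate of turn (`Gyr`), magnetic field (`Mag`),
per-sample velocity increment (`VelInc`), the per-sample
orientation-increment quaternion (`Ori`, 4 channels), and yaw/pitch/roll
Euler angles (`YPR`). Surfaces carry fixed ordinals
(FE, StrU, StrD, SlpU, SlpD, GR, BnkL, BnkR, CS → 0–8) so confusion
matrices and reports always share an axis order.

Fused inputs are built by `channel_layout(groups, sensors)`: the outer
loop runs over signal groups in caller (selection) order, the inner loop
over sensors in a fixed canonical rank, then channels in catalog order.
Keeping the sensor loop canonical makes a layout a pure function of the
chosen sets, independent of the order in which a greedy search
discovered them.

## Synthetic cohort generator

`simulate_cohort` emulates the study design: `n_participants` × 9
surfaces × `trials_per_condition` trials (defaults 30 and 6), trial
durations drawn from N(16.4 s, 4.2² s²) truncated below at 6 s
(truncation avoids non-physical short trials; the source design reports
only mean ± sd), 100 Hz sampling, and optionally a fixed number of
trials (default 14) whose left-thigh stream is entirely missing.

Per sensor site the kinematic model is:

- **orientation(t)** = baseline + cadence-locked harmonic oscillation +
  white orientation jitter. The baseline yaw is a per-participant
  heading; surface effects shift pitch (slopes, stairs) or roll (banks)
  with opposite signs for up/down and left/right. The oscillation
  amplitude scales with a per-site gain (shanks 1.0, thighs 0.6, trunk
  0.35, wrist 0.15) and the surface's vertical-amplitude factor.
- **Gyr** is the analytic time-derivative of the oscillatory component
  (Euler rates standing in for body rates — adequate at these
  amplitudes) plus white noise; **YPR** is the orientation itself;
  **Acc** = R(orientation)ᵀ·[0, 0, −g] + cadence-locked body
  acceleration + noise; **FreeAcc** = Acc − gravity projection, exact;
  **Mag** = R(orientation)ᵀ·B_earth + noise; **VelInc** = Acc / 100,
  exact; **Ori** is the unit quaternion of the per-sample rotation
  Gyr·dt, exactly unit-norm. The rotation convention is intrinsic
  Z-Y-X (yaw-pitch-roll), declared once and used for Acc, Mag, and YPR
  consistently (cross-checked against `scipy.spatial.transform` in the
  tests). These identities make the generator self-consistent: tests
  verify them by recomputation on generated trials.

Surface effect defaults: stairs slow cadence (×0.7) and enlarge vertical
amplitude (×1.8) with a pitch shift; slopes shift pitch ±10°; banks
shift roll ±8°; grass and cobblestone raise orientation jitter (3–5×
the flat-even floor); flat-even is the low-noise reference. FE/GR/CS
therefore differ only in roughness and mild cadence factors and remain
the hardest triple, mirroring the difficulty ranking reported for real
data.

Two modelling choices concentrate surface information in the lower
limbs, as observed in real recordings: (1) surface baselines and
surface-roughness jitter are scaled by the site gain (a wrist does not
tilt with the slope the way an ankle-mounted sensor's mounting does once
arm posture is free); and (2) the wrist carries a large
surface-independent jitter floor (4° vs 0.2° at the lower limbs) and an
arm swing whose amplitude and phase are redrawn every trial —
involuntary upper-extremity movement is irregular, so cadence and
amplitude cues are masked at the wrist. Without (2) a classifier can
read the surface's cadence factor straight off a clean wrist signal and
the lower-limb advantage disappears.

Presets: `default_config` (the study-design conditions),
`separable_config` (doubled effect contrasts, reduced noise — a
desk-scale cohort a small network separates within ~20 epochs), and
`planted_mag_config` (identical kinematics on all surfaces; each surface
instead rotates the reference magnetic-field vector by a distinct yaw,
making `Mag` the only informative group; participant headings are fixed
so the field coding is not confounded with heading).

**What the synthetic cohorts do not show.** They contain no soft-tissue
artifact, no ground-reaction events, no drift, no real magnetometer
disturbances, and their class structure is planted by construction.
Passing the end-to-end tests demonstrates that the pipeline — fusion,
leakage-free scaling, the architecture, the training regimen, the fold
logic, the selection procedures — behaves correctly, not that the
published real-data accuracies are reproduced. Reproducing those
requires the original open dataset and full-scale training.

## Preprocessing

Order: smoothing → cleaning → combination → segmentation →
standardization.

- **Smoothing**: second-order Butterworth low-pass, 6 Hz cut-off,
  applied forward-backward (zero-phase) by default — the biomechanics
  convention, preserving gait-event timing; a causal single pass is
  available by flag. NaN samples are left in place; each maximal finite
  run is filtered independently and runs shorter than the warm-up pass
  through unchanged. Fully missing streams are not filtered — they go to
  the drop policy.
- **Cleaning**: missing samples take the nearest preceding value;
  leading runs take the first subsequent value. A channel with no
  observed values raises an unrepairable-channel error, and trials whose
  *required* sensors are absent or unrepairable are removed entirely
  (`drop_unusable`), with the dropped keys reported.
- **Segmentation**: non-overlapping windows from sample 0;
  ⌊n/L⌋ windows per trial, remainder discarded.
- **Standardization**: per-channel global min-max over all training-fold
  segments, mapping training data into [0, 1]. Validation/test values
  may exceed [0, 1]; they are deliberately not clipped (clipping would
  discard information). Constant channels map to 0. The scaler records
  the trial keys it was fitted from, so leakage is checkable.
  Per-segment scaling was rejected because it would erase inter-segment
  amplitude cues (e.g. rough-surface variance).

## Architecture

Five blocks of Conv1D(kernel 3, stride 1, zero "same" padding) → ReLU →
BatchNorm → MaxPool(size 3, stride 3), filters 64-64-128-128-128, with
dropout 0.5 after the pools of blocks 3–5, then Flatten and a 9-unit
softmax dense layer: 25 layers.

Pooling length arithmetic is **ceil-mode** by default (output
⌈n/3⌉): under floor-mode ("valid") arithmetic a 100-sample window
collapses to length 0 before the fifth pool, so ceil-mode is the only
scheme under which this exact layer stack accepts all five window
lengths 100–500. Floor-mode is available (`pool_mode="floor"`); under it
a 400-sample input flattens to 128 features and the parameter total is
140,041, whereas ceil-mode ends at length 2 and 141,193. Parameter
counts include the two non-trainable batch-normalization statistics per
channel (4 per channel total), and are verified against an independent
closed-form layer-wise sum in the tests.

The backend (`gaitsurf.nn`) is a small NumPy layer library written for
this model family: im2col convolution so the inner loops run in BLAS,
hand-derived backward passes (checked against central finite differences
in the tests), Glorot-uniform initialization under a run seed, and Adam.
Batch-normalization moving statistics use a cumulative average during
warm-up before switching to the exponential rule (momentum 0.99): with
short schedules a purely exponential update never leaves its 0/1
initialization, which silently ruins inference-mode predictions.

## Training and cross-validation

Adam (lr 0.001), batch size 32, sparse categorical cross-entropy, up to
100 epochs by default. Early stopping monitors validation accuracy
("no improvement" = not strictly better, min-delta 0) with patience 25
and best-weights restore; the learning rate is multiplied by 0.1 after
10 stagnant epochs (floor 1e-6). Monitoring validation loss instead is a
flag.

Folds partition *trials*: each (participant, surface) pair contributes
one trial to each of the 6 folds when six trials exist; pairs with fewer
trials are spread round-robin over a seed-shuffled fold order. For test
fold k the validation fold is (k mod 6) + 1 — the 4/1/1 split is fixed
by design, and the deterministic rotation makes runs reproducible. The
scaler is refitted inside every rotation on its training folds. Train/
validation provenance overlap raises a hard `LeakageError`. Class
imbalance (unequal per-class window counts from unequal trial durations)
is left unweighted in the loss; the weighted metrics report its effect.

## Metrics

Rows of the confusion matrix are actual classes, columns predicted.
Recall_i = e_ii / row-sum, precision_i = e_ii / column-sum, F1 their
harmonic mean, 0/0 ≡ 0; weighted averages use actual-class counts, which
makes weighted recall algebraically equal to accuracy (asserted
exactly in the tests). The printed equations in some sources transpose
the precision/recall indices while their figure captions use the
row-based convention; `paper_literal_eqs=True` reproduces the
transposed form.

## Selection harnesses

- **Signal groups**: sequential forward selection — score all 7 groups
  singly, then repeatedly extend the current set by each remaining group
  and accept the best strictly improving candidate; stop when none
  improves. Replaying the published accuracy table yields the published
  count of 27 evaluations.
- **Sensors**: score all 6 sites singly, rank descending (ties broken by
  canonical site rank), walk the ranked list keeping each addition only
  on strict improvement; if anything was rejected, one closing
  all-sensor configuration is evaluated (the published table contains
  exactly such a final row), giving 12 evaluations on the replay.
- **Window sweep**: one evaluation per length in {100, …, 500}.

Accuracy comparisons use full floating precision; exact ties reject the
addition, preferring the smaller configuration. All candidates within a
search share one fold plan and seed so they differ only in
configuration. Evaluators are injectable: production uses 6-fold
cross-validation; a single-rotation holdout evaluator
(`make_holdout_evaluator`) is provided for screening at one-sixth the
cost, and mock tables drive the schedule tests.

## Scaled-down experiment sizes

The self-contained experiments run on one CPU core: the end-to-end
check uses the separable preset at 6 participants × 9 surfaces × 2
trials, L = 100, 20-epoch schedule (≈ 1 650 windows, ~2 minutes per
sensor configuration); planted-signal recovery uses 4 participants × 1
trial with the holdout evaluator and 8-epoch trainings; fold-plan
structure is exercised on the full 30 × 9 × 6 design with stub-length
trials, since the plan depends only on trial keys.

## Known limitations

- The NumPy backend targets this architecture family; it has no GPU
  path, no autograd, and no serialization of optimizer state (weights
  round-trip via `get_weights`/`set_weights`).
- The generator's difficulty ordering is planted, not emergent; absolute
  accuracies on synthetic cohorts say nothing about real-data accuracy.
- The reader for external deposits handles the package's own canonical
  CSV schema (site-prefixed channel names plus a manifest); mapping a
  third-party deposit's layout onto it is the caller's responsibility
  and fails loudly on unresolvable columns.
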