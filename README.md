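# vrmotion

Kinematic analysis and classification of coordinated bimanual upper-limb
movements recorded by consumer VR hardware, aimed at telerehabilitation
research: given the 6-DoF pose streams of a head-mounted display (HMD) and
two hand controllers, the package quantifies a user's motor performance and
recognizes which prescribed bimanual gesture is being performed at every
instant.

## The pipeline

The input is a multivariate time series sampled at 89 Hz: for each device a
3-D position in the global frame {G} (meters) and an orientation as
Tait-Bryan angles γ, β, α about the X, Y, Z axes (radians).  Because a VR
user walks and turns freely, hand poses are expressed relative to the
head-centric frame {H}: with the HMD at (R_GH, P_GH) and a controller at
(R_GC, P_GC),

    R_HC = R_GHᵀ · R_GC,      P_HC = R_GHᵀ · (P_GC − P_GH),

the inverse homogeneous transform of the head pose.  From these the
pipeline builds a 30-variable table per time step (HMD linear/angular
velocities in {G}; per controller: position and orientation in {H},
linear/angular velocities in {G}) and proceeds through five stages:

1. **Calibration** — the user repeats each of 5 bimanual gestures
   (reach right, reach left, raise, lower, push forward) 5 times.  The
   per-axis average maximal excursion of the controller midpoint relative
   to the head, D̄ = (1/5)·Σₙ maxₜ |P_h,n(t) − P_H,n(t)|, sets cursor
   thresholds at 0.25·D̄, so a user with limited range of motion drives
   the interface with proportionally smaller movements.
2. **Segmentation** — the speed statistic Ω(t) (mean of the two
   controllers' finite-difference speeds) is thresholded at 0.077 m/s for
   longer than 0.2 s; consecutive interval pairs (outward + return, with
   the enclosed dwell) form one repetition segment.
3. **Motor metrics** — per arm and movement: range of motion, mean speed,
   smoothness (mean/peak speed), path length.
4. **Saliency** — per segment, each variable is normalized by its own SD,
   the 30×30 covariance matrix is eigendecomposed, and spectral gaps
   (largest consecutive drop in sorted eigenvalues, then in absolute
   loadings) select the dominant components and the variables that
   characterize each gesture.
5. **Classification** — a 13-step moving window (0.15 s) yields 21
   features (12 relative-pose means, 6 orientation SDs, 3 left-right
   angle correlations) and a mode-based true class; a bagged ensemble of
   decision trees is evaluated by stratified 5-fold cross-validation, and
   feature importance is scored by out-of-bag permutation.

No public recordings accompany this protocol, so the package ships a
first-class synthetic generator (`vrmotion.synthetic`) that emulates the
calibration session — minimum-jerk reaches with gesture-specific coupled
angle excursions, plus a realistic tracking-noise model — and provides
ground truth for every stage.

## Worked example

```python
import vrmotion as vm

session, truth = vm.generate_calibration_session(seed=1)
table = vm.assemble_variable_table(session)
segments = vm.segment_session(session)
print(f"{len(session)} time steps -> {len(segments)} segments")

results = vm.SaliencyModel(table, segments).fit()
print(results.summary())

dataset = vm.build_dataset(table)
fit = vm.MovementClassificationModel(dataset, n_trees=30).fit(seed=1, importance=False)
print(fit.summary())
```

prints (abridged):

```
7621 time steps -> 25 segments
Saliency analysis (spectral-gap PCA)
========================================
segments: 25; dominant components per segment: {1: 13, 2: 12}
     right: gamma_H_R, X_H_R, X_H_L, gamma_H_L, alpha_H_L, alpha_H_R, ...
        up: Y_H_R, Y_H_L, beta_H_R, gamma_H_R, alpha_H_R, gamma_H_L, ...
Bagged-trees movement classification
========================================
windows: 7608; features: 21; trees: 30; seed: 1
5-fold CV accuracy: 0.9627
per-class true-positive rates:
          down: 0.9539
   no_movement: 0.9839
         ...
```

The 25 segments are the 5 gestures × 5 repetitions recovered purely from
the speed statistic; the salient sets contain each gesture's programmed
driving angles (e.g. γ and α of both controllers for the lateral reaches);
the classifier labels 13-step windows with ~96% cross-validated accuracy
on this synthetic session.

The same stages are available from the shell:

```sh
vrmotion simulate --seed 1 --out out
vrmotion run --seed 1 --out out          # full pipeline with manifest
```

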