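# Methods

## Coordinate conventions and kinematics

Poses arrive as global-frame positions (m) and Tait-Bryan angles (rad):
γ about X, β about Y, α about Z.  Consumer VR runtimes do not expose the
rotation order of their logged Euler angles, so the composition order is a
configuration choice; the default is intrinsic Z-X-Y, the order used by
the Unity engine family that drives most commercial headsets.  All angle
math goes through `scipy.spatial.transform.Rotation`, and the choice only
matters jointly: the same convention must be used for composing device
rotations and for decomposing relative rotations back to angles.  Which
individual angle variables appear salient for a gesture depends on the
convention; the relative rotation matrices themselves do not.

Controller poses are re-expressed in the head frame {H} via the inverse
homogeneous transform of the HMD pose, `R_HCᵀ = R_GHᵀ R_GC`,
`P_HC = R_GHᵀ (P_GC − P_GH)`.  Velocities are forward finite differences
(configurably central) of the global-frame coordinates; angle series are
unwrapped before differencing so angular velocities carry no 2π wrap
spikes.  The stencil costs one row: an N-step session yields an
(N−1)-row variable table, and per-step labels are truncated to match.
Angular velocity is computed per angle (the derivative of each unwrapped
Tait-Bryan coordinate), not as a body-frame rate vector, because the
analysis treats each of the 30 variables as an independent scalar series.

## Segmentation

Ω(t) is the mean of the two controllers' instantaneous speeds ‖ΔP‖/Δt.
The mean rule (rather than max or midpoint-speed) is the default because
the protocol's gestures are bimanually symmetric — the two speeds are
nearly equal — and averaging halves one-sided jitter.  Movement intervals
are maximal runs with Ω above 0.077 m/s lasting strictly longer than
0.2 s; a run of k samples spans (k−1)·Δt, so the criterion keeps runs of
at least ⌈0.2/Δt⌉+1 samples (19 at 89 Hz).  Both thresholds are
per-session configuration: they are empirical, participant-specific
quantities, and the defaults are the protocol's operating values.
Interval roles alternate outward/return by position, relying on the
protocol's excursion–return structure; no trajectory-shape analysis is
attempted.  Consecutive interval pairs plus the enclosed dwell form one
repetition segment; class labels follow the fixed protocol order (right,
left, up, down, forward; 5 consecutive repetitions each).  Indexing is
0-based and half-open throughout.

## Motor-performance metrics

Range of motion is the maximum distance of a controller from the headset
along an anatomical axis of {H} (X mediolateral, Y vertical,
Z anteroposterior; configurable).  Note this is a distance from the head,
so it includes the arm's baseline offset, not just the excursion
amplitude.  Mean speed, smoothness and path length are computed on the
movement intervals of a segment only — the dwell between excursions
describes holding still, not moving.  Smoothness is mean speed divided by
peak speed, which lies in (0, 1] (1 = constant speed; a minimum-jerk
reach scores exactly 8/15 ≈ 0.533).  Some clinical reports quote the
reciprocal ratio (values above 1); the reciprocal is available via
`smoothness(..., invert=True)` but the bounded form is the default.
Motionless input makes the ratio undefined and returns NaN.

## Spectral-gap PCA saliency

Within each segment, every variable is divided by its own within-segment
SD (population, ddof=0; zero-SD columns pass through with a flag), so the
covariance matrix is in effect a correlation matrix and each column can
contribute at most unit variance.  The covariance is the divide-by-N
mean of products of mean-removed columns, eigendecomposed with `eigh`.
Dominant components are the eigenvalues preceding the largest consecutive
difference of the descending spectrum; ties break toward fewer components
(parsimony).  Within each dominant eigenvector the same largest-drop rule
on sorted absolute loadings selects the salient variables; eigenvector
sign is irrelevant.  Per-gesture salient sets are the union over the
five repetitions, ordered by occurrence count.

A single out-and-back reach actually carries two temporal courses — the
displacement profile s(t) shared by all pose variables, and its
derivative shared by the velocity variables.  In data with realistic
sample-level orientation jitter the differentiated angular velocities are
heavily noise-attenuated, so the displacement component dominates and the
spectral gap typically falls after the first eigenvalue; the velocity
course survives as a weaker second component that occasionally (≈ 40% of
segments at default noise) captures the gap.  The modal dominant count
over many segments is 1.

## Windowed features and classification

A 13-step (0.15 s) window slides with stride 1.  Its true class is the
mode of the per-step labels (≥ 7 of 13); the only possible ties involve
three or more classes in one window and break deterministically toward
the class occurring earliest in the window.  Features are the means of
the 12 controller-in-{H} pose variables, the sample (ddof=1) SDs of the
6 controller orientation angles, and the Pearson correlations of the
three homologous left–right angle pairs — 21 in total.  An alternative
SD set (right-controller position + orientation) is available via
`FeatureSpec`, preserving the 21-feature count.  Zero-variance columns in
a correlation pair report 0.

The classifier is bagging over full-depth Gini decision trees
(scikit-learn underneath), every tree trained on a with-replacement
resample of the training set size, all features candidates at every
split.  Prediction is a simple majority vote with ties broken toward the
first class in sorted order.  The ensemble size default is 100 trees and
is deliberately configurable: it is a free parameter of the method, not a
protocol constant.  Evaluation uses stratified, seed-shuffled 5-fold
cross-validation with pooled out-of-fold predictions.  Stratification is
a design choice; when windows from several participants are pooled,
adjacent overlapping windows can fall into different folds, so
cross-validated accuracy should be read as optimistic with respect to a
leave-participant-out protocol (participant grouping can be emulated by
evaluating per-session datasets separately).  Feature importance is
out-of-bag permutation importance: for each tree, the increase in error
on its out-of-bag rows when one feature's values are shuffled, summed
over trees and reported as a positive "error increase" score.

## Synthetic sessions

The generator emulates the calibration protocol: a standing user
(HMD ≈ 1.6 m, hands near the shoulders) performs 5 gestures × 5
repetitions in protocol order, with baseline dwells (0.8 s) between
repetitions and a hold (0.6 s) at full extension.  Reaches follow
minimum-jerk (quintic) profiles over 1.0 s — the standard point-to-point
model, chosen for its closed forms: mean speed A/T, peak 1.875·A/T,
mean/peak = 8/15.  Default amplitudes are comfortable adult excursions
(0.40–0.50 m per gesture).  Each gesture also drives a programmed set of
controller Tait-Bryan angles (amplitude 0.6 rad) with the same profile,
emulating the coordinated forearm pronation and shoulder rotation of the
real gestures; these driving variables are the saliency ground truth.

Sensor noise has two parts, both configurable: a slow first-order
autoregressive jitter (stationary SD 2 mm position / 0.5° orientation,
correlation time 1 s) modelling postural sway and tracking drift, and
per-sample white measurement noise (0.1 mm position, 0.7° orientation)
modelling quantization and IMU-fused orientation error, consistent with
published accuracy characterizations of consumer VR tracking.  Purely
white position noise of millimetre scale would be unphysical here: at
89 Hz it would put the finite-difference speed floor near 0.4 m/s, far
above any usable movement-detection threshold, so the position error
budget is dominated by the correlated term.  The white orientation term
is what makes differentiated angular velocities noisy, as in real data.

The generator does not simulate a joint chain (shoulder/elbow angles);
it works at the end-effector + orientation level, which is exactly what
the sensors observe.  Consequences for interpreting green tests: passing
says the pipeline recovers what this kinematic world programs in —
counts, amplitudes, salient angle sets, separable window classes.  It
does not certify accuracy figures on human recordings, where
inter-participant variability, asymmetric and curved reaches, and
non-stationary noise will lower every score.  The impaired-session
variant (one arm with scaled amplitude, stretched reach time and a
multi-peak, pause-separated sub-reach profile) exists to verify metric
sensitivity, not to model any clinical population.

Ground truth stores, besides per-step labels (movement steps carry the
gesture class; dwells and holds are `no_movement`), the interval
boundaries the detector finds on the noise-free speed statistic.  These,
not the programmed movement onsets, are the right oracle for boundary
accuracy: a minimum-jerk reach needs several samples to exceed the speed
threshold, so onset-based truth would be biased by construction.

## Numerical choices and degenerate inputs

- Rotation orthonormality is validated to 1e−6 on input and asserted to
  1e−9 in tests; relative-pose round trips hold to < 1e−9 m.
- Zero-excursion calibration axes are disabled with a warning rather than
  given zero thresholds (which would make the cursor hair-triggered).
- An odd interval count drops the dangling final interval with a warning;
  an interval surplus or deficit relative to the protocol warns but
  proceeds.
- Single-class training data degenerates to a constant predictor with a
  warning.
- Problem sizes in the test-suite and acceptance script — full 5×5
  sessions (~7,600 steps), 100-seed segmentation sweeps, 100-segment
  saliency ensembles, 10–100-tree ensembles — were chosen so every
  statistical check runs at full protocol scale while the whole suite
  completes in about a minute on one core.
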