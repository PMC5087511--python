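# Methods

`posewatch` turns streams of tracked body-joint coordinates into three
decisions: *which static posture is held* (for remotely guided
rehabilitation), *has the subject fallen* (for in-home telecare), and *should
an alarm escalate*. This note describes the models behind those decisions,
the synthetic data they are validated on, and the choices made where the
design was genuinely open.

## The feature pipeline

A frame is a timestamped map from 14 named joints (head, center shoulder,
shoulders, elbows, hands, hips, knees, feet) to 3D positions in meters
(camera frame: x right, y up, z depth). A joint is either tracked — it has a
position — or absent; every consumer declares which joints it needs and
receives an explicit joint-missing signal otherwise.

Features fed to the networks are normalized coordinates in [0, 1]:

1. **Anchor.** Each frame is translated to a body-anchored origin: the
   shoulder midpoint for upper-body joint sets, the hip midpoint for
   lower-body sets. Fall windows are instead anchored at
   `(head.x, standing_head_y, head.z)` of the window's first frame, so the
   vertical coordinate measures *descent from standing height*.
2. **Scale.** Coordinates are divided by the subject's calibrated stature.
3. **Range.** The affine map `v -> (v + 1) / 2` takes [-1, 1] to [0, 1];
   values outside are clipped.

The anchor makes features invariant to where the subject stands (including
camera distance), and the stature scale makes proportionally built subjects
of different heights indistinguishable — the property behind the observation
that subject characteristics do not move the results. Sigmoid units expect
inputs in [0, 1], which fixes the output range.

Subject calibration is an enrollment step: stature can be estimated from one
clean frame as `head.y - mean(detected feet y)` (single-foot fallback
permitted, for robustness to partial tracking), and `standing_head_y` is the
head height observed while standing, recorded *in the stream's own
coordinate frame* — under a pitched camera vertical extents foreshorten by
`cos(angle)`, and the calibration must foreshorten with them.

A deliberately simple geometric baseline is included for stance: standing is
declared when the head-to-knee vertical distance is at least 2/3 of stature
(the ratio roughly halves when seated; the boundary case is assigned to
standing as a fixed tie-break). It illustrates why a single-threshold rule
is too crude for general posture work — its accuracy collapses once bodies
deviate from the assumed proportions — and serves as a template sanity check
for the simulator.

## The network

All three classifiers are the same estimator: a fully connected perceptron
with one hidden layer,

    y_j = f( sum_i w_ji x_i - theta_j )
    o_k = f( sum_j w'_kj y_j - theta'_k )

trained by full-batch gradient descent on the summed squared error

    E = 1/2 * sum_p sum_k (d_k^p - o_k^p)^2

with the classical backpropagated deltas (output delta
`(d - o) f'(v')`, hidden delta `(sum_k delta'_k w'_kj) f'(v)`). Biases are
weights on a constant -1 input, which is why they enter with a minus sign.
Design points:

* **One hidden layer exactly.** The layer count is not configurable; the
  error and update equations above define a single hidden layer, and every
  study here uses it.
* **Step normalization.** The per-epoch update is the summed per-pattern
  update scaled by 1/P (P = number of patterns). The raw summed step grows
  linearly with the training-set size; at the default learning rate 0.3 on a
  632-pattern set it saturates every sigmoid output and never recovers,
  while the normalized step trains to 100% accuracy. `max_error` (the stop
  threshold, default 0.01) is still defined on the *sum* scale of E, so on
  realistic set sizes training typically runs to `max_epochs` (default
  20000) with `converged=False` — which is a recorded outcome, not an error.
  The CLI can additionally report the per-pattern MSE.
* **Initialization.** Weights and biases start uniform in [-0.5, 0.5] from a
  seeded generator; training is bit-reproducible given the seed, and every
  serialized model records it.
* **Transfer functions.** Logistic sigmoid by default. The tanh variant uses
  tanh hidden units and an output layer affinely rescaled to (0, 1) —
  without the rescale, 0/1 one-hot targets are unreachable and the
  comparison between transfers cannot be run.
* **Hidden sizing.** The heuristic `round(2 (n_in + n_out) / 3)` gives 13
  for both posture topologies; the shipped defaults are the empirically
  better 12 (upper) and 10 (lower), and the heuristic remains the default
  for other joint sets (e.g. 21 for the 30-input fall network).
* **Decoding.** The predicted class is the argmax output provided it
  reaches a confidence threshold (default 0.5) and beats the runner-up by a
  margin (default 0.05); otherwise the decoder returns `none`. Ties resolve
  to the lowest output index before the margin rule rejects them.

Gradient correctness is anchored by the suite's central oracle test:
analytic gradients (recovered from a single training step) agree with
central finite differences of E to 1e-6 on random 4-3-2 and 15-12-5
networks, for both transfers.

## The three classifiers

* **Upper body** (5 classes: both arms raised, right arm raised, left arm
  raised, arms outstretched, both arms down): 5 joints x 3 coordinates = 15
  inputs. The shoulder pair is represented by its midpoint — which is also
  the normalization anchor — so the joint set is center shoulder, elbows and
  hands; an 18-input variant with both individual shoulders is available by
  configuration. Which joint the original 15-coordinate design dropped is
  not recoverable; this choice is documented, not asserted as historical.
* **Lower body** (standing/sitting): hips, knees and feet, 18 inputs,
  hidden 10.
* **Fall** (fall/no-fall): a sliding window of 10 consecutive head
  positions at 30 fps (~0.33 s), 30 inputs. A single static head position
  cannot express an *abrupt* movement; the window is the smallest temporal
  context that separates a fall (~2-3 m/s descent ending near the floor)
  from sitting down quickly (~0.6 m/s ending at chair height). Windows are
  broken by head dropout: only consecutive tracked frames are classified.

## The alarm state machine

Fall observations drive a four-stage escalation — Normal, Abnormal (fall
observed, timer running), Urgent (down longer than `safety_time`), Emergency
(down longer than `safety_time + urgent_grace`; alarm fires and the stage
latches until an authorized manual reset). Standing back up discards the
episode from Abnormal or Urgent. Defaults: `safety_time` 10 s,
`urgent_grace` 5 s — the escalation delays are deployment policy, not
measured quantities. Further semantics:

* the timer starts only on the Normal -> Abnormal transition; continuous
  fall observations never restart a running episode;
* head-not-visible frames leave the timer running, so a subject who falls
  out of view still escalates;
* time-driven escalation is applied before the frame's observation, so a
  stand-up that arrives after the alarm is already due cannot outrun it;
* "standing back up" is debounced: the lower-body classifier must report
  standing *and* the head must have recovered to 80% of its standing height,
  continuously for 0.5 s — a single flickered frame does not discard an
  episode;
* the alarm action is a pluggable hook (default: a structured log line);
  actual alert delivery is out of scope.

The rehabilitation driver walks an ordered plan of target postures. An
*attempt* is a 2 s evaluation window that succeeds when at least 70% of its
frames classify as the target; each posture gets a bounded number of
attempts (default 3) before the session moves on, and an exhausted stream
marks the remaining postures not-attempted. The exported session report
(JSON, schema-versioned) is the artifact a remote therapist would receive.

## The synthetic scene

No recordings of the original six subjects exist, so the simulator defines
the study conditions:

* **Subjects.** Stick figures parameterized by stature and segment ratios;
  the default pool is six subjects with statures evenly spaced 1.50-1.95 m.
  The tracked foot joint sits at ankle height (4% of stature).
* **Postures.** Joint-angle templates for all seven classes. Seated, the
  pelvis drops by 0.26 stature and knees/feet slide toward the camera;
  arm elevation angles define the upper-body classes. All templates are
  mutually separated by more than 3x the default pose jitter (0.02 m).
* **Motion.** Scripts compose timed events: posture holds, falls (descent
  drawn from 0.5-1.0 s, quadratic ease-in, head coming to rest at 0.2
  stature), quick-sit (0.8 s descent to the seated pose), bend-down (head
  drop <= 50% of stature with recovery), stand-up.
* **Camera.** A pinhole with 58 deg x 50 deg field of view aimed slightly
  above mid-height (0.575 stature, so floor-level feet and overhead hands
  both fit at the 2.5 m working distance), a 0.8 m minimum sensing depth
  (the physical floor of structured-light sensors — the cause of the
  sub-1 m failure regime), additive Gaussian coordinate noise (4 mm,
  growing linearly beyond 4.5 m depth), and a vertical-view tracking-loss
  model: beyond 35 deg of camera elevation the skeleton fitter loses the
  whole body on a linearly growing fraction of frames (saturating ~97% by
  50 deg), because the tracker's body model assumes a roughly frontal view.
  Horizontal subject rotation does not impair tracking. Joints outside the
  frustum are reported undetected, and visibility is monotone in distance
  within the working range.
* **Datasets.** Posture datasets are stratified (class counts within one),
  shuffled, and rendered with 0.02 m pose jitter; frames that lose a
  required joint to the frustum are re-recorded, mimicking an operator
  holding the pose until it is tracked cleanly. Distractor poses — used to
  measure rejection of unknown configurations — draw random arm elevations
  (or intermediate stances) and keep only candidates at least 3 jitter
  sigmas from every class template. Fall-window sets mix scripted falls
  with standing/seated holds and both confounders.

What the simulator does **not** model: occlusion by furniture or by the
subject's own body, tracker identity swaps and non-Gaussian error bursts,
clothing/lighting effects, and multi-person scenes. Passing results
therefore demonstrate that the pipeline's mechanisms behave as designed
under controlled geometry — not field accuracy on real depth-camera data.

## Evaluation conventions

Rates are computed over *trials* (one rendered situation: a held posture, a
scripted fall, a confounder), never over frames. Positive and negative
trials form separate pools: TP% is detected targets over positive trials,
TN% is correct rejections over negative trials, and FP/FN are their
complements — the only reading under which all four printed columns of the
reference tables are mutually consistent.

The four sweeps (hidden-layer size, training-set size, camera distance,
camera/subject angles) regenerate data, retrain and re-evaluate per
condition and seed (default 5 seeds, means reported), and emit tidy CSV plus
a rendered text table. The headline benchmark trains at the optimal
configuration (upper 15-12-5 and lower 18-10-2, sigmoid, 632/735 training
samples), evaluates 500 held-out frames and 500 distractors per body half,
and drives 100 scripted fall sequences per camera condition through the
full monitor. At these sizes the whole benchmark runs in a few minutes on
one CPU; they are the package's reference problem sizes.

## Known limitations

* **Open-set rejection is weak by construction.** A sigmoid network trained
  to saturation under squared error emits confident (~1 vs ~0) outputs
  almost everywhere off the training manifold, so the confidence-threshold
  decoder rejects only a thin sliver near decision boundaries. Measured on
  random intermediate poses, rejection is a few percent — far below the
  in-distribution accuracy. Genuine unknown-pose rejection needs a
  different mechanism (a background class, density estimates, or calibrated
  probabilities); the threshold rule is kept because it is the specified
  decoder.
* At the close end of the working range (~1-1.3 m) a fast fall can cross
  the narrow visible band in fewer frames than one window, and the fallen
  head rests below the view: a small percentage of such falls never
  produce a classifiable window. This is the residual miss rate visible in
  the distance study.
* The seated pose of the tallest subjects puts the ankles at the very edge
  of the vertical field of view at 2.5 m; such frames are re-recorded
  during dataset generation and can be joint-missing at inference.
* Escalation timing defaults (10 s + 5 s) and the stand-up debounce are
  policy choices; deployments should set them clinically.
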