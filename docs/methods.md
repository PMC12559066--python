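# Methods

## Problem and scope

`liftload` estimates the *category* of a lifted or lowered load (light,
medium, heavy) from 2D body-keypoint trajectories recorded from the side
(sagittal view). The premise is biomechanical: the motion of body segments
is shaped by the forces acting on them, so kinematics observable in video
carry information about the load. The package starts at the keypoint
boundary — person detection, pose estimation and tracking are upstream
concerns — and covers feature extraction, sequence classifiers, the
training/evaluation protocol, and a seeded motion simulator that stands in
for human-subjects recordings.

## Kinematic features

Each instance is a COCO-17 keypoint track clipped to one lift or lower.
Because only one body side is visible in side view, seven joints are kept:
head (the COCO nose point is used as the head proxy — COCO-17 has no
head/neck landmark and the nose is the most stable face point in profile),
plus the visible-side shoulder, elbow, wrist, hip, knee and ankle. The
visible side is the one with higher mean limb-keypoint confidence, ties
going to the right.

Per frame the feature vector has 47 entries in fixed order `[r | ang | v | a]`:

- `r` (14): joint positions re-centred on the per-frame person-box centre
  and divided by the maximum box height seen in the sequence. One global
  scale plus per-frame centring makes the features invariant to uniform
  scaling and translation of the image (verified to 1e-9 in tests).
- `ang` (5): unsigned inter-segment angles at the shoulder (head-shoulder
  vs shoulder-elbow and shoulder-elbow vs shoulder-hip), elbow, hip and
  knee, computed as arccos of the clamped normalised dot product of the
  two segment vectors from the shared joint. The unsigned convention in
  [0, pi] was chosen because it makes the horizontal-mirror augmentation
  exact on this slice; the field also uses signed conventions, but nothing
  downstream needs the sign. A segment shorter than 1e-6 px carries the
  previous frame's angle forward (isolated tracker glitches should not
  void an instance); a degenerate first frame is an error.
- `v`, `a` (14 + 14): central-difference velocity and acceleration of `r`
  (one-sided at the boundaries), in per-frame units. The sequence fps is
  kept as metadata, so per-second units are a multiplication away; at a
  fixed frame rate the classifiers are covariant to this choice.

Mirroring negates the x columns of `r`, `v`, `a` and fixes everything
else; it is an involution used both as training augmentation and at test
time.

## Models

All models consume zero-padded batches with a validity mask and are
padding-invariant: masked frames are zero-filled before every convolution
(so a same-padded convolution sees exactly what it would see on the
truncated sequence), excluded from the attention softmax support, and
excluded from temporal pooling. Tests verify each model against an
unpadded oracle to 1e-5.

The main model is a Transformer: two temporal convolutions (kernel 3,
stride 1, ReLU between) project 47 -> D per frame; a learned positional
table of shape max_len x D is added (a sinusoidal table is a config
switch); L pre-norm residual blocks follow, each with multi-head
self-attention (scores Q K^T / sqrt(D/heads), row-wise softmax) and an
MLP of width `mlp_ratio * D`; masked average pooling over time feeds a
linear classification head (an MLP head is a config switch). Defaults:
D = 4 x 47 = 188, L = 2, 4 heads, mlp_ratio 4, dropout 0.1 on attention
weights, projections and residual paths (stochastic depth). Dropout is
active only in training mode.

Baselines: a 1D residual CNN (depthwise convolution projection, two
residual conv blocks, masked average pooling, linear head) and a
bidirectional LSTM (conv projection, two BiLSTM layers; the head reads the
forward state at the last valid frame concatenated with the backward state
at frame 0). Baseline widths (64) are package constants — reasonable
defaults, not claims about any reference system.

The networks are implemented directly in NumPy with hand-written backward
passes (`liftload.nn`). Gradients are exact (finite-difference-checked
during development; the attention and block oracles in the test suite pin
the forward math), and training is bitwise reproducible for a fixed seed
on a single thread.

## Training protocol

Cross-entropy loss; AdamW (decoupled weight decay 0.05, applied to weight
matrices only); learning rate 1e-3 by default with linear warmup then
cosine annealing to zero; batch size 32; 100 epochs (10 warmup) as the
reference schedule. Each epoch every training sequence is mirrored with
probability 0.5 and perturbed with i.i.d. Gaussian noise (sigma 0.01).
The final-epoch model is used — no early stopping or validation split.
At inference the model is applied to the sequence and its mirror and the
two probability vectors are averaged (test-time augmentation); averaging
probabilities rather than logits reads "average the outputs" in its
post-softmax sense.

Two choices the protocol description leaves open are fixed as follows:

- **Input standardisation.** Per-channel mean/sd are fitted on the raw
  training frames of each fold and stored with the model. The per-frame
  velocity/acceleration channels are roughly two orders of magnitude
  smaller than positions and angles; without standardisation they are
  effectively invisible to the optimiser and training is erratic.
- **Noise units.** The augmentation noise is added in standardised units,
  so sigma = 0.01 means one percent of each channel's own spread. Added in
  raw units the same sigma would be negligible for positions but several
  standard deviations for velocities, destroying exactly the channels
  that carry the load signal.

Load categories use the study bins — light 2.7-5.4 kg, medium 6.8-9.5 kg,
heavy 10.9-13.6 kg; a load in no bin is an error, never silently rounded.
The binary setting (light vs heavy) drops medium instances from training
and testing alike.

Two split protocols: leave-one-subject-out (one fold per subject), and a
stratified intra-subject split that deals each (subject, category,
posture) cell round-robin across n folds (default 3), holding out about a
third of every cell; cells smaller than the fold count stay in training
and are logged. Accuracy is aggregated per fold and reported as
mean ± sd across folds (sd with one delta dof); the instance-pooled
accuracy is also kept because fold sizes differ.

McNemar's test compares paired predictions: with b/c the discordant
counts, the exact two-sided binomial test is used for b + c < 25 and the
continuity-corrected chi-square otherwise (statsmodels supplies both; the
test suite checks the exact branch against an independent enumeration for
all b + c <= 12). Two identical prediction vectors give p = 1 by
convention.

## The synthetic study

The simulator emulates the structure of a 19-participant laboratory
study: 3 postures (mid-shin, knuckle, shoulder) x 9 loads
{2.7 ... 13.6 kg} x {lift, lower}, full factorial = 1026 instances,
rendered at 30 Hz in a 1920x1080 frame.

Each subject gets a stature drawn from Normal(1.7 m, 0.1 m) truncated to
[1.4, 2.1], segment lengths as standard anthropometric fractions of
stature (shank 0.246, thigh 0.245, hip-shoulder 0.288, upper arm 0.186,
forearm 0.146, shoulder-head 0.130), and a multiplicative tempo effect
drawn log-normally with sd 0.05 — a modest, realistic between-subject
spread in movement speed. Each instance adds log-normal tempo jitter with
sd 0.03.

Within an instance, the wrist follows a minimum-jerk path (the standard
smooth-reaching model; any smooth monotone profile would serve) between
the posture's start height (mid-shin 0.162, knuckle 0.44, shoulder 0.818
of stature) and a carry height of 0.63 stature; lowering reverses the
path exactly. The hip crouches as the wrist drops; knee, trunk flexion
and elbow close the chain by circle-circle intersection, so all segment
lengths are constant within an instance before rendering noise (asserted
to 1e-6 relative in the tests; measured drift is at float64 rounding). Joints are projected to COCO-17 pixels, the occluded
side is drawn as a copy at confidence 0.2 (so side selection is exercised
realistically), eyes/ears are placed near the head point, 1 px Gaussian
jitter is added, and a tight per-frame box over confident keypoints is
computed.

The load enters only through tempo: duration = T0 (1 + beta * load/13.6)
x subject tempo x jitter, with T0 = 2.2 s and beta = 0.5 by default,
giving 61-119 frames and a heavy/light duration ratio of about 1.36.
Because the wrist travel is fixed, heavier loads also mean lower peak
wrist speed, the qualitative signature reported for real lifts. This is a
deliberately first-order coupling: real lifting also changes postural
strategy, smoothness and asymmetry with load, none of which the default
generator emulates. Passing the recovery tests therefore shows that the
pipeline can learn a tempo-mediated load signal through the full
feature/model/protocol stack — not that the real-data accuracies are
reproduced; those depend on unreleased recordings and are out of reach
here. Note a consequence of the design: the subject tempo effect is a
genuine confound under leave-one-subject-out evaluation, so even the
Bayes-optimal classifier is imperfect (about 0.94 for the default panel),
and subjects with extreme tempo draws are classified near chance — visible
as low single-fold accuracies.

## Problem sizes for the bundled experiments

The test suite and `scripts/acceptance.py` run the full 19-subject,
1026-instance study with a compact Transformer (D = 32, L = 2, 2 heads,
ReLU block MLPs, no stochastic depth, float32) — the same architecture
family at a width that cross-validates in minutes on one core: 14 epochs
(3 warmup, lr 3e-3) for binary, 10 epochs for three-way, 2 epochs for the
shuffled-label null. Measured at seed 0: binary LOSO 0.93 ± 0.12,
three-way 0.65, shuffled-label null 0.50. The invariance and oracle tests
exercise the full default architecture (D = 188, 4 heads, GELU,
stochastic depth) at short sequence lengths where it is cheap.

## Numerical notes and limitations

- Determinism holds per platform (fixed seeds, single-threaded BLAS);
  floating-point results can differ across BLAS builds.
- Attention masking adds -1e9 to masked scores pre-softmax; with float32
  this underflows to exactly zero weight.
- `interpolate_gaps` fills low-confidence gaps up to 5 frames by linear
  interpolation (filled points carry confidence equal to the threshold,
  making the operation idempotent); longer or boundary gaps are reported,
  never guessed.
- The simulator's elbow is held at a fixed fraction of arm extension by
  the trunk-flexion closure, so its elbow angle varies little within an
  instance; the other four angles move substantially.
- Continuous load regression, 3D kinematics, inverse dynamics and
  risk-index computation are out of scope.
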