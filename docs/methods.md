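# Methods

`neglectsim` is a desk-scale simulator of unilateral spatial neglect
(USN): a two-hemisphere artificial neural network is trained to direct
spatial attention to targets on a table, damaged by cutting connection
weights, tested under four head/target geometries, and retrained to
model rehabilitation.  This note documents the model, its assumptions,
the parameters that matter, and what the simulations can and cannot
show.

## The spatial world

The workspace is a table in front of a seated humanoid torso.  Sixteen
target areas are arranged in 2 depth rows × 8 columns at trunk-centered
azimuths ±7.5°, ±22.5°, ±37.5°, ±52.5° (15° pitch, 8 left / 8 right of
the sagittal mid-plane).  The four test conditions each place 8 targets
(two rows of four):

| condition | target columns (azimuth) | neck angle |
|---|---|---|
| A | −22.5 … +22.5 (straddling the midline) | 0° |
| B | +7.5 … +52.5 (all right of midline) | 0° |
| C | same as B | 40° right |
| D | same as A | 40° right |

Contrasting B/C separates the trunk midline from the line of sight, and
A/D tests whether a head turn alone moves the neglected region — the
protocol geometry of the classic patient study this battery mirrors.

## Stimulus encoding

Targets are sensed in the *camera* frame, which rotates with the head:
`camera_azimuth = trunk_azimuth − neck_angle − eye_offset`.  Each eye
produces a 2×8 retinotopic map whose cells sit at the column azimuths;
a target activates a Gaussian bump (σ = 7.5°, half the column pitch) in
its depth row, centred on its camera azimuth (a one-hot code is
selectable).  Both eyes share the head frame by default
(`interocular_offset_deg = 0`); the per-eye distinction is retained in
the data model because the two hemispheres read different eyes.

Neck posture enters as an antagonist muscle pair: turning the head
θ degrees to the right flexes the right muscle (input −θ/40) and
stretches the left (+θ/40).  The two inputs always sum to zero.

**Hemifield routing.**  Each hemisphere receives its eye's retinal map
with the *contralateral* hemifield at unit gain and the ipsilateral
hemifield attenuated by `ipsilateral_gain` (default 0.125), plus its own
muscle input — 17 inputs per hemisphere.  This lateralized gradient,
rather than an absolute split, matters for two reasons.  First, the
spatial signatures of lesion experiments (omissions confined to the
camera hemifield contralateral to the damage, and their displacement
when the head turns) follow directly from it.  Second, an absolute
split (gain 0) makes the symmetric control network provably untrainable:
with the head turned 40° nearly all targets fall in one camera
hemifield, and a single hemisphere's rank-8 output pathway cannot emit
more than 8 linearly independent area codes.  A weak ipsilateral path
restores trainability while preserving lateralization — in the spirit
of neuronal-gradient accounts of neglect.

**Training set.**  The 16 areas are crossed with the neck postures 0°
and 40° and every pair whose target stays inside the ±67.5° camera
field of view is kept: 16 + 12 = 28 examples (the two leftmost columns
are out of view when the head is turned right).  The teacher is always
the one-hot *trunk-centered* area label, so head-turned examples force
the network to solve a sensorimotor coordinate transformation using the
muscle input.

## Architecture

Per hemisphere: input (17) → **Attention Bias** (softmax — a normalized
spatial salience distribution) → **Cognition** (logistic sigmoid; tanh
selectable) → a shared linear **Activator** of 16 units, one per table
area.  The activator value is the "likelihood" of exploring an area and
may exceed 1 or go negative, being an unsquashed sum of both
hemispheres' projections.  A trial counts as successful exploration iff
the correct area's likelihood is strictly greater than 0.5; otherwise it
is an omission (the model analogue of a neglected target).

Two configurations:

* **control** — 8 attention + 8 cognition units per hemisphere, all
  weights initialized uniformly in [−1, 1], no inter-hemispheric links.
* **specialized** — plasticity mechanisms biased toward the right
  hemisphere: RH gets 4 extra units in both hidden layers (12/12 vs
  8/8) and keeps the [−1, 1] initialization, while all LH blocks start
  in [−0.1, 0.1]; in addition each hemisphere's attention layer
  projects to the *contralateral* cognition layer (cross links).  No
  explicit asymmetry is trained in — the functional specialization
  emerges from these initial conditions during learning.

Every non-input layer has a trainable bias drawn from its hemisphere's
range (the shared activator bias from the wider of the two).  Cross
blocks are named by their source hemisphere and use the source's
initialization range.

## Training

Full-batch gradient descent with momentum on the mean squared error
between activator output and the one-hot teacher; gradients pass
through the softmax attention layers with the full softmax Jacobian
(the cross-entropy shortcut does not apply to MSE).  Defaults:
learning rate 1.0, momentum 0.9.  Training stops when every training
example's correct-area output exceeds 0.5 *and* the epoch MSE is at or
below 3e-5 (`all_targets_active`), or after 150 000 epochs.  The MSE
threshold was set so that a converged network reproduces the
near-perfect healthy state (mean correct-target likelihood ≥ 0.999);
at looser thresholds (e.g. 1e-3) the healthy likelihood stalls near
0.97, while much tighter ones over-fit the capacity-limited control
network into a degenerate division of labour between the hemispheres
(see below).  Typical convergence: ~15–25 k epochs for the specialized
configuration, several times more for the harder control one.  The
analytic gradients are verified against central finite differences
(relative error < 1e-5) for every architecture variant in the test
suite.

## Lesioning

A lesion assigns exactly 0 to the weights of the ipsilateral
Attention-Bias→Cognition block of one hemisphere — an anterior/posterior
intra-hemispheric disconnection.  Biases are untouched and structure is
preserved, so the damaged cognition layer idles at its bias level.  An
optional extended scope (`include_cross=True`) also cuts the
hemisphere's outgoing cross block; it is not the default because
severing both paths suppresses the weak-but-present ipsilesional
performance that characterizes the milder LH-damage syndrome.  The
lesion record stores the pre-lesion Euclidean norm of the cut blocks;
recovery strength is later expressed as a percentage of it.

## Test battery and metrics

A battery presents the 8 targets of each condition (32 trials), reads
the correct-area likelihood for each, and applies the strict >0.5 rule.
Reported metrics: the 2×4 likelihood grid per condition (far row first,
columns in increasing azimuth), omission counts, the percentage of
successful trials, and the mean likelihood over all 32 cells.
Experiments are replicated across 5 seeds and aggregated by *cell-wise
median*, with summary metrics recomputed from the median grid
(median-then-metric), matching how the reference tables were reported.
The four published median grids ship as CSV fixtures and the metric
code reproduces their stated success rates (84.38 % / 43.75 %), mean
likelihoods (0.737 / 0.345) and per-condition omission counts exactly.

## Rehabilitation

Therapy is simulated as repeated sessions of 100 backpropagation epochs
on the full training set — the same algorithm as initial learning, with
all weights trainable (a lesioned-only mode exists for ablations).
After each session the battery is re-run and the cut block's Euclidean
strength is measured.  Recovery is declared at the first session with
zero omissions across all 32 trials; the curve (session, omissions,
strength-%) reproduces the shape of the published recovery figures:
recovery completes with the rebuilt block at only ~30 % of its
pre-lesion norm, and LH damage recovers in fewer sessions than RH
damage.

**Known quantitative limitation.**  At the package defaults the median
sessions-to-recovery is of order 1–3, far below the ~22 (LH) and ~49
(RH) sessions of the reference experiment, although the ordering, the
completeness of recovery and the ~30 % terminal strength all reproduce.
Absolute session counts are governed by the learning rate and the
amount of structure the lesion removes — quantities the reference work
does not specify — and with every non-lesioned weight still optimal, a
single 100-epoch session at our learning rate nearly re-fits the cut
block.  We report the measured counts rather than tuning a separate
(unjustifiable) therapy learning rate to slow recovery down.

## Design choices on genuinely open points

* **Layer order** input → attention (softmax) → cognition (sigmoid) →
  shared linear activator: the lesion is described as cutting
  attention-to-cognition links and as an anterior/posterior
  disconnection, which requires attention upstream of cognition.
* **Cross links** are attention→contralateral-cognition, present only
  in the specialized configuration, absent from the control.
* **Posture crossing**: training must include head-turned examples or
  the healthy network fails condition C/D; a left-right balanced
  crossing (−40/0/40°) was tested and rejected — it rank-stresses both
  hemispheres at the turned postures and degrades control convergence.
* **Ipsilateral gain 0.125** was chosen (scan over 0.05–0.3) as the
  value where the control model both trains to the healthy criterion
  and shows side-symmetric, contralateral lesion deficits; smaller
  gains starve the control of capacity it needs at turned postures and
  skew the two lesion arms apart, larger ones blur contralaterality.
  A residual trace of the capacity limit remains: the control right
  hemisphere would need 12 output directions to own every left-camera
  target at the turned posture but has only rank 8, so a shared,
  threshold-straddling cell can appear on the "wrong" side of a
  lesioned battery (typically one near-row cell at +22.5°).
* **Numerical details**: softmax is stabilized by max-subtraction;
  training aborts on non-finite gradients; exact-0.5 likelihoods count
  as omissions (strict inequality); weight serialization round-trips
  bit-exactly through JSON.

## What the synthetic world does and does not capture

All inputs are generated geometrically; there is no camera image, no
depth or vergence, no reach kinematics, and no trial-to-trial noise —
given a network, behaviour is deterministic, and variability enters
only through weight initialization.  Passing batteries therefore show
that the *architecture + geometry* reproduce the lateralized deficit
and recovery phenomenology; they say nothing about pixel-level vision,
motor execution, or patient-level variability.  Session counts and
epoch counts are order-of-magnitude model properties, not clinical
predictions.
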