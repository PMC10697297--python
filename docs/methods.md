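# Methods

## Problem and pipeline

Longitudinal laboratory series from routine care are irregular: visits are
nominally scheduled (here every 3 months) but jittered and skipped, spans
differ per patient, and each series is short relative to the dynamics of
interest. This package pretrains one small forecaster per laboratory
marker on such series in two stages, then transfers the frozen forecasters
to an episodic cohort — patients with a *single* observation per marker at
an index procedure and a binary event label — by using the forecasters'
rolled-out predictions as classification features.

The pipeline is: interpolation onto a monthly grid → sliding-window
framing → per-timestep feature encoding → stage-1 supervised next-month
training → stage-2 self-supervised autoregressive fine-tuning → frozen
rollout features for downstream classifiers.

## Interpolation

Three interpolants fill the monthly grid between the first observation t0
and the second-to-last observation tm: piecewise linear, shape-preserving
cubic Hermite (PCHIP), and the degree-n interpolating polynomial in
barycentric form. All satisfy the interpolation condition exactly at
observed months, enforced explicitly after evaluation. PCHIP node
derivatives follow the Fritsch–Butland weighted harmonic mean with weights
w1 = 2·h_right + h_left and w2 = h_right + 2·h_left, zeroed where the
adjacent secant slopes change sign or vanish; endpoint derivatives use the
standard one-sided three-point formula with monotonicity projection. A
textual source for this construction reads as if the interpolated *value*
were zeroed at sign changes; that would violate the interpolation
condition, so the derivative convention (which the cited weight formula
belongs to) is used. Barycentric weights use the O(n²) product formula on
nodes rescaled to [-2, 2]; the node count is capped at 50 because
high-degree polynomial interpolation is numerically fragile. No
extrapolation beyond the observed span is ever performed, and months after
the designated fill end are never filled.

## Framing

With window span r = 12 months (13 monthly points, read inclusively — the
stage-1 constraint i + r + 1 ≤ m only makes sense this way), stage-1
frames start at every month i with i + r ≤ m − 1 and predict the value one
month after the window; series whose interpolated span is ≤ r produce no
frames. A `certain_min` threshold drops frames containing fewer real
(non-interpolated) observations than required; with quarterly visits a
13-point window holds at most 5 real observations (months 0,3,6,9,12).

Stage 2 isolates the one window ending at tm and targets the last real
observation at tn, which lies g = n − m − 1 months past the window end.
Samples with g above g_max (default r/2 = 6) are dropped, as are patients
whose span is shorter than the window (no padding — sub-year series are
excluded upstream by design). The stage-2 target is always a real
observation; stage-1 targets may be interpolated.

## Feature encoding

Each window month is a 5-vector: log1p laboratory value, log1p age, a sex
bit (1 = male), a certainty bit (1 = real observation), and a clinical
category index scaled to [0, 1]. log1p keeps all features non-negative
and requires no cohort statistics, so the encoding cannot leak
information across patients or splits. Category cut-points per marker
(2 or 3 groups) ship as a configurable table with physiologically
plausible defaults; bins are half-open with boundary values in the upper
bin. The 3-level category is encoded as a scaled ordinal rather than
one-hot to preserve the fixed 5-feature input width the architecture
assumes; age is the age at t0 and is held constant across a window.

## Network

Per marker: a bidirectional LSTM with 5 hidden units per direction over
the 5-feature rows, ReLU, a condensing affine layer mapping the
concatenated 10-unit state back to width 5, ReLU (together the
longitudinal iterative block), and a regressor of two affine layers
5 → 2 → 1 with ReLU between, emitting the predicted next-month normalized
value. The two directional streams are concatenated before condensing.
The condensed final-step vector is the latent progress embedding; pooling
across steps was the plausible alternative and the final step was chosen
for its autoregressive role.

Rollout extends a window month by month: each iteration runs the block
and the regressor, and the *regressor's prediction* becomes the appended
month's value — appended months carry certainty 0, the patient's static
age and sex, and a category recomputed from the denormalized prediction.
Feeding back the condensed row's value channel instead was considered and
rejected: nothing in stage-1 training constrains that channel, so
rollouts from a stage-1-trained model are unanchored, whereas the
regressor output is exactly the quantity stage 1 supervises. A batch is
rolled to its maximum gap and each sample's prediction is read at its own
iteration index g; with all gaps zero the computation reduces exactly to
the stage-1 forward pass (one block pass, then the regressor).

## Training

Stage 1 minimizes the MSE of next-month prediction over minibatches of
frames; stage 2 minimizes the MSE of the rollout prediction at each
sample's own gap against the last real observation, with gradients
flowing through the autoregressive feedback (the value channel; the
recomputed category is piecewise constant and carries none). Optimizer:
Adam, learning rate 1e-3, batch size 64, 50 epochs per stage by default,
no early stopping. Learning rate and batch size are not dictated by the
method and are exposed in `TrainConfig`.

Regimes: `supervised` (stage 1 only), `ssl` (stage 2 from scratch),
`two_stage` (stage 1 then stage 2), `hybrid` (both objectives interleaved
per epoch under one optimizer state). Two exact degeneracies hold and are
tested: two-stage with zero stage-2 epochs equals supervised, and the
stage-2 algorithm with all gaps zero equals stage 1 on the same windows
(both stages draw batch shuffles from the same seeded stream to make the
equality exact).

Numerical choices that matter at this model scale:

* **Bias calibration at init.** With 2 regressor hidden units and highly
  correlated inputs, a large fraction of random seeds starts with every
  ReLU path inactive for all inputs, freezing the output at a constant;
  and the normalized targets sit near 4–5 while a random-init network
  outputs near 0, an offset that small step budgets cannot cover. Freshly
  initialized networks therefore get each ReLU layer's bias centered so
  the mean preactivation on a probe batch is +0.25, and the final bias
  set to the target mean. Fine-tuning stages inherit parameters untouched.
* **Gradient clipping.** Global-norm clipping at 5.0; backpropagation
  through the autoregressive unroll occasionally produces exploding
  gradients.
* **Determinism.** All randomness flows from seeded generators; identical
  configuration and seed reproduce parameters bitwise.

## Evaluation protocol

Evaluation forecasts the last real observation of held-out patients from
their stage-2 window (gap at most r/2 — no interpolation support inside
the gap) and scores R² per evaluation set. The full protocol is a
patient-level 80:20 split per repeat with 5-fold cross-validation inside
the training side and test metrics on the held-out 20%, repeated 5 times
with distinct seeds (25 entries); R² is computed per fold and then
averaged. Patient-level splitting plus per-patient interpolation makes
leakage impossible by construction. The ablation grid runs regimes ×
interpolation methods × certainty thresholds with splits shared across
cells so comparisons are paired.

Head-to-head regime comparisons use *step-matched* budgets: every regime
consumes about 2·epochs·nb1 optimizer steps, where nb1 is the frame set's
minibatches per epoch. The stage-2 set holds one sample per patient —
roughly 15× fewer minibatches per epoch than the frame set — so matching
epochs instead would starve the SSL-only baseline of gradient steps
entirely at desk scale.

## Synthetic cohorts

No real data ships with the package; the generator emulates the assumed
structure. Pretext series follow a latent log-linear trend
value(t) = baseline·exp(slope·t/12) with multiplicative stationary AR(1)
observation noise (default marginal SD 0.05, autocorrelation 0.6). Visits
occur at months {0, k·interval ± jitter} with independent dropout
(defaults: interval 3, jitter 1, dropout 0.15), always keeping the first
and last visit; spans are uniform on a configurable range with minimum 12
months. Baselines are log-normal per marker with plausible levels for the
six markers (total-/HDL-cholesterol ratio, LDL-c, LDL-c/HDL-c ratio,
fasting glucose, white-cell count, uric acid). Two deliberate couplings
give the dynamics clinical texture: the trend slope correlates with the
baseline level (coupling 0.6 — sicker patients progress faster), and
baselines above the ~75th percentile receive an extra +0.25/yr log slope
(uncontrolled markers progress; this is also what makes forward rollouts
*diverge* for high-level patients while controlled patients stay flat).
Noise-free trajectories are returned as ground truth for recovery tests.

Downstream records hold one value per marker: negatives draw from the
stable baseline regime; positives have their log-mean shifted by
0.5·effect_size SDs and their dispersion inflated by 1 + 0.75·effect_size,
so single-visit class overlap is high while rollouts diverge. Event and
censoring gaps are both geometric with mean 28 months: making censoring
gaps longer (as they are in reality) would leak the label through the
rollout horizon, violating the zero-effect null (at effect_size = 0 no
classifier may beat chance). Age is N(57, 12²) clipped to [30, 95], sex
Bernoulli(0.65) — defaults, not claims about any real cohort. Imbalance
defaults to 42 positives / 441 negatives with balancing by seeded
negative downsampling to 84.

What the generator does not emulate: inter-marker physiological
correlation (beyond the shared demographics), assay changes, outlier
visits, informative visit timing, and treatment feedback. Passing tests
on this generator show the machinery is correct and the directional
properties hold under the assumed structure — not that the method attains
any particular performance on real records.

## Transfer stage

A single downstream observation is carried back across the 13-point
window (constant value; certainty set only at the final month — the
window anchors its one real value where a stage-2 window anchors its
last real observation). Zero-filling the earlier months is available as a
config alternative. Frozen per-marker networks roll each window to the
patient's own horizon (g, or g/2 with floor division) and the
concatenated condensed vectors (30 features) and predictions (6 features)
are compared against the raw features (6 values + age + sex) under four
classifier families — LightGBM, SVM, logistic regression, k-NN — with
library-default hyperparameters and fixed seeds, evaluated by stratified
5-fold cross-validation repeated with reshuffled folds (the study design
names only five repetitions; cross-validation was chosen over a fixed
split). Agreement is the mean pairwise Cohen's kappa over the four
classifiers' pooled held-out predictions. AUROC for the SVM uses its
decision function. A snapshot export table gives denormalized rollout
predictions at horizons 0, g/2 and g per patient for distribution plots.

## Problem sizes

Desk-scale sizes keep the full test suite and the acceptance script to
minutes on one CPU: recovery uses 200 patients × 1 marker, the regime
comparison 300 patients × 1 marker with spans 16–26 months and 12 epochs
per stage at step-matched budgets, pretraining for transfer 100 patients
× 6 markers with 25 epochs per stage (enough for the held-out R² of each
marker model to plateau — under-converged forecasters produce
representations that carry no transferable signal), and the downstream
study the default 483-record imbalance balanced to 84, with five
repetitions of the classifier training. These are the package's chosen
study sizes; all are configuration.

## Known limitations

* At these problem sizes the four training regimes reach statistically
  similar held-out R² on the generator's well-behaved dynamics; the large
  separations reported on real hospital data (supervised and hybrid
  collapsing below the mean-line) likely require real-EHR pathologies —
  heterogeneity, outliers, and a stage-2 corpus orders of magnitude
  larger — that the log-linear + AR(1) generator cannot produce.
* The latent output of the frozen forecaster is a representation;
  denormalizing it (as in the snapshot export) yields values on the
  laboratory scale but not calibrated clinical predictions.
* One model per marker: no cross-marker information is shared during
  pretraining.
* Only numeric markers are supported; categorical laboratory results are
  out of scope.
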