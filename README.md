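# glp — laboratory-progress pretraining for irregular clinical time series

Routine-care laboratory series are irregular and sparse: visits are
nominally quarterly but jittered and skipped, and spans differ per
patient. Cohorts for rare or specific events are worse — often a single
observation per patient. This package implements a two-stage pretraining
pipeline that learns the *progression* of common laboratory markers from
the prevalent, longitudinal cohort and transfers it, frozen, to classify
a clinical event in the episodic cohort. It is aimed at biostatisticians
and ML researchers working with longitudinal EHR laboratory data.

## Method

For each marker, observations y_{t_0}, …, y_{t_n} (t in months) are
densified onto a monthly grid between t_0 and the second-to-last
observation t_m by linear, PCHIP (Fritsch–Butland) or barycentric
interpolation. Windows of r + 1 = 13 monthly points are framed with a
next-month target (stage 1, supervised, MSE); the final window ending at
t_m is kept aside with the last *real* observation y_{t_n} as target,
g = n − m − 1 months past the window (g ≤ r/2). In stage 2 the model
rolls forward autoregressively — each predicted month is appended to the
window and the prediction at the sample's own g is optimized against
y_{t_n} (self-supervised, MSE).

The per-marker network is a bidirectional LSTM (hidden size 5) with a
condensing layer back to the 5-feature input width (ReLU after each), and
a regressor 5 → 2 → 1 predicting the next-month normalized value. Each
month is encoded as (log1p value, log1p age, sex, certainty bit, clinical
category). Training compares four regimes: supervised only, SSL only,
hybrid (interleaved), and two-stage; evaluation forecasts held-out
patients' y_{t_n} and scores R², with patient-level 80:20 splits, 5-fold
CV and 5 repeats.

For transfer, the six frozen marker models roll each episodic patient's
single observation out to their event horizon; the condensed vectors
(Progress_emb, 30 features) and predictions (Progress_out, 6 features)
feed LightGBM / SVM / logistic-regression / k-NN classifiers, compared
against the raw features, with mean pairwise Cohen's kappa measuring
classifier agreement. No real data ships with the package; a synthetic
cohort generator with the assumed statistical structure (log-linear
latent trends, AR(1) observation noise, scheduled visits with jitter and
dropout, imbalanced episodic outcomes) drives all experiments — see
`docs/methods.md`.

## Worked example

```python
from glp import (GLP, CohortConfig, TrainConfig,
                 simulate_pretext_cohort, simulate_downstream_cohort)

series, _ = simulate_pretext_cohort(CohortConfig(n_patients=100, seed=21))
results = GLP(series, config=TrainConfig(epochs=12, seed=7)).fit()
print(results.summary())

records = simulate_downstream_cohort(CohortConfig(seed=200), effect_size=0.75)
study = results.transfer_study(records, seed=0, n_repeats=3)
for block in ("original", "progress_emb", "progress_out"):
    r = study[block]
    print(f"{block:>13}: accuracy {r.mean_accuracy:.3f}  "
          f"kappa {r.mean_kappa:.3f}")
```

prints

```
Laboratory-progress pretraining results
=======================================================
regime: two_stage     interpolation: linear
window r: 12 months   certain_min: 0   g_max: 6
epochs/stage: 12   seed: 7
-------------------------------------------------------
marker            held-out R²    final loss
Chol/HDL-c              0.869       0.03958
Glucose AC              0.775       0.05416
LDL-c                   0.569       0.27160
LDL-c/HDL-c             0.867       0.01952
UA                      0.822       0.06219
WBC                     0.355       0.21697
-------------------------------------------------------
mean                    0.710
     original: accuracy 0.550  kappa 0.169
 progress_emb: accuracy 0.578  kappa 0.555
 progress_out: accuracy 0.614  kappa 0.592
```

Held-out R² is the forecasting quality of each frozen marker model on
unseen patients (WBC is noisiest by construction). In the downstream
study the raw single-visit features are nearly uninformative (accuracy
0.55 on balanced classes) while the rolled-out predictions both classify
better and make the four classifier families agree far more (kappa 0.17
→ 0.59) — the divergence of event-prone trajectories is what the frozen
forecasters add.

The command line mirrors the library: `glp simulate --out dir/`,
`glp pretrain --data dir/ --out models/`,
`glp finetune --models models/ --data dir/downstream.csv --out report/`.

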