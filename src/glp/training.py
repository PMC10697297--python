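"""Two-stage training, baselines, and the forecasting evaluation protocol.

Stage 1 is supervised next-month prediction on interpolated frames; stage 2
is self-supervised autoregressive fine-tuning on each series' final
real-anchored window, targeting the last real observation ``g`` months
ahead.  The baselines are SSL-only (stage 2 from scratch), supervised-only
(stage 1 alone) and hybrid (both objectives interleaved within each epoch
under one optimizer).  Evaluation always forecasts the held-out patients'
last real observation from their stage-2 window — no interpolation support
within the gap — and scores with R².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .encoding import ThresholdTable, assemble_features, normalize_value
from .framing import (DEFAULT_G_MAX, DEFAULT_R, build_stage1_frames,
                      build_stage2_sample, locate_anchors)
from .interpolation import fill_timeline
from .model import GLPNetwork, rollout
from .synthetic import pretext_to_frames

__all__ = [
    "TrainConfig", "FrameSet", "Stage2Set", "EvalReport",
    "build_marker_dataset", "train_stage1", "train_stage2", "train_hybrid",
    "train_regime", "r_squared", "evaluate_forecast", "cross_validate",
    "ablation_grid", "regime_comparison", "REGIMES",
]

REGIMES = ("supervised", "ssl", "hybrid", "two_stage")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the pretraining pipeline (per-stage epochs)."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    grad_clip: float = 5.0
    regime: str = "two_stage"
    interpolation: str = "linear"
    certain_min: int = 0
    r: int = DEFAULT_R
    g_max: int = DEFAULT_G_MAX
    seed: int = 0
    n_folds: int = 5
    n_repeats: int = 5
    test_fraction: float = 0.2

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")


@dataclass
class FrameSet:
    """Encoded stage-1 frames of one marker."""

    marker: str
    X: np.ndarray            # (n, r+1, 5)
    y: np.ndarray            # (n,) normalized next-month targets
    patient_ids: np.ndarray

    def __len__(self):
        return len(self.y)


@dataclass
class Stage2Set:
    """Encoded stage-2 samples of one marker (one per eligible patient)."""

    marker: str
    X: np.ndarray            # (n, r+1, 5)
    y: np.ndarray            # (n,) normalized last-observation targets
    g: np.ndarray            # (n,) month gaps
    patient_ids: np.ndarray

    def __len__(self):
        return len(self.y)


def build_marker_dataset(series: list, marker: str, cfg: TrainConfig,
                         table: ThresholdTable,
                         patient_filter=None) -> tuple[FrameSet, Stage2Set]:
    """Interpolate, frame and encode every series of one marker.

    Each patient contributes only their own observations (interpolation and
    framing never cross patients), so patient-level splits are leak-free by
    construction.
    """
    fx, fy, fp = [], [], []
    sx, sy, sg, sp = [], [], [], []
    for s in series:
        if s.marker != marker:
            continue
        if patient_filter is not None and s.patient_id not in patient_filter:
            continue
        obs = pretext_to_frames(s)
        anchors = locate_anchors(obs)
        timeline = fill_timeline(obs, cfg.interpolation, anchors.tm)
        for frame in build_stage1_frames(timeline, cfg.r, cfg.certain_min):
            fx.append(assemble_features(frame.values, frame.is_real,
                                        s.age, s.sex, marker, table))
            fy.append(normalize_value(frame.target_value))
            fp.append(s.patient_id)
        sample = build_stage2_sample(timeline, anchors, cfg.r, cfg.g_max,
                                     target_value=obs.values[-1])
        if sample is not None:
            sx.append(assemble_features(sample.values, sample.is_real,
                                        s.age, s.sex, marker, table))
            sy.append(normalize_value(sample.target_value))
            sg.append(sample.g)
            sp.append(s.patient_id)
    shape = (0, cfg.r + 1, 5)
    frames = FrameSet(marker,
                      np.array(fx) if fx else np.empty(shape),
                      np.array(fy), np.array(fp, dtype=np.int64))
    samples = Stage2Set(marker,
                        np.array(sx) if sx else np.empty(shape),
                        np.array(sy), np.array(sg, dtype=np.int64),
                        np.array(sp, dtype=np.int64))
    return frames, samples


# ---------------------------------------------------------------------------
# training engines
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return [perm[i:i + batch_size] for i in range(0, n, batch_size)]


def _calibrate_init(model: GLPNetwork, X: np.ndarray, y: np.ndarray) -> None:
    """Data-dependent bias centering of a freshly initialized network.

    Two pathologies of small random init are removed before training, using
    one probe batch: (1) ReLU death — with only 2 regressor hidden units
    and strongly correlated inputs, a sizeable fraction of seeds starts
    with every ReLU path inactive for all inputs, which freezes the output
    at a constant forever; each ReLU layer's bias is shifted so its mean
    preactivation is +0.25.  (2) Level offset — normalized laboratory
    values sit well above zero while the initial output is near zero, so
    the final bias is set to the target mean.  Applied only to untrained
    networks; fine-tuning stages inherit their parameters from the
    previous stage untouched.
    """
    if model.stage != "init":
        return
    probe = X[: min(len(X), 256)]
    u, _, _ = model.libc._states(probe)
    pre_c = u.data.mean(axis=0) @ model.libc.Wc.data
    model.libc.bc.data[:] = 0.25 - pre_c
    _, next_step = model.libc.forward(probe)
    pre_1 = next_step.data.mean(axis=0) @ model.regressor.W1.data
    model.regressor.b1.data[:] = 0.25 - pre_1
    model.regressor.b2.data[:] = float(np.mean(y))
    model.stage = "calibrated"


def _stage1_loss(model: GLPNetwork, X: np.ndarray, y: np.ndarray) -> Tensor:
    _, next_step = model.libc.forward(X)
    pred = model.regressor.forward(next_step)            # (B, 1)
    return ((pred - Tensor(y.reshape(-1, 1))) ** 2).mean()

def _stage2_loss(model: GLPNetwork, X: np.ndarray, g: np.ndarray,
                 y: np.ndarray, table: ThresholdTable) -> Tensor:
    res = rollout(model, X, g, table)
    target = Tensor(y.reshape(res.selected.data.shape))
    return ((res.selected - target) ** 2).mean()


def train_stage1(frames: FrameSet, cfg: TrainConfig, table: ThresholdTable,
                 model: GLPNetwork | None = None,
                 epochs: int | None = None) -> GLPNetwork:
    """Supervised next-month training on interpolated frames (MSE, Adam)."""
    if len(frames) == 0:
        raise ValueError("empty frame set")
    if model is None:
        model = GLPNetwork(frames.marker, seed=cfg.seed)
    _calibrate_init(model, frames.X, frames.y)
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
    opt = Adam(model.params(), lr=cfg.learning_rate, clip_norm=cfg.grad_clip)
    trace = []
    for _ in range(epochs):
        losses = []
        for idx in _batches(len(frames), cfg.batch_size, rng):
            loss = _stage1_loss(model, frames.X[idx], frames.y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    model.stage = "stage1"
    model.loss_trace = getattr(model, "loss_trace", {})
    model.loss_trace["stage1"] = trace
    return model


def train_stage2(samples: Stage2Set, cfg: TrainConfig, table: ThresholdTable,
                 init: GLPNetwork | None = None,
                 epochs: int | None = None) -> GLPNetwork:
    """Self-supervised autoregressive fine-tuning on stage-2 samples.

    Each batch is rolled out to its maximum gap; every sample's prediction
    is read at its own iteration index g and the MSE against the last real
    observation is minimized.  With no `init` (SSL-only regime) a freshly
    initialized network is trained.
    """
    if len(samples) == 0:
        raise ValueError("empty stage-2 sample set")
    if np.any(samples.g > cfg.g_max):
        raise ValueError("stage-2 sample with g > g_max present")
    model = init if init is not None else GLPNetwork(samples.marker, seed=cfg.seed)
    _calibrate_init(model, samples.X, samples.y)
    epochs = cfg.epochs if epochs is None else epochs
    # same seed stream as stage 1: with identical windows and g == 0 the
    # two algorithms then follow the same gradient path exactly
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
    opt = Adam(model.params(), lr=cfg.learning_rate, clip_norm=cfg.grad_clip)
    trace = []
    for _ in range(epochs):
        losses = []
        for idx in _batches(len(samples), cfg.batch_size, rng):
            loss = _stage2_loss(model, samples.X[idx], samples.g[idx],
                                samples.y[idx], table)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    model.stage = "stage2" if init is not None else "ssl"
    model.loss_trace = getattr(model, "loss_trace", {})
    model.loss_trace["stage2"] = trace
    return model


def train_hybrid(frames: FrameSet, samples: Stage2Set, cfg: TrainConfig,
                 table: ThresholdTable,
                 epochs: int | None = None) -> GLPNetwork:
    """Interleave stage-1 and stage-2 minibatches each epoch, one optimizer."""
    if len(frames) == 0 or len(samples) == 0:
        raise ValueError("hybrid training needs both frame and sample sets")
    if np.any(samples.g > cfg.g_max):
        raise ValueError("stage-2 sample with g > g_max present")
    model = GLPNetwork(frames.marker, seed=cfg.seed)
    _calibrate_init(model, frames.X, np.concatenate([frames.y, samples.y]))
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 33)))
    opt = Adam(model.params(), lr=cfg.learning_rate, clip_norm=cfg.grad_clip)
    trace = []
    for _ in range(epochs):
        b1 = _batches(len(frames), cfg.batch_size, rng)
        b2 = _batches(len(samples), cfg.batch_size, rng)
        losses = []
        for k in range(max(len(b1), len(b2))):
            for kind, batches in (("s1", b1), ("s2", b2)):
                if k >= len(batches):
                    continue
                idx = batches[k]
                if kind == "s1":
                    loss = _stage1_loss(model, frames.X[idx], frames.y[idx])
                else:
                    loss = _stage2_loss(model, samples.X[idx], samples.g[idx],
                                        samples.y[idx], table)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    model.stage = "hybrid"
    model.loss_trace = {"hybrid": trace}
    return model


def train_regime(frames: FrameSet, samples: Stage2Set, cfg: TrainConfig,
                 table: ThresholdTable,
                 stage1_epochs: int | None = None,
                 stage2_epochs: int | None = None) -> GLPNetwork:
    """Train under cfg.regime.  Per-stage epoch overrides allow the regime
    degeneracies (two_stage with zero stage-2 epochs == supervised, with
    zero stage-1 epochs == SSL-only) to be exercised directly."""
    if cfg.regime == "supervised":
        return train_stage1(frames, cfg, table, epochs=stage1_epochs)
    if cfg.regime == "ssl":
        return train_stage2(samples, cfg, table, epochs=stage2_epochs)
    if cfg.regime == "hybrid":
        return train_hybrid(frames, samples, cfg, table, epochs=stage1_epochs)
    # two_stage
    e1 = cfg.epochs if stage1_epochs is None else stage1_epochs
    e2 = cfg.epochs if stage2_epochs is None else stage2_epochs
    if e1 == 0:
        model = GLPNetwork(frames.marker, seed=cfg.seed)
    else:
        model = train_stage1(frames, cfg, table, epochs=e1)
    if e2 > 0:
        model = train_stage2(samples, cfg, table, init=model, epochs=e2)
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def r_squared(predictions, truths) -> float:
    """1 - SS_res / SS_tot; negative when worse than the mean line."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predictions and truths must be equal-length 1-D")
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot == 0.0:
        raise ValueError("R² undefined: truths are all identical")
    return float(1.0 - np.sum((t - p) ** 2) / ss_tot)


def evaluate_forecast(model: GLPNetwork, samples: Stage2Set,
                      table: ThresholdTable) -> float:
    """R² of forecasting the last real observation of each sample."""
    res = rollout(model, samples.X, samples.g, table, samples.marker)
    return r_squared(res.progress_out, samples.y)


@dataclass
class EvalReport:
    """Per-fold/per-repeat R² entries of one evaluation cell."""

    marker: str
    regime: str
    interpolation: str
    certain_min: int
    entries: pd.DataFrame        # columns: repeat, fold, r2
    split_log: list = field(default_factory=list)
    # one dict per repeat: {"test_patients": array, "folds": [array, ...]}

    @property
    def mean_r2(self) -> float:
        return float(self.entries["r2"].mean())


def _derive_seed(*parts) -> int:
    return int(np.random.SeedSequence(tuple(int(p) for p in parts)
                                      ).generate_state(1)[0] % (2 ** 31))


def _split_patients(patients: np.ndarray, test_fraction: float,
                    rng: np.random.Generator):
    perm = rng.permutation(patients)
    n_test = max(1, int(round(test_fraction * len(patients))))
    return perm[n_test:], perm[:n_test]


def cross_validate(series: list, marker: str, cfg: TrainConfig,
                   table: ThresholdTable) -> EvalReport:
    """Patient-level 80:20 split with n-fold CV inside the training side,
    repeated with distinct seeds.

    Per repeat, the 80% training side is partitioned into `cfg.n_folds`
    folds; each fold's model trains on the remaining folds and is scored by
    forecasting the held-out 20% patients' last observation from their
    stage-2 window.  The report carries n_folds x n_repeats R² entries.
    """
    patients = np.unique([s.patient_id for s in series if s.marker == marker])
    if len(patients) < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} patients, got {len(patients)}")
    rows = []
    split_log = []
    for rep in range(cfg.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 101, rep)))
        train_pats, test_pats = _split_patients(patients, cfg.test_fraction, rng)
        _, test_samples = build_marker_dataset(series, marker, cfg, table,
                                               patient_filter=set(test_pats))
        folds = np.array_split(rng.permutation(train_pats), cfg.n_folds)
        split_log.append({"test_patients": np.sort(test_pats),
                          "folds": [np.sort(f) for f in folds]})
        for fold_id, fold in enumerate(folds):
            fit_pats = set(train_pats) - set(fold)
            sub_cfg = replace(cfg, seed=_derive_seed(cfg.seed, rep, fold_id))
            frames, samples = build_marker_dataset(series, marker, sub_cfg,
                                                   table, patient_filter=fit_pats)
            model = train_regime(frames, samples, sub_cfg, table)
            rows.append({"repeat": rep, "fold": fold_id,
                         "r2": evaluate_forecast(model, test_samples, table)})
    return EvalReport(marker, cfg.regime, cfg.interpolation, cfg.certain_min,
                      pd.DataFrame(rows), split_log)


def ablation_grid(series: list, marker: str, cfg: TrainConfig,
                  table: ThresholdTable,
                  regimes=REGIMES,
                  methods=("linear", "pchip", "barycentric"),
                  certain_range=range(0, 6)):
    """Full factorial regimes x interpolation x certain_min with shared
    patient splits across cells.

    Returns (table, summary): a tidy DataFrame with one row per
    (regime, interpolation, certain, repeat, fold) and the per-cell mean R².
    """
    regimes = list(regimes)
    methods = list(methods)
    certain_range = list(certain_range)
    if not regimes or not methods or not certain_range:
        raise ValueError("all grids must be non-empty")
    rows = []
    for regime in regimes:
        for method in methods:
            for certain in certain_range:
                cell_cfg = replace(cfg, regime=regime, interpolation=method,
                                   certain_min=certain)
                report = cross_validate(series, marker, cell_cfg, table)
                for _, entry in report.entries.iterrows():
                    rows.append({"marker": marker, "regime": regime,
                                 "interpolation": method, "certain": certain,
                                 "repeat": int(entry["repeat"]),
                                 "fold": int(entry["fold"]),
                                 "r2": float(entry["r2"])})
    tidy = pd.DataFrame(rows)
    summary = (tidy.groupby(["regime", "interpolation", "certain"])["r2"]
               .mean().reset_index(name="mean_r2"))
    return tidy, summary


def regime_comparison(series: list, marker: str, cfg: TrainConfig,
                      table: ThresholdTable,
                      regimes=REGIMES,
                      n_repeats: int | None = None) -> pd.DataFrame:
    """Head-to-head regimes at matched total epoch budgets.

    Per repeat: one shared 80:20 patient split; every regime trains on the
    same patients with a total budget of 2 x cfg.epochs (two_stage splits
    it across its stages, hybrid interleaves both objectives within
    cfg.epochs epochs so it consumes the same number of minibatches) and is
    scored on the shared held-out patients.  Returns one row per
    (regime, repeat).
    """
    n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
    patients = np.unique([s.patient_id for s in series if s.marker == marker])
    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 202, rep)))
        train_pats, test_pats = _split_patients(patients, cfg.test_fraction, rng)
        _, test_samples = build_marker_dataset(series, marker, cfg, table,
                                               patient_filter=set(test_pats))
        for regime in regimes:
            sub_cfg = replace(cfg, regime=regime,
                              seed=_derive_seed(cfg.seed, rep, REGIMES.index(regime)))
            frames, samples = build_marker_dataset(series, marker, sub_cfg,
                                                   table,
                                                   patient_filter=set(train_pats))
            # step-matched budgets: every regime consumes ~2*epochs*nb1
            # optimizer steps, where nb1/nb2 are minibatches per epoch of
            # the frame/sample sets (the sample set is far smaller — one
            # sample per patient — so its epoch count is scaled up)
            nb1 = max(1, -(-len(frames) // cfg.batch_size))
            nb2 = max(1, -(-len(samples) // cfg.batch_size))
            total = 2 * cfg.epochs * nb1
            budget = {
                "supervised": (2 * cfg.epochs, 0),
                "ssl": (0, max(1, round(total / nb2))),
                "hybrid": (max(1, round(total / (nb1 + nb2))), 0),
                "two_stage": (cfg.epochs,
                              max(1, round(cfg.epochs * nb1 / nb2))),
            }[regime]
            model = train_regime(frames, samples, sub_cfg, table,
                                 stage1_epochs=budget[0],
                                 stage2_epochs=budget[1])
            rows.append({"regime": regime, "repeat": rep,
                         "r2": evaluate_forecast(model, test_samples, table)})
    return pd.DataFrame(rows)
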