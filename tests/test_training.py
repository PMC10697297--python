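"""Training engines: metric, convergence, determinism, regime degeneracies,
and the cross-validation protocol."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from glp.encoding import assemble_features, normalize_value
from glp.training import (FrameSet, Stage2Set, TrainConfig, ablation_grid,
                          build_marker_dataset, cross_validate,
                          evaluate_forecast, r_squared, train_hybrid,
                          train_regime, train_stage1, train_stage2)

MARKER = "LDL-c"


def encoded_frames(values_fn, n, table, r=12, seed=0, g=None):
    """Build a FrameSet (or Stage2Set when g is given) of synthetic windows."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _ in range(n):
        vals = values_fn(rng)
        X.append(assemble_features(vals[:-1], [True] * (r + 1), 55.0, 1,
                                   MARKER, table))
        y.append(normalize_value(vals[-1]))
    X, y = np.array(X), np.array(y)
    pids = np.arange(n)
    if g is None:
        return FrameSet(MARKER, X, y, pids)
    return Stage2Set(MARKER, X, y, np.asarray(g), pids)


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(np.full(3, y.mean()), y) == pytest.approx(0.0)

    def test_hand_computed_negative_value(self):
        assert r_squared([1.0, 2.0, 5.0], [1.0, 2.0, 3.0]) == pytest.approx(-1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0], [1.0])
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0, 3.0])


class TestStage1:
    def test_constant_series_is_learned(self, table):
        frames = encoded_frames(lambda rng: np.full(14, 120.0), 64, table)
        cfg = TrainConfig(epochs=50, seed=1)
        model = train_stage1(frames, cfg, table)
        assert model.loss_trace["stage1"][-1] < 1e-4

    def test_seeded_determinism(self, table):
        frames = encoded_frames(
            lambda rng: np.exp(rng.normal(4.7, 0.2, size=14)), 48, table)
        cfg = TrainConfig(epochs=3, seed=7)
        m1 = train_stage1(frames, cfg, table)
        m2 = train_stage1(frames, cfg, table)
        assert m1.loss_trace["stage1"] == m2.loss_trace["stage1"]
        assert m1.param_hash() == m2.param_hash()

    def test_loss_decreases_on_generator_data(self, small_cohort, table):
        _, series, _ = small_cohort
        cfg = TrainConfig(epochs=5, seed=2)
        frames, _ = build_marker_dataset(series, MARKER, cfg, table)
        model = train_stage1(frames, cfg, table)
        trace = model.loss_trace["stage1"]
        assert trace[-1] <= trace[0]

    def test_empty_frames_rejected(self, table):
        empty = FrameSet(MARKER, np.empty((0, 13, 5)), np.empty(0),
                         np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            train_stage1(empty, TrainConfig(), table)


class TestStage2:
    def test_gap_above_limit_rejected(self, table):
        samples = encoded_frames(lambda rng: np.full(14, 100.0), 4, table,
                                 g=[0, 2, 9, 1])
        with pytest.raises(ValueError):
            train_stage2(samples, TrainConfig(), table)

    def test_seeded_determinism(self, table):
        samples = encoded_frames(
            lambda rng: np.exp(rng.normal(4.7, 0.2, size=14)), 16, table,
            g=[0, 1, 2, 3] * 4)
        cfg = TrainConfig(epochs=3, seed=5)
        m1 = train_stage2(samples, cfg, table)
        m2 = train_stage2(samples, cfg, table)
        assert m1.param_hash() == m2.param_hash()

    def test_all_zero_gaps_reproduce_stage1_gradient_path(self, table):
        """With every gap 0 the self-supervised pass degenerates to the
        supervised algorithm: identical parameters on identical windows."""
        def gen(rng):
            return np.exp(rng.normal(4.7, 0.2, size=14))
        frames = encoded_frames(gen, 32, table, seed=3)
        samples = encoded_frames(gen, 32, table, seed=3, g=[0] * 32)
        cfg = TrainConfig(epochs=4, seed=9)
        m1 = train_stage1(frames, cfg, table)
        m2 = train_stage2(samples, cfg, table)
        assert m1.param_hash() == m2.param_hash()


class TestRegimeDegeneracies:
    def test_two_stage_without_stage2_equals_supervised(self, small_cohort,
                                                        table):
        _, series, _ = small_cohort
        cfg = TrainConfig(epochs=2, seed=4)
        frames, samples = build_marker_dataset(series, MARKER, cfg, table)
        sup = train_regime(frames, samples, replace(cfg, regime="supervised"),
                           table)
        two = train_regime(frames, samples, replace(cfg, regime="two_stage"),
                           table, stage2_epochs=0)
        assert sup.param_hash() == two.param_hash()

    def test_two_stage_without_stage1_equals_ssl(self, small_cohort, table):
        _, series, _ = small_cohort
        cfg = TrainConfig(epochs=2, seed=4)
        frames, samples = build_marker_dataset(series, MARKER, cfg, table)
        ssl = train_regime(frames, samples, replace(cfg, regime="ssl"), table)
        two = train_regime(frames, samples, replace(cfg, regime="two_stage"),
                           table, stage1_epochs=0)
        assert ssl.param_hash() == two.param_hash()


class TestHybrid:
    def test_empty_inputs_rejected(self, table):
        frames = encoded_frames(lambda rng: np.full(14, 100.0), 8, table)
        empty = Stage2Set(MARKER, np.empty((0, 13, 5)), np.empty(0),
                          np.empty(0, dtype=int), np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            train_hybrid(frames, empty, TrainConfig(), table)

    def test_runs_and_scores_finite(self, small_cohort, table):
        _, series, _ = small_cohort
        cfg = TrainConfig(epochs=2, seed=6)
        frames, samples = build_marker_dataset(series, MARKER, cfg, table)
        model = train_hybrid(frames, samples, cfg, table)
        r2 = evaluate_forecast(model, samples, table)
        assert np.isfinite(r2)
        m2 = train_hybrid(frames, samples, cfg, table)
        assert model.param_hash() == m2.param_hash()


@pytest.fixture(scope="module")
def report(small_cohort, table):
    _, series, _ = small_cohort
    cfg = TrainConfig(epochs=1, seed=3, regime="supervised",
                      n_folds=5, n_repeats=5)
    return cross_validate(series, MARKER, cfg, table)


class TestCrossValidate:
    def test_entry_count(self, report):
        assert len(report.entries) == 25
        assert report.entries["r2"].notna().all()

    def test_folds_partition_training_patients(self, report, small_cohort):
        _, series, _ = small_cohort
        patients = set(s.patient_id for s in series if s.marker == MARKER)
        for rep_log in report.split_log:
            fold_union = np.concatenate(rep_log["folds"])
            test = rep_log["test_patients"]
            assert len(fold_union) == len(set(fold_union))
            assert set(fold_union) | set(test) == patients
            assert not set(fold_union) & set(test)

    def test_too_few_patients_rejected(self, small_cohort, table):
        _, series, _ = small_cohort
        few = [s for s in series if s.patient_id < 3]
        with pytest.raises(ValueError):
            cross_validate(few, MARKER, TrainConfig(n_folds=5), table)


class TestAblationGrid:
    def test_grid_shape_and_summary_identity(self, small_cohort, table):
        _, series, _ = small_cohort
        cfg = TrainConfig(epochs=1, seed=2, n_folds=2, n_repeats=1)
        tidy, summary = ablation_grid(
            series, MARKER, cfg, table,
            regimes=("supervised", "ssl"), methods=("linear",),
            certain_range=(0, 1))
        assert len(summary) == 4                      # 2 regimes x 1 x 2
        assert len(tidy) == 4 * 2                     # x n_folds
        for _, row in summary.iterrows():
            cell = tidy[(tidy["regime"] == row["regime"])
                        & (tidy["interpolation"] == row["interpolation"])
                        & (tidy["certain"] == row["certain"])]
            assert row["mean_r2"] == pytest.approx(cell["r2"].mean(),
                                                   abs=1e-12)

    def test_shared_splits_across_cells(self, small_cohort, table):
        _, series, _ = small_cohort
        cfg = TrainConfig(epochs=1, seed=8, n_folds=2, n_repeats=1)
        r_a = cross_validate(series, MARKER, replace(cfg, regime="supervised"),
                             table)
        r_b = cross_validate(series, MARKER, replace(cfg, regime="ssl"), table)
        for log_a, log_b in zip(r_a.split_log, r_b.split_log):
            np.testing.assert_array_equal(log_a["test_patients"],
                                          log_b["test_patients"])

    def test_empty_grid_rejected(self, small_cohort, table):
        _, series, _ = small_cohort
        with pytest.raises(ValueError):
            ablation_grid(series, MARKER, TrainConfig(), table, regimes=())
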