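"""Downstream transfer: balancing, episodic windows, frozen extraction,
classifier metrics and agreement."""

import numpy as np
import pytest

from glp.encoding import CERTAIN, DISCRETE, VALUE, denormalize_value
from glp.model import GLPNetwork
from glp.synthetic import CohortConfig, simulate_downstream_cohort
from glp.transfer import (balance_downsample, classification_metrics,
                          episodic_to_frame, extract_representations,
                          mean_pairwise_kappa, run_classifiers,
                          snapshot_export)


@pytest.fixture(scope="module")
def records():
    return simulate_downstream_cohort(CohortConfig(seed=31), n_pos=12,
                                      n_neg=40, effect_size=0.75)


@pytest.fixture(scope="module")
def frozen_models():
    """Untrained (random but fixed) networks — extraction semantics do not
    depend on training."""
    return {m: GLPNetwork(m, seed=5) for m in CohortConfig().markers}


class TestBalanceDownsample:
    def test_default_counts_give_84(self):
        records = simulate_downstream_cohort(CohortConfig(seed=1))
        balanced = balance_downsample(records, seed=0)
        assert len(balanced) == 84
        assert sum(r.event_label for r in balanced) == 42

    def test_balanced_input_unchanged(self, records):
        pos = [r for r in records if r.event_label == 1]
        neg = [r for r in records if r.event_label == 0][:len(pos)]
        assert balance_downsample(pos + neg, seed=0) == pos + neg

    def test_seeded_determinism(self, records):
        a = balance_downsample(records, seed=3)
        b = balance_downsample(records, seed=3)
        assert a == b

    def test_no_positives_rejected(self, records):
        neg_only = [r for r in records if r.event_label == 0]
        with pytest.raises(ValueError):
            balance_downsample(neg_only, seed=0)


class TestEpisodicToFrame:
    def test_single_certainty_bit_at_window_end(self, records, table):
        M = episodic_to_frame(records[0], "LDL-c", table, r=12)
        assert M.shape == (13, 5)
        np.testing.assert_array_equal(M[:, CERTAIN],
                                      [0.0] * 12 + [1.0])

    def test_value_carried_constant(self, records, table):
        M = episodic_to_frame(records[0], "WBC", table, r=12)
        assert np.ptp(M[:, VALUE]) == 0.0
        assert np.ptp(M[:, DISCRETE]) == 0.0

    def test_final_value_round_trips(self, records, table):
        for rec in records[:5]:
            M = episodic_to_frame(rec, "UA", table, r=12)
            assert denormalize_value(M[-1, VALUE]) == pytest.approx(
                rec.values["UA"], abs=1e-9)

    def test_zero_fill_mode(self, records, table):
        M = episodic_to_frame(records[0], "LDL-c", table, r=12, fill="zero")
        assert np.all(M[:-1, VALUE] == 0.0)
        assert M[-1, VALUE] > 0

    def test_missing_marker_rejected(self, records, table):
        rec = records[0]
        bad = type(rec)(rec.patient_id, rec.age, rec.sex,
                        {"LDL-c": 100.0}, rec.event_label, rec.gap_months)
        with pytest.raises(ValueError):
            episodic_to_frame(bad, "WBC", table)


class TestExtractRepresentations:
    def test_widths(self, frozen_models, records, table):
        reps = extract_representations(frozen_models, records, table)
        n = len(records)
        assert reps.original.shape == (n, 8)       # 6 values + age + sex
        assert reps.progress_emb.shape == (n, 30)  # 6 markers x 5
        assert reps.progress_out.shape == (n, 6)
        assert reps.labels.shape == (n,)

    def test_models_stay_frozen(self, frozen_models, records, table):
        before = {m: net.param_hash() for m, net in frozen_models.items()}
        extract_representations(frozen_models, records, table, horizon="g/2")
        after = {m: net.param_hash() for m, net in frozen_models.items()}
        assert before == after

    def test_zero_gap_equals_single_pass(self, frozen_models, table, records):
        rec = records[0]
        zero_g = type(rec)(rec.patient_id, rec.age, rec.sex, rec.values,
                           rec.event_label, 0)
        reps = extract_representations(frozen_models, [zero_g], table)
        for k, marker in enumerate(reps.markers):
            net = frozen_models[marker]
            X = episodic_to_frame(zero_g, marker, table)[None]
            _, nxt = net.libc.forward(X)
            out = net.regressor.forward(nxt)
            np.testing.assert_allclose(reps.progress_emb[0, 5 * k:5 * k + 5],
                                       nxt.data[0], atol=1e-12)
            assert reps.progress_out[0, k] == pytest.approx(out.data[0, 0],
                                                            abs=1e-12)

    def test_marker_model_mismatch_rejected(self, frozen_models, records,
                                            table):
        swapped = dict(frozen_models)
        swapped["LDL-c"] = frozen_models["WBC"]
        with pytest.raises(ValueError):
            extract_representations(swapped, records, table)
        with pytest.raises(ValueError):
            extract_representations({"LDL-c": frozen_models["LDL-c"]},
                                    records, table)


class TestRunClassifiers:
    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.0, 0.05, size=(30, 4)),
                       rng.normal(5.0, 0.05, size=(30, 4))])
        y = np.repeat([0, 1], 30)
        report = run_classifiers(X, y, seed=0, n_repeats=2)
        assert np.all(report.metrics["accuracy"] == 1.0)
        assert report.mean_kappa == pytest.approx(1.0)

    def test_shuffled_labels_score_near_chance(self):
        """Label permutation null: mean AUROC within the permutation band."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        y = rng.permutation(np.repeat([0, 1], 40))
        report = run_classifiers(X, y, seed=1, n_repeats=3)
        # 95% band for AUROC under H0 with n=40/40 is roughly 0.5 +/- 0.13
        assert abs(report.metrics["auroc"].mean() - 0.5) < 0.13

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            run_classifiers(np.zeros((10, 2)), np.zeros(10, dtype=int))


def test_metric_identities_on_hand_confusion_matrix():
    """TP=8, FN=2, TN=9, FP=1."""
    y_true = np.array([1] * 10 + [0] * 10)
    y_pred = np.array([1] * 8 + [0] * 2 + [0] * 9 + [1] * 1)
    m = classification_metrics(y_true, y_pred)
    assert m["sensitivity"] == pytest.approx(0.8)
    assert m["specificity"] == pytest.approx(0.9)
    assert m["accuracy"] == pytest.approx(0.85)
    assert m["precision"] == pytest.approx(8 / 9)
    assert m["f1"] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))


class TestMeanPairwiseKappa:
    def test_perfect_agreement(self):
        p = np.array([1, 0, 1, 1, 0])
        assert mean_pairwise_kappa([p, p.copy(), p.copy()]) == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 0, 1, 1])
        assert mean_pairwise_kappa([a, b]) == pytest.approx(-1.0)

    def test_independent_predictions_average_near_zero(self):
        rng = np.random.default_rng(5)
        kappas = [mean_pairwise_kappa([rng.integers(0, 2, 50),
                                       rng.integers(0, 2, 50)])
                  for _ in range(1000)]
        assert abs(np.mean(kappas)) < 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            mean_pairwise_kappa([np.array([1, 0])])
        with pytest.raises(ValueError):
            mean_pairwise_kappa([np.array([1, 0]), np.array([1, 0, 1])])


class TestSnapshotExport:
    def test_rows_and_inverse_normalization(self, frozen_models, records,
                                            table):
        df = snapshot_export(frozen_models, records, table)
        assert len(df) == 3 * len(records)
        assert set(df["horizon"]) == {"0", "g/2", "g"}
        assert set(records[0].values) <= set(df.columns)
        assert np.all(np.isfinite(df[list(records[0].values)].to_numpy()))

    def test_positive_class_scatters_under_trained_rollout(self, table):
        """With a real effect size, event-positive patients' denormalized
        rollout predictions at horizon g are more dispersed than the
        negatives' (majority over 5 downstream seeds)."""
        from glp.synthetic import simulate_pretext_cohort
        from glp.training import TrainConfig, build_marker_dataset, train_regime

        cfg = CohortConfig(n_patients=80, seed=91, markers=("LDL-c",))
        series, _ = simulate_pretext_cohort(cfg)
        tc = TrainConfig(epochs=25, seed=4)
        frames, samples = build_marker_dataset(series, "LDL-c", tc, table)
        model = train_regime(frames, samples, tc, table)
        wins = 0
        for k in range(5):
            recs = simulate_downstream_cohort(
                CohortConfig(seed=500 + k, markers=("LDL-c",)),
                n_pos=60, n_neg=60, effect_size=0.75)
            df = snapshot_export({"LDL-c": model}, recs, table)
            at_g = df[df["horizon"] == "g"]
            pos = np.log1p(at_g[at_g["event_label"] == 1]["LDL-c"])
            neg = np.log1p(at_g[at_g["event_label"] == 0]["LDL-c"])
            wins += pos.std() > neg.std()
        assert wins >= 3
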