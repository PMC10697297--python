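"""Frozen-representation transfer to episodic binary event classification.

The six per-marker pretrained networks are frozen and applied to episodic
downstream patients (one observation per marker, taken at an index
procedure).  Each patient's single value is carried back across an
(r+1)-month window with the certainty bit set only at the final month, the
window is rolled out to the patient's own horizon (the month gap g to the
event/censor date, or g/2), and the condensed vectors (``progress_emb``,
6 x 5 = 30 features) and regressor outputs (``progress_out``, 6 features)
are concatenated across markers.  Four classifier families (LightGBM, SVM,
logistic regression, k-NN) are then compared on the original features
versus the extracted representations, with mean pairwise Cohen's kappa
measuring their agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, cohen_kappa_score,
                             confusion_matrix, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .encoding import ThresholdTable, assemble_features, denormalize_value
from .framing import DEFAULT_R
from .model import GLPNetwork, rollout
from .synthetic import DownstreamRecord

__all__ = [
    "RepresentationSet", "ClassifierReport",
    "balance_downsample", "episodic_to_frame", "extract_representations",
    "run_classifiers", "mean_pairwise_kappa", "snapshot_export",
    "classification_metrics",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("LGBM", "SVM", "LR", "KNN")


def balance_downsample(records: list, seed: int = 0) -> list:
    """Keep all positives; sample an equal number of negatives without
    replacement.  Already-balanced input is returned unchanged."""
    pos = [r for r in records if r.event_label == 1]
    neg = [r for r in records if r.event_label == 0]
    if not pos:
        raise ValueError("no positive records to balance against")
    if len(pos) > len(neg):
        raise ValueError("positives exceed negatives; downsampling undefined")
    if len(pos) == len(neg):
        return list(records)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    return pos + [neg[i] for i in sorted(keep)]


def episodic_to_frame(record: DownstreamRecord, marker: str,
                      table: ThresholdTable, r: int = DEFAULT_R,
                      fill: str = "carry") -> np.ndarray:
    """Build an (r+1, 5) window from a single observation.

    ``carry`` (default) repeats the observed value across the window;
    ``zero`` fills the preceding months with zero-valued months.  In every
    mode only the final month carries the certainty bit — the single real
    observation sits at the window's end, exactly where a stage-2 window
    anchors its last real value.
    """
    if marker not in record.values:
        raise ValueError(f"record {record.patient_id} has no value for {marker!r}")
    value = record.values[marker]
    if fill == "carry":
        values = np.full(r + 1, value, dtype=np.float64)
    elif fill == "zero":
        values = np.zeros(r + 1, dtype=np.float64)
        values[-1] = value
    else:
        raise ValueError(f"unknown fill mode {fill!r}")
    is_real = np.zeros(r + 1, dtype=bool)
    is_real[-1] = True
    return assemble_features(values, is_real, record.age, record.sex,
                             marker, table)


@dataclass
class RepresentationSet:
    """Per-patient downstream feature blocks."""

    patient_ids: np.ndarray
    original: np.ndarray       # (n, n_markers + 2): normalized values, age, sex
    progress_emb: np.ndarray   # (n, n_markers * 5)
    progress_out: np.ndarray   # (n, n_markers)
    labels: np.ndarray
    g: np.ndarray
    markers: tuple

    def block(self, name: str) -> np.ndarray:
        return {"original": self.original, "progress_emb": self.progress_emb,
                "progress_out": self.progress_out}[name]


def _horizons(g: np.ndarray, horizon: str) -> np.ndarray:
    if horizon == "g":
        return g
    if horizon == "g/2":
        return g // 2
    raise ValueError("horizon must be 'g' or 'g/2'")


def extract_representations(models: dict, records: list,
                            table: ThresholdTable, horizon: str = "g",
                            r: int = DEFAULT_R,
                            fill: str = "carry") -> RepresentationSet:
    """Roll each patient's window out to the chosen horizon under every
    frozen marker model and concatenate the representations.

    `models` maps marker name -> trained GLPNetwork; every marker present
    in the records must have a model whose marker matches.
    """
    markers = tuple(sorted(records[0].values))
    for marker in markers:
        if marker not in models:
            raise ValueError(f"no model supplied for marker {marker!r}")
        if models[marker].marker != marker:
            raise ValueError(
                f"model for {marker!r} was trained on {models[marker].marker!r}")
    g = np.array([rec.gap_months for rec in records], dtype=np.int64)
    steps = _horizons(g, horizon)
    embs, outs, orig_vals = [], [], []
    for marker in markers:
        X = np.stack([episodic_to_frame(rec, marker, table, r, fill)
                      for rec in records])
        res = rollout(models[marker], X, steps, table, marker)
        embs.append(res.progress_emb)
        outs.append(res.progress_out[:, None])
        orig_vals.append(np.log1p([rec.values[marker] for rec in records]))
    original = np.column_stack(
        orig_vals + [np.log1p([rec.age for rec in records]),
                     [float(rec.sex) for rec in records]])
    return RepresentationSet(
        patient_ids=np.array([rec.patient_id for rec in records]),
        original=original,
        progress_emb=np.hstack(embs),
        progress_out=np.hstack(outs),
        labels=np.array([rec.event_label for rec in records], dtype=np.int64),
        g=g,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# downstream classification
# ---------------------------------------------------------------------------

def _make_classifiers(seed: int) -> dict:
    return {
        "LGBM": LGBMClassifier(random_state=seed, verbose=-1),
        "SVM": SVC(random_state=seed),
        "LR": LogisticRegression(max_iter=1000, random_state=seed),
        "KNN": KNeighborsClassifier(),
    }


@dataclass
class ClassifierReport:
    """Cross-validated downstream metrics for the four classifier families."""

    metrics: pd.DataFrame          # rows: classifier x repeat
    kappa_per_repeat: np.ndarray   # mean pairwise kappa, one per repeat
    predictions: dict              # classifier -> (n_repeats, n) held-out labels

    @property
    def mean_metrics(self) -> pd.DataFrame:
        return self.metrics.groupby("classifier").mean(numeric_only=True)

    @property
    def mean_kappa(self) -> float:
        return float(self.kappa_per_repeat.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.metrics["accuracy"].mean())


def classification_metrics(y_true, y_pred, y_prob=None) -> dict:
    """AUROC, accuracy, sensitivity, specificity, precision and F1 of one
    binary prediction vector (AUROC only when scores are given)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "sensitivity": recall_score(y_true, y_pred, zero_division=0),
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    if y_prob is not None:
        out["auroc"] = roc_auc_score(y_true, np.asarray(y_prob, dtype=np.float64))
    return out


def run_classifiers(X: np.ndarray, y: np.ndarray, seed: int = 0,
                    n_repeats: int = 5, n_splits: int = 5) -> ClassifierReport:
    """Stratified cross-validated fit/predict for the four families.

    Each repeat reshuffles the folds; held-out predictions are pooled over
    folds, scored, and retained per classifier so agreement (mean pairwise
    Cohen's kappa) is measured on identical held-out patients.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    rows = []
    kappas = []
    predictions = {name: np.empty((n_repeats, len(y)), dtype=np.int64)
                   for name in CLASSIFIER_NAMES}
    for rep in range(n_repeats):
        rep_seed = int(np.random.SeedSequence((seed, 303, rep)
                                              ).generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=rep_seed)
        preds = {name: np.empty(len(y), dtype=np.int64)
                 for name in CLASSIFIER_NAMES}
        probs = {name: np.empty(len(y)) for name in CLASSIFIER_NAMES}
        for train_idx, test_idx in skf.split(X, y):
            for name, clf in _make_classifiers(rep_seed).items():
                with warnings.catch_warnings():
                    # lightgbm's sklearn wrapper invents feature names for
                    # plain arrays and sklearn then warns at predict time
                    warnings.filterwarnings(
                        "ignore", message="X does not have valid feature names")
                    clf.fit(X[train_idx], y[train_idx])
                    preds[name][test_idx] = clf.predict(X[test_idx])
                    if hasattr(clf, "decision_function"):
                        probs[name][test_idx] = clf.decision_function(X[test_idx])
                    else:
                        probs[name][test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        for name in CLASSIFIER_NAMES:
            rows.append({"classifier": name, "repeat": rep,
                         **classification_metrics(y, preds[name], probs[name])})
            predictions[name][rep] = preds[name]
        kappas.append(mean_pairwise_kappa([preds[n] for n in CLASSIFIER_NAMES]))
    return ClassifierReport(pd.DataFrame(rows), np.array(kappas), predictions)


def mean_pairwise_kappa(predictions: list) -> float:
    """Arithmetic mean of Cohen's kappa over all unordered classifier pairs."""
    if len(predictions) < 2:
        raise ValueError("need at least 2 prediction vectors")
    lengths = {len(p) for p in predictions}
    if len(lengths) != 1:
        raise ValueError("prediction vectors must have equal length")
    kappas = [cohen_kappa_score(a, b) for a, b in combinations(predictions, 2)]
    return float(np.mean(kappas))


def snapshot_export(models: dict, records: list, table: ThresholdTable,
                    r: int = DEFAULT_R, fill: str = "carry") -> pd.DataFrame:
    """Denormalized rollout outputs at horizons 0, g/2 and g per patient.

    The raw material of a scatter-vs-converge distribution plot: one row
    per patient per horizon, one column of denormalized predicted values
    per marker, plus the event label.
    """
    markers = tuple(sorted(records[0].values))
    g = np.array([rec.gap_months for rec in records], dtype=np.int64)
    horizon_steps = {"0": np.zeros_like(g), "g/2": g // 2, "g": g}
    per_marker = {}
    for marker in markers:
        X = np.stack([episodic_to_frame(rec, marker, table, r, fill)
                      for rec in records])
        res = rollout(models[marker], X, g, table, marker)
        per_marker[marker] = {
            name: denormalize_value(res.step_outputs[steps, np.arange(len(g))])
            for name, steps in horizon_steps.items()}
    rows = []
    for name in ("0", "g/2", "g"):
        for i, rec in enumerate(records):
            row = {"patient_id": rec.patient_id, "horizon": name,
                   "event_label": rec.event_label, "gap_months": int(g[i])}
            row.update({m: float(per_marker[m][name][i]) for m in markers})
            rows.append(row)
    return pd.DataFrame(rows)
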