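"""Model/Results front door for the laboratory-progress pipeline.

`GLP` is constructed from cohort data (lists of series or a long-format
DataFrame plus static covariates); `fit` trains one network per marker
under the configured regime on a patient-level train split and scores each
on held-out patients, returning a `GLPResults` carrying the frozen
networks, per-marker held-out R², loss traces and a `summary()` table.
Downstream representation extraction and the classifier comparison hang
off the results object.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import replace

import numpy as np
import pandas as pd

from .encoding import ThresholdTable, default_threshold_table
from .model import GLPNetwork
from .synthetic import LabSeries
from .training import (TrainConfig, _derive_seed, _split_patients,
                       build_marker_dataset, evaluate_forecast, train_regime)
from .transfer import (balance_downsample, extract_representations,
                       run_classifiers, snapshot_export)

__all__ = ["GLP", "GLPResults"]


class GLP:
    """Per-marker laboratory-progress forecasters over one pretext cohort.

    Parameters
    ----------
    series : list of LabSeries
        Longitudinal observations, one series per patient x marker.
    config : TrainConfig, optional
        Training hyperparameters (regime, interpolation method, window
        length r, certainty threshold, epochs, seed, ...).
    thresholds : ThresholdTable, optional
        Clinical category cut-points per marker (defaults ship with the
        package).
    markers : sequence of str, optional
        Restrict fitting to these markers (default: all present).
    """

    def __init__(self, series: list, config: TrainConfig | None = None,
                 thresholds: ThresholdTable | None = None, markers=None):
        if not series:
            raise ValueError("empty cohort")
        self.series = list(series)
        self.config = config or TrainConfig()
        self.thresholds = thresholds or default_threshold_table()
        present = sorted({s.marker for s in self.series})
        self.markers = tuple(markers) if markers is not None else tuple(present)
        missing = [m for m in self.markers if m not in present]
        if missing:
            raise ValueError(f"markers {missing} absent from the cohort")

    @classmethod
    def from_dataframe(cls, long_df: pd.DataFrame, static_df: pd.DataFrame,
                       **kwargs) -> "GLP":
        """Build from a long table (patient_id, marker, month, value) and a
        static table (patient_id, age, sex)."""
        static = static_df.set_index("patient_id")
        series = []
        for (pid, marker), grp in long_df.groupby(["patient_id", "marker"],
                                                  sort=True):
            grp = grp.sort_values("month")
            series.append(LabSeries(
                int(pid), str(marker),
                grp["month"].to_numpy(np.int64),
                grp["value"].to_numpy(np.float64),
                float(static.loc[pid, "age"]), int(static.loc[pid, "sex"])))
        return cls(series, **kwargs)

    def fit(self, test_fraction: float | None = None) -> "GLPResults":
        """Train one network per marker; score each on held-out patients.

        The patient-level split is shared across markers (the split seed
        depends only on the configured seed), so per-marker R² values are
        comparable.
        """
        cfg = self.config
        if test_fraction is not None:
            cfg = replace(cfg, test_fraction=test_fraction)
        patients = np.unique([s.patient_id for s in self.series])
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 404)))
        train_pats, test_pats = _split_patients(patients, cfg.test_fraction, rng)
        models, r2, traces = {}, {}, {}
        for k, marker in enumerate(self.markers):
            sub_cfg = replace(cfg, seed=_derive_seed(cfg.seed, 404, k))
            frames, samples = build_marker_dataset(
                self.series, marker, sub_cfg, self.thresholds,
                patient_filter=set(train_pats))
            model = train_regime(frames, samples, sub_cfg, self.thresholds)
            _, test_samples = build_marker_dataset(
                self.series, marker, sub_cfg, self.thresholds,
                patient_filter=set(test_pats))
            models[marker] = model
            r2[marker] = (evaluate_forecast(model, test_samples, self.thresholds)
                          if len(test_samples) >= 2 else float("nan"))
            traces[marker] = dict(getattr(model, "loss_trace", {}))
        return GLPResults(self, models, r2, traces, cfg)


class GLPResults:
    """Fitted per-marker networks with held-out diagnostics."""

    def __init__(self, model: GLP, networks: dict, r2: dict, loss_traces: dict,
                 config: TrainConfig):
        self.model = model
        self.networks = networks
        self.r2 = r2
        self.loss_traces = loss_traces
        self.config = config
        self.thresholds = model.thresholds

    @property
    def mean_r2(self) -> float:
        vals = [v for v in self.r2.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> str:
        lines = [
            "Laboratory-progress pretraining results",
            "=" * 55,
            f"regime: {self.config.regime:<12}  interpolation: "
            f"{self.config.interpolation}",
            f"window r: {self.config.r} months   certain_min: "
            f"{self.config.certain_min}   g_max: {self.config.g_max}",
            f"epochs/stage: {self.config.epochs}   seed: {self.config.seed}",
            "-" * 55,
            f"{'marker':<15}{'held-out R²':>14}{'final loss':>14}",
        ]
        for marker, net in self.networks.items():
            trace = self.loss_traces.get(marker, {})
            last = np.nan
            for stage in ("stage2", "hybrid", "stage1"):
                if trace.get(stage):
                    last = trace[stage][-1]
                    break
            lines.append(f"{marker:<15}{self.r2[marker]:>14.3f}{last:>14.5f}")
        lines.append("-" * 55)
        lines.append(f"{'mean':<15}{self.mean_r2:>14.3f}")
        return "\n".join(lines)

    # -- downstream transfer ----------------------------------------------

    def extract(self, records: list, horizon: str = "g", fill: str = "carry"):
        """Frozen-model representations for episodic downstream records."""
        return extract_representations(self.networks, records, self.thresholds,
                                       horizon=horizon, r=self.config.r,
                                       fill=fill)

    def transfer_study(self, records: list, seed: int = 0, horizon: str = "g",
                       balance: bool = True, n_repeats: int = 5) -> dict:
        """Downstream classification on original features vs extracted
        representations; returns block name -> ClassifierReport."""
        if balance:
            records = balance_downsample(records, seed=seed)
        reps = self.extract(records, horizon=horizon)
        return {block: run_classifiers(reps.block(block), reps.labels,
                                       seed=seed, n_repeats=n_repeats)
                for block in ("original", "progress_emb", "progress_out")}

    def snapshot(self, records: list) -> pd.DataFrame:
        return snapshot_export(self.networks, records, self.thresholds,
                               r=self.config.r)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = {}
        for k, (marker, net) in enumerate(self.networks.items()):
            fname = f"glp_{k}.npz"
            net.save(directory / fname)
            index[marker] = {"file": fname, "r2": self.r2[marker]}
        meta = {"markers": index,
                "config": {f: getattr(self.config, f)
                           for f in self.config.__dataclass_fields__}}
        (directory / "index.json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load_networks(directory) -> dict:
        directory = pathlib.Path(directory)
        meta = json.loads((directory / "index.json").read_text())
        return {marker: GLPNetwork.load(directory / info["file"])
                for marker, info in meta["markers"].items()}
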