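"""Synthetic cohorts with the statistical structure the method assumes.

Two cohorts are emulated:

* a **pretext cohort** of longitudinal laboratory series — one value per
  visit, visits nominally every 3 months with jitter and dropout, spans of
  at least a year — following a latent log-linear trend
  ``value(t) = baseline * exp(slope * t / 12)`` observed under
  multiplicative AR(1) noise;
* an episodic **downstream cohort** — one observation per marker per
  patient at an index procedure, a binary event label with heavy class
  imbalance, and a month gap g between the index procedure and the event
  (or censoring).

The trend slope is correlated with the baseline level (patients with
higher marker levels progress faster), which gives forward rollouts of a
trained forecaster something real to amplify: event-positive patients are
drawn with shifted and more dispersed levels, so their trajectories
diverge while stable patients converge.  Ground-truth latent trajectories
are returned alongside the observations so recovery tests can score
against the noise-free signal.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_MARKERS",
    "CohortConfig",
    "LabSeries",
    "LatentTrajectory",
    "DownstreamRecord",
    "simulate_pretext_cohort",
    "simulate_downstream_cohort",
    "ground_truth_at",
    "pretext_to_frames",
    "write_pretext_csv",
    "write_downstream_csv",
    "load_pretext_csv",
    "load_downstream_csv",
]

DEFAULT_MARKERS = (
    "Chol/HDL-c", "LDL-c", "LDL-c/HDL-c", "Glucose AC", "WBC", "UA",
)

# Log-scale baseline distributions per marker (conventional units).
_DEFAULT_LOG_MEAN = {
    "Chol/HDL-c": np.log(4.0), "LDL-c": np.log(110.0),
    "LDL-c/HDL-c": np.log(2.5), "Glucose AC": np.log(105.0),
    "WBC": np.log(7.0), "UA": np.log(6.0),
}
_DEFAULT_LOG_SD = {
    "Chol/HDL-c": 0.20, "LDL-c": 0.25, "LDL-c/HDL-c": 0.25,
    "Glucose AC": 0.15, "WBC": 0.20, "UA": 0.15,
}

#: Mean months between the index procedure and the event (2.32 years).
EVENT_GAP_MEAN_MONTHS = 28.0


def _per_marker(value, markers, default_map=None) -> dict:
    """Normalise a scalar / dict / None into a per-marker dict."""
    if value is None:
        return {m: default_map[m] for m in markers}
    if isinstance(value, dict):
        missing = [m for m in markers if m not in value]
        if missing:
            raise ValueError(f"missing per-marker values for {missing}")
        return {m: float(value[m]) for m in markers}
    return {m: float(value) for m in markers}


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for both cohorts.

    Slope and noise parameters act on the log scale; `trend_slope_sd` is
    the SD of the per-year log slope, `noise_sd` the stationary SD of the
    multiplicative AR(1) observation noise.  Trend slopes are correlated
    with the baseline level (`slope_level_coupling`), and baselines in the
    pathological range (above the ~75th percentile) receive an extra
    per-year log slope of `progression_boost` — uncontrolled markers
    progress faster, which is the dynamic the downstream event class is
    meant to express.
    """

    n_patients: int = 200
    markers: tuple = DEFAULT_MARKERS
    visit_interval_months: int = 3
    visit_dropout_prob: float = 0.15
    jitter_months: int = 1
    span_months_range: tuple = (18, 48)
    trend_slope_sd: object = 0.08
    noise_sd: object = 0.05
    baseline_log_mean: object = None
    baseline_log_sd: object = None
    ar1_rho: float = 0.6
    slope_level_coupling: float = 0.6
    progression_boost: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.span_months_range
        if lo < 12:
            raise ValueError("span range below 12 months: series shorter than "
                             "a year are excluded from the study design")
        if lo > hi:
            raise ValueError("span_months_range must be (min, max) with min <= max")
        if not 0 <= self.visit_dropout_prob < 1:
            raise ValueError("visit_dropout_prob must be in [0, 1)")
        if self.visit_interval_months < 1:
            raise ValueError("visit_interval_months must be positive")
        if self.jitter_months < 0:
            raise ValueError("jitter_months must be non-negative")
        if not 0.0 <= abs(self.slope_level_coupling) <= 1.0:
            raise ValueError("slope_level_coupling must lie in [-1, 1]")
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "span_months_range", (int(lo), int(hi)))
        slope = _per_marker(self.trend_slope_sd, self.markers)
        noise = _per_marker(self.noise_sd, self.markers)
        if any(v < 0 for v in slope.values()) or any(v < 0 for v in noise.values()):
            raise ValueError("all standard deviations must be >= 0")
        object.__setattr__(self, "trend_slope_sd", slope)
        object.__setattr__(self, "noise_sd", noise)
        object.__setattr__(
            self, "baseline_log_mean",
            _per_marker(self.baseline_log_mean, self.markers, _DEFAULT_LOG_MEAN))
        object.__setattr__(
            self, "baseline_log_sd",
            _per_marker(self.baseline_log_sd, self.markers, _DEFAULT_LOG_SD))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "markers" in raw:
            raw["markers"] = tuple(raw["markers"])
        if "span_months_range" in raw:
            raw["span_months_range"] = tuple(raw["span_months_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["markers"] = list(self.markers)
        raw["span_months_range"] = list(self.span_months_range)
        for key in ("trend_slope_sd", "noise_sd",
                    "baseline_log_mean", "baseline_log_sd"):
            raw[key] = {m: float(v) for m, v in raw[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass(frozen=True)
class LabSeries:
    """Irregular observations of one patient x one marker."""

    patient_id: int
    marker: str
    months: np.ndarray
    values: np.ndarray
    age: float
    sex: int


@dataclass(frozen=True)
class LatentTrajectory:
    """Noise-free monthly latent values on months 0..T (ground truth)."""

    patient_id: int
    marker: str
    values: np.ndarray
    slope: float      # per-year log slope
    baseline: float


@dataclass(frozen=True)
class DownstreamRecord:
    """One episodic patient: a single value per marker at the index event."""

    patient_id: int
    age: float
    sex: int
    values: dict
    event_label: int          # 1 = event occurred
    gap_months: int           # months from index procedure to event/censor


def ground_truth_at(trajectory: LatentTrajectory, month: int) -> float:
    """Noise-free latent value at an integer month (oracle for tests)."""
    month = int(month)
    if not 0 <= month < len(trajectory.values):
        raise ValueError(f"month {month} outside trajectory range "
                         f"0..{len(trajectory.values) - 1}")
    return float(trajectory.values[month])


def _sample_demographics(rng: np.random.Generator):
    age = float(np.clip(rng.normal(57.0, 12.0), 30.0, 95.0))
    sex = int(rng.random() < 0.65)
    return age, sex


def _visit_months(rng: np.random.Generator, span: int, interval: int,
                  jitter: int, dropout: float) -> np.ndarray:
    """Scheduled visits every `interval` months with jitter and dropout;
    the first (0) and last (span) visits are always retained."""
    months = {0, span}
    k = 1
    while k * interval < span:
        if rng.random() >= dropout:
            m = k * interval
            if jitter:
                m += int(rng.integers(-jitter, jitter + 1))
            if 0 < m < span:
                months.add(m)
        k += 1
    return np.array(sorted(months), dtype=np.int64)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) log-noise of length n with marginal SD `sd`."""
    e = np.empty(n)
    if sd == 0.0:
        e.fill(0.0)
        return e
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_pretext_cohort(config: CohortConfig):
    """Generate the longitudinal pretraining cohort.

    Returns (series, trajectories): one LabSeries and one LatentTrajectory
    per patient x marker.  Fully reproducible from config.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    lo, hi = config.span_months_range
    coupling = config.slope_level_coupling
    series: list[LabSeries] = []
    trajectories: list[LatentTrajectory] = []
    for pid in range(config.n_patients):
        age, sex = _sample_demographics(rng)
        span = int(rng.integers(lo, hi + 1))
        visits = _visit_months(rng, span, config.visit_interval_months,
                               config.jitter_months, config.visit_dropout_prob)
        for marker in config.markers:
            mu = config.baseline_log_mean[marker]
            sd = config.baseline_log_sd[marker]
            z_level = rng.normal()
            z_indep = rng.normal()
            log_baseline = mu + sd * z_level
            slope = config.trend_slope_sd[marker] * (
                coupling * z_level + np.sqrt(1.0 - coupling ** 2) * z_indep)
            if z_level > 0.674:  # pathological range (~top quartile)
                slope += config.progression_boost
            t_grid = np.arange(span + 1, dtype=np.float64)
            latent = np.exp(log_baseline + slope * t_grid / 12.0)
            noise = _ar1_noise(rng, span + 1, config.noise_sd[marker],
                               config.ar1_rho)
            observed = latent[visits] * np.exp(noise[visits])
            series.append(LabSeries(pid, marker, visits, observed, age, sex))
            trajectories.append(LatentTrajectory(
                pid, marker, latent, float(slope), float(np.exp(log_baseline))))
    return series, trajectories


def simulate_downstream_cohort(config: CohortConfig, n_pos: int = 42,
                               n_neg: int = 441,
                               effect_size: float = 1.0):
    """Generate the episodic event-labelled cohort.

    Negative patients draw marker levels from the stable baseline regime;
    positive patients' log levels are shifted by ``0.5 * effect_size`` SDs
    and their dispersion inflated by ``1 + 0.75 * effect_size``, so that
    classes overlap heavily per visit but diverge under forward rollout.
    Event/censoring gaps are geometric with mean ~28 months for both
    classes (class-dependent gaps would leak labels through the rollout
    horizon).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    records: list[DownstreamRecord] = []
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    for pid, label in enumerate(labels):
        age, sex = _sample_demographics(rng)
        values = {}
        for marker in config.markers:
            mu = config.baseline_log_mean[marker]
            sd = config.baseline_log_sd[marker]
            if label == 1:
                mu = mu + 0.5 * effect_size * sd
                sd = sd * (1.0 + 0.75 * effect_size)
            values[marker] = float(np.exp(mu + sd * rng.normal()))
        gap = int(rng.geometric(1.0 / EVENT_GAP_MEAN_MONTHS))
        records.append(DownstreamRecord(pid, age, sex, values, int(label), gap))
    return records


def pretext_to_frames(series: LabSeries):
    """Convenience: the ObservationSequence of a LabSeries."""
    from .interpolation import ObservationSequence
    return ObservationSequence(series.months, series.values)


# ---------------------------------------------------------------------------
# CSV round-tripping (long format + static covariates)
# ---------------------------------------------------------------------------

def write_pretext_csv(series: list, long_path, static_path) -> None:
    long_rows = [(s.patient_id, s.marker, int(m), float(v))
                 for s in series for m, v in zip(s.months, s.values)]
    pd.DataFrame(long_rows, columns=["patient_id", "marker", "month", "value"]
                 ).to_csv(long_path, index=False)
    static = {(s.patient_id): (s.age, s.sex) for s in series}
    pd.DataFrame([(pid, a, x) for pid, (a, x) in sorted(static.items())],
                 columns=["patient_id", "age", "sex"]).to_csv(static_path, index=False)


def load_pretext_csv(long_path, static_path) -> list:
    long = pd.read_csv(long_path)
    static = pd.read_csv(static_path).set_index("patient_id")
    series = []
    for (pid, marker), grp in long.groupby(["patient_id", "marker"], sort=True):
        grp = grp.sort_values("month")
        series.append(LabSeries(
            int(pid), str(marker),
            grp["month"].to_numpy(np.int64), grp["value"].to_numpy(np.float64),
            float(static.loc[pid, "age"]), int(static.loc[pid, "sex"])))
    return series


def write_downstream_csv(records: list, path) -> None:
    markers = sorted({m for r in records for m in r.values})
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "age": r.age, "sex": r.sex,
               "event_label": r.event_label, "gap_months": r.gap_months}
        row.update({m: r.values[m] for m in markers})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_downstream_csv(path, markers=None) -> list:
    df = pd.read_csv(path)
    meta = {"patient_id", "age", "sex", "event_label", "gap_months"}
    if markers is None:
        markers = [c for c in df.columns if c not in meta]
    return [DownstreamRecord(int(r["patient_id"]), float(r["age"]), int(r["sex"]),
                             {m: float(r[m]) for m in markers},
                             int(r["event_label"]), int(r["gap_months"]))
            for _, r in df.iterrows()]
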