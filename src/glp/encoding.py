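"""Per-timestep feature encoding for the laboratory-progress networks.

Each month in a window is encoded as a 5-feature row:

====  ==============  =====================================================
col   name            content
====  ==============  =====================================================
0     value_norm      log1p of the (positive) laboratory value
1     age_norm        log1p of the patient age in years
2     sex_bit         1 = male, 0 = female
3     certain_bit     1 = real observation, 0 = interpolated/predicted
4     discrete_code   clinical category index scaled to [0, 1]
====  ==============  =====================================================

log1p keeps every feature non-negative and needs no cohort-level min/max,
so the encoding leaks no information across patients.  The clinical
category cut-points are configuration (institutions differ); a plausible
default table ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "ThresholdTable",
    "FeatureMatrix",
    "normalize_value",
    "denormalize_value",
    "discretize",
    "assemble_features",
    "default_threshold_table",
    "FEATURE_NAMES",
    "VALUE", "AGE", "SEX", "CERTAIN", "DISCRETE",
]

FEATURE_NAMES = ("value_norm", "age_norm", "sex_bit", "certain_bit", "discrete_code")
VALUE, AGE, SEX, CERTAIN, DISCRETE = range(5)

#: Physiologically plausible default cut-points (conventional units).
#: These are configuration defaults, not clinical assertions.
_DEFAULT_CUTS = {
    "Chol/HDL-c": [3.5, 5.0],
    "LDL-c": [100.0, 130.0],
    "LDL-c/HDL-c": [2.0, 3.5],
    "Glucose AC": [70.0, 126.0],
    "WBC": [4.0, 11.0],
    "UA": [3.5, 7.2],
}


@dataclass(frozen=True)
class ThresholdTable:
    """Per-marker ordered cut-points defining 2 (low/high) or 3
    (low/normal/high) clinical categories."""

    cuts: dict

    def __post_init__(self):
        clean = {}
        for marker, c in self.cuts.items():
            c = [float(v) for v in c]
            if len(c) not in (1, 2):
                raise ValueError(
                    f"{marker}: need 1 or 2 cut-points (2 or 3 groups), got {len(c)}"
                )
            if len(c) == 2 and not c[0] < c[1]:
                raise ValueError(f"{marker}: cut-points must be strictly increasing")
            clean[marker] = tuple(c)
        object.__setattr__(self, "cuts", clean)

    def n_groups(self, marker: str) -> int:
        return len(self._get(marker)) + 1

    def _get(self, marker: str):
        if marker not in self.cuts:
            raise KeyError(f"unknown marker {marker!r}")
        return self.cuts[marker]

    @classmethod
    def from_yaml(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({m: spec["cuts"] if isinstance(spec, dict) else spec
                    for m, spec in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({m: {"cuts": list(c)} for m, c in self.cuts.items()}, fh)


def default_threshold_table() -> ThresholdTable:
    return ThresholdTable(dict(_DEFAULT_CUTS))


#: Alias so the feature matrix has a nominal type; rows are plain ndarrays.
FeatureMatrix = np.ndarray


def normalize_value(x):
    """log(1+x); defined for x >= 0 so the encoded space stays above zero."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("normalize_value requires non-negative input")
    return np.log1p(x)


def denormalize_value(z):
    """Inverse of :func:`normalize_value`: exp(z) - 1."""
    return np.expm1(np.asarray(z, dtype=np.float64))


def discretize(x, marker: str, table: ThresholdTable):
    """0-based category index of the half-open bin [cut_k, cut_{k+1})
    containing x; boundary values fall in the upper bin."""
    cuts = np.asarray(table._get(marker))
    return np.searchsorted(cuts, np.asarray(x, dtype=np.float64), side="right")


def discrete_code(x, marker: str, table: ThresholdTable):
    """Category index scaled to [0, 1] (index / (groups - 1))."""
    idx = discretize(x, marker, table)
    return idx / (table.n_groups(marker) - 1)


def assemble_features(values, is_real, age: float, sex: int,
                      marker: str, table: ThresholdTable) -> np.ndarray:
    """Build the (len(values), 5) feature matrix for one window.

    `values` are raw (denormalized) laboratory values; `is_real` marks which
    months were actually observed.  Age and sex are static per patient and
    repeated down the window.
    """
    values = np.asarray(values, dtype=np.float64)
    is_real = np.asarray(is_real, dtype=bool)
    if values.shape != is_real.shape:
        raise ValueError("values and is_real must have the same length")
    if sex not in (0, 1):
        raise ValueError("sex must be 0 (female) or 1 (male)")
    n = len(values)
    out = np.empty((n, 5), dtype=np.float64)
    out[:, VALUE] = normalize_value(values)
    out[:, AGE] = np.log1p(float(age))
    out[:, SEX] = float(sex)
    out[:, CERTAIN] = is_real.astype(np.float64)
    out[:, DISCRETE] = discrete_code(values, marker, table)
    return out
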