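"""Monthly-timeline interpolation for irregular laboratory series.

Irregular observations (one value per visit month) are densified onto a
monthly grid with one of three interpolants:

* ``linear`` — straight line through each bracketing pair of observations;
* ``pchip`` — shape-preserving piecewise cubic Hermite interpolation with
  Fritsch–Butland node derivatives (the weighted harmonic mean of adjacent
  secant slopes, zeroed where the slopes change sign or vanish);
* ``barycentric`` — the single degree-n interpolating polynomial evaluated
  in the numerically stable barycentric form.

All interpolants reproduce the observations exactly at observed months; no
extrapolation beyond the observed span is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicHermiteSpline

__all__ = [
    "ObservationSequence",
    "InterpolatedTimeline",
    "interpolate_linear",
    "interpolate_pchip",
    "interpolate_barycentric",
    "fill_timeline",
    "METHODS",
]

# Polynomial interpolation through many nodes is numerically fragile; cap
# the node count rather than silently returning garbage.
MAX_BARYCENTRIC_NODES = 50

METHODS = ("linear", "pchip", "barycentric")


@dataclass(frozen=True)
class ObservationSequence:
    """Observed (month, value) pairs of one patient x one marker."""

    months: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        months = np.asarray(self.months, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if months.ndim != 1 or months.shape != values.shape:
            raise ValueError("months and values must be 1-D and equal length")
        if len(months) < 2:
            raise ValueError("need at least 2 observations")
        if np.any(np.diff(months) <= 0):
            raise ValueError("months must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.months)


@dataclass(frozen=True)
class InterpolatedTimeline:
    """Consecutive monthly grid with per-month real-observation flags."""

    months: np.ndarray   # consecutive integers t0..tm
    values: np.ndarray
    is_real: np.ndarray  # bool; True iff the month was observed

    def __post_init__(self):
        months = np.asarray(self.months, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        is_real = np.asarray(self.is_real, dtype=bool)
        if not (len(months) == len(values) == len(is_real)):
            raise ValueError("field lengths differ")
        if np.any(np.diff(months) != 1):
            raise ValueError("months must be consecutive integers")
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "is_real", is_real)

    def __len__(self) -> int:
        return len(self.months)


def _check_query(obs: ObservationSequence, query_months) -> np.ndarray:
    q = np.atleast_1d(np.asarray(query_months, dtype=np.float64))
    if q.size and (q.min() < obs.months[0] or q.max() > obs.months[-1]):
        raise ValueError(
            f"query months must lie within the observed span "
            f"[{obs.months[0]}, {obs.months[-1]}] (no extrapolation)"
        )
    return q


def interpolate_linear(obs: ObservationSequence, query_months) -> np.ndarray:
    """Piecewise-linear interpolation from each bracketing observed pair."""
    q = _check_query(obs, query_months)
    t = obs.months.astype(np.float64)
    y = obs.values
    # index of the left bracket for each query
    k = np.clip(np.searchsorted(t, q, side="right") - 1, 0, len(t) - 2)
    slope = (y[k + 1] - y[k]) / (t[k + 1] - t[k])
    return y[k] + (q - t[k]) * slope


def _pchip_derivatives(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fritsch–Butland node derivatives.

    Interior nodes get the weighted harmonic mean of the two adjacent
    secant slopes, with weights w1 = 2*h_right + h_left and
    w2 = h_right + 2*h_left; the derivative is zero wherever the adjacent
    slopes differ in sign or either vanishes.  Endpoints use the standard
    one-sided three-point formula projected to preserve monotonicity.
    """
    h = np.diff(t)
    d = np.diff(y) / h
    n = len(t)
    deriv = np.zeros(n)
    for j in range(1, n - 1):
        d_left, d_right = d[j - 1], d[j]
        if d_left == 0.0 or d_right == 0.0 or np.sign(d_left) != np.sign(d_right):
            deriv[j] = 0.0
        else:
            h_left, h_right = h[j - 1], h[j]
            w1 = 2.0 * h_right + h_left
            w2 = h_right + 2.0 * h_left
            deriv[j] = (w1 + w2) / (w1 / d_left + w2 / d_right)
    deriv[0] = _pchip_edge(h[0], h[1], d[0], d[1]) if n > 2 else d[0]
    deriv[-1] = _pchip_edge(h[-1], h[-2], d[-1], d[-2]) if n > 2 else d[-1]
    return deriv


def _pchip_edge(h0: float, h1: float, d0: float, d1: float) -> float:
    """One-sided three-point endpoint derivative with sign clipping."""
    est = ((2.0 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
    if np.sign(est) != np.sign(d0):
        return 0.0
    if np.sign(d0) != np.sign(d1) and abs(est) > 3.0 * abs(d0):
        return 3.0 * d0
    return est


def interpolate_pchip(obs: ObservationSequence, query_months) -> np.ndarray:
    """Shape-preserving piecewise cubic Hermite interpolation."""
    q = _check_query(obs, query_months)
    t = obs.months.astype(np.float64)
    if len(obs) == 2:  # a single segment degenerates to the straight line
        return interpolate_linear(obs, q)
    deriv = _pchip_derivatives(t, obs.values)
    spline = CubicHermiteSpline(t, obs.values, deriv)
    return spline(q)


def _barycentric_weights(t: np.ndarray) -> np.ndarray:
    n = len(t)
    if n > MAX_BARYCENTRIC_NODES:
        raise ValueError(
            f"barycentric interpolation capped at {MAX_BARYCENTRIC_NODES} nodes "
            f"(got {n}); high-degree polynomial interpolation is unstable"
        )
    # Rescale nodes to [-2, 2] so the weight products neither overflow nor
    # underflow for realistic month grids.
    scale = 4.0 / (t[-1] - t[0])
    ts = (t - t[0]) * scale - 2.0
    w = np.ones(n)
    for j in range(n):
        diff = ts[j] - ts
        diff[j] = 1.0
        w[j] = 1.0 / np.prod(diff)
    return w, ts, scale


def interpolate_barycentric(obs: ObservationSequence, query_months) -> np.ndarray:
    """Evaluate the degree-n interpolating polynomial in barycentric form."""
    q = _check_query(obs, query_months)
    t = obs.months.astype(np.float64)
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicated nodes")
    w, ts, scale = _barycentric_weights(t)
    qs = (q - t[0]) * scale - 2.0
    out = np.empty_like(qs)
    for i, x in enumerate(qs):
        diff = x - ts
        exact = np.nonzero(diff == 0.0)[0]
        if exact.size:
            out[i] = obs.values[exact[0]]
        else:
            ratios = w / diff
            out[i] = np.dot(ratios, obs.values) / ratios.sum()
    return out


_DISPATCH = {
    "linear": interpolate_linear,
    "pchip": interpolate_pchip,
    "barycentric": interpolate_barycentric,
}


def fill_timeline(obs: ObservationSequence, method: str,
                  upto_month: int) -> InterpolatedTimeline:
    """Densify observations onto a monthly grid from t0 up to `upto_month`.

    `upto_month` must itself be an observed month (interpolation only ever
    runs between real observations); months after it are never filled.
    """
    if method not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    upto_month = int(upto_month)
    if upto_month not in obs.months:
        raise ValueError(f"upto_month={upto_month} is not an observed month")
    grid = np.arange(obs.months[0], upto_month + 1, dtype=np.int64)
    # restrict to the observations at or before upto_month
    mask = obs.months <= upto_month
    sub_months = obs.months[mask]
    if len(sub_months) == 1:  # upto_month == t0: single-point timeline
        values = obs.values[mask].copy()
    else:
        sub = ObservationSequence(sub_months, obs.values[mask])
        values = np.asarray(_DISPATCH[method](sub, grid), dtype=np.float64)
    is_real = np.isin(grid, sub_months)
    # enforce the interpolation condition exactly at observed months
    values[is_real] = obs.values[mask]
    return InterpolatedTimeline(grid, values, is_real)
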