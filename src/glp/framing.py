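"""Sliding-window framing of interpolated monthly timelines.

Stage-1 (supervised) frames slide a fixed window of r+1 monthly points over
the interpolated part of a series, predicting the value one month after the
window; sliding stops so that the target never passes the second-to-last
real observation t_m.  Stage 2 (self-supervised) isolates the single final
window ending at t_m and targets the last real observation t_n, which sits
g = n - m - 1 months beyond the window; samples with g above g_max
(default r/2) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interpolation import InterpolatedTimeline, ObservationSequence

__all__ = [
    "Anchors",
    "Frame",
    "Stage2Sample",
    "locate_anchors",
    "build_stage1_frames",
    "build_stage2_sample",
    "DEFAULT_R",
    "DEFAULT_G_MAX",
]

DEFAULT_R = 12          # window span in months -> r+1 = 13 monthly points
DEFAULT_G_MAX = DEFAULT_R // 2


@dataclass(frozen=True)
class Anchors:
    """First (t0), second-to-last (tm) and last (tn) observed months."""

    t0: int
    tm: int
    tn: int


@dataclass(frozen=True)
class Frame:
    """One stage-1 training frame: window of r+1 monthly values plus the
    next-month target."""

    start_month: int
    values: np.ndarray       # raw values, length r+1
    is_real: np.ndarray      # bool, length r+1
    target_month: int
    target_value: float

    @property
    def n_real(self) -> int:
        return int(self.is_real.sum())


@dataclass(frozen=True)
class Stage2Sample:
    """The final real-anchored window (months tm-r..tm) with the last real
    observation y_tn as target, g months beyond the window end."""

    start_month: int
    values: np.ndarray
    is_real: np.ndarray
    g: int
    target_value: float


def locate_anchors(obs: ObservationSequence) -> Anchors:
    """First, second-to-last and last observed months.

    With exactly two observations the second-to-last collapses onto the
    first (tm = t0).
    """
    months = obs.months
    if len(months) < 2:
        raise ValueError("need at least 2 observations")
    return Anchors(int(months[0]), int(months[-2]), int(months[-1]))


def build_stage1_frames(timeline: InterpolatedTimeline, r: int = DEFAULT_R,
                        certain_min: int = 0) -> list[Frame]:
    """All stage-1 frames of a timeline filled up to t_m.

    Frames start at every month i with i + r <= m - 1 (equivalently the
    target i + r + 1 <= m); a series whose interpolated span is <= r yields
    no frames at all.  Frames with fewer than `certain_min` real
    observations in the window are discarded.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    t0 = int(timeline.months[0])
    m = int(timeline.months[-1])
    frames: list[Frame] = []
    for start in range(t0, m - r):  # start + r <= m - 1
        lo = start - t0
        window_vals = timeline.values[lo:lo + r + 1]
        window_real = timeline.is_real[lo:lo + r + 1]
        if int(window_real.sum()) < certain_min:
            continue
        target_month = start + r + 1
        frames.append(Frame(
            start_month=start,
            values=window_vals.copy(),
            is_real=window_real.copy(),
            target_month=target_month,
            target_value=float(timeline.values[target_month - t0]),
        ))
    return frames


def build_stage2_sample(timeline: InterpolatedTimeline, anchors: Anchors,
                        r: int = DEFAULT_R,
                        g_max: int = DEFAULT_G_MAX,
                        target_value: float | None = None) -> Stage2Sample | None:
    """The one self-supervised sample of a series, or None.

    Returns None when the interpolated span is shorter than the window
    (t_m - t_0 < r) or when the gap to the last observation exceeds g_max.
    `target_value` is the raw value at t_n; it must be supplied because the
    timeline (which stops at t_m) does not contain it.
    """
    if target_value is None:
        raise ValueError("target_value (the observation at t_n) is required")
    t0, tm, tn = anchors.t0, anchors.tm, anchors.tn
    if int(timeline.months[-1]) != tm:
        raise ValueError("timeline must be filled exactly up to t_m")
    if tm - t0 < r:
        return None
    g = tn - tm - 1
    if g < 0:
        raise ValueError("t_n must lie after t_m")
    if g > g_max:
        return None
    lo = (tm - r) - t0
    return Stage2Sample(
        start_month=tm - r,
        values=timeline.values[lo:lo + r + 1].copy(),
        is_real=timeline.is_real[lo:lo + r + 1].copy(),
        g=g,
        target_value=float(target_value),
    )
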