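"""Gaze event detection: I-VT segmentation of raw sample streams.

A gaze stream is a DataFrame with columns ``t_ms`` (non-decreasing, ms from
stimulus onset), ``x_px``, ``y_px`` and ``valid`` (0/1). Samples whose
inter-sample angular velocity stays below a threshold group into fixations;
fast sweeps become saccades; runs of invalid samples longer than a
configurable gap become blinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, pixels_to_degrees

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "BlinkEvent",
    "EventLists",
    "detect_events",
    "read_gaze_tsv",
    "write_gaze_tsv",
]

GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float

    @property
    def end_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    duration_ms: float
    amplitude_deg: float

    @property
    def end_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class BlinkEvent:
    onset_ms: float
    duration_ms: float

    @property
    def end_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class EventLists:
    """Time-ordered fixation/saccade/blink lists for one trial."""

    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    blinks: list[BlinkEvent] = field(default_factory=list)


def _validate_stream(stream: pd.DataFrame) -> None:
    for col in GAZE_COLUMNS:
        if col not in stream.columns:
            raise ValueError(f"gaze stream missing column {col!r}")
    t = stream["t_ms"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("gaze timestamps must be non-decreasing")


def detect_events(
    stream: pd.DataFrame,
    velocity_threshold_deg_s: float = 30.0,
    min_fixation_ms: float = 60.0,
    geometry: ScreenGeometry | None = None,
    blink_min_gap_ms: float = 50.0,
) -> EventLists:
    """Segment a gaze stream into fixations, saccades and blinks (I-VT).

    Consecutive valid samples with angular velocity below
    ``velocity_threshold_deg_s`` form fixation candidates (kept if at least
    ``min_fixation_ms`` long; centroid = mean position); above-threshold
    runs form saccades (amplitude = start-to-end angular distance); invalid
    gaps of at least ``blink_min_gap_ms`` become blinks.
    """
    if velocity_threshold_deg_s <= 0 or min_fixation_ms <= 0:
        raise ValueError("thresholds must be positive")
    geometry = geometry or ScreenGeometry()
    _validate_stream(stream)
    out = EventLists()
    if len(stream) == 0:
        return out

    t = stream["t_ms"].to_numpy(dtype=float)
    x = stream["x_px"].to_numpy(dtype=float)
    y = stream["y_px"].to_numpy(dtype=float)
    valid = stream["valid"].to_numpy().astype(bool)

    # Blinks: maximal invalid runs spanning >= blink_min_gap_ms.
    inv = ~valid
    if inv.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], inv.view(np.int8), [0]))))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            onset, end = t[i0], t[i1 - 1]
            dur = end - onset if i1 - i0 > 1 else _median_dt(t)
            if dur >= blink_min_gap_ms:
                out.blinks.append(BlinkEvent(onset, dur))

    vi = np.flatnonzero(valid)
    if len(vi) < 2:
        return out

    tv, xv, yv = t[vi], x[vi], y[vi]
    dt = np.diff(tv)
    dt[dt == 0] = np.nan
    disp = np.hypot(np.diff(xv), np.diff(yv))
    ang = np.array([pixels_to_degrees(d, geometry) for d in disp])
    vel = ang / (dt / 1000.0)  # deg/s per inter-sample interval
    # An interval crossing an invalid gap is not classifiable as fixation.
    gap = np.diff(vi) > 1
    slow = (vel < velocity_threshold_deg_s) & ~gap
    fast = (vel >= velocity_threshold_deg_s) & ~gap

    for i0, i1, kind in _runs(slow, fast):
        # interval run [i0, i1) covers samples vi[i0] .. vi[i1]
        onset, end = tv[i0], tv[i1]
        if kind == "slow":
            if end - onset >= min_fixation_ms:
                sl = slice(i0, i1 + 1)
                out.fixations.append(
                    FixationEvent(onset, end - onset, float(xv[sl].mean()), float(yv[sl].mean()))
                )
        else:
            amp = pixels_to_degrees(
                float(np.hypot(xv[i1] - xv[i0], yv[i1] - yv[i0])), geometry
            )
            out.saccades.append(SaccadeEvent(onset, end - onset, amp))
    return out


def _median_dt(t: np.ndarray) -> float:
    d = np.diff(t)
    return float(np.median(d)) if len(d) else 0.0


def _runs(slow: np.ndarray, fast: np.ndarray):
    """Yield maximal runs (start, end, kind) of interval classifications."""
    n = len(slow)
    i = 0
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            yield i, j + 1, "slow"
            i = j + 1
        elif fast[i]:
            j = i
            while j + 1 < n and fast[j + 1]:
                j += 1
            yield i, j + 1, "fast"
            i = j + 1
        else:
            i += 1


def read_gaze_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_stream(df)
    return df[list(GAZE_COLUMNS)]


def write_gaze_tsv(stream: pd.DataFrame, path) -> None:
    _validate_stream(stream)
    stream[list(GAZE_COLUMNS)].to_csv(path, sep="\t", index=False)
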