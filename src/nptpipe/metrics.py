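"""AOI gaze metrics over early and late visual-search windows.

Five metrics per AOI and analysis window:

* FFD — first fixation duration (ms)
* TFD — total fixation duration (s)
* VD  — visit (dwell) duration (s); a visit runs from the first fixation
  inside an AOI until gaze leaves it, and includes saccades between
  consecutive in-AOI fixations
* FC  — fixation count
* VC  — visit count

Windows are half-open ``[t0, t1)`` in trial-relative ms. Early search is
``[0, 5000)``; late search runs from 5 s until the subject's response.
Events straddling a window edge contribute only their in-window portion to
duration metrics but count once, in the window containing their onset, for
count metrics — so early + late durations and counts both reconcile with a
whole-trial computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoi import AOI, assign_aoi
from .events import EventLists, FixationEvent

__all__ = ["Visit", "bin_early_late", "compute_visits", "compute_metrics", "EARLY_SPLIT_MS"]

EARLY_SPLIT_MS = 5000.0  # early/late search boundary


@dataclass(frozen=True)
class Visit:
    aoi_index: int
    onset_ms: float
    end_ms: float
    n_fixations: int

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.onset_ms


def bin_early_late(response_time_ms: float) -> tuple[tuple[float, float], tuple[float, float] | None]:
    """Early ``[0, 5000)`` and late ``[5000, response]`` windows (ms).

    The late window is ``None`` when the response came within 5 s.
    """
    if response_time_ms <= 0:
        raise ValueError("response time must be positive")
    early = (0.0, min(EARLY_SPLIT_MS, response_time_ms))
    if response_time_ms <= EARLY_SPLIT_MS:
        return (0.0, EARLY_SPLIT_MS), None
    return (0.0, EARLY_SPLIT_MS), (EARLY_SPLIT_MS, response_time_ms)


def _fixation_aois(fixations: list[FixationEvent], aois: list[AOI]) -> list[int | None]:
    return [assign_aoi(f.x_px, f.y_px, aois) for f in fixations]


def compute_visits(events: EventLists, aois: list[AOI]) -> list[Visit]:
    """Group consecutive same-AOI fixations into visits.

    A visit starts at the onset of the first fixation inside an AOI and ends
    at the end of the last consecutive fixation inside it; saccades between
    those fixations are part of the visit. A fixation landing outside the
    AOI (or on no AOI) closes the visit.
    """
    fixes = sorted(events.fixations, key=lambda f: f.onset_ms)
    labels = _fixation_aois(fixes, aois)
    visits: list[Visit] = []
    i = 0
    while i < len(fixes):
        lab = labels[i]
        if lab is None:
            i += 1
            continue
        j = i
        while j + 1 < len(fixes) and labels[j + 1] == lab:
            j += 1
        visits.append(Visit(lab, fixes[i].onset_ms, fixes[j].end_ms, j - i + 1))
        i = j + 1
    return visits


def _overlap(onset: float, end: float, window: tuple[float, float]) -> float:
    return max(0.0, min(end, window[1]) - max(onset, window[0]))


def _in_window(onset: float, window: tuple[float, float]) -> bool:
    return window[0] <= onset < window[1]


def compute_metrics(
    events: EventLists,
    aois: list[AOI],
    window: tuple[float, float],
) -> pd.DataFrame:
    """Per-AOI metric rows for one trial and one analysis window.

    Returns a DataFrame with one row per AOI and columns
    ``aoi_index, aoi_label, ffd_ms, tfd_s, vd_s, fc, vc``. FFD is NaN for an
    AOI that received no fixation in the window (missing, not zero, so that
    averages run over visited AOIs only).
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    fixes = sorted(events.fixations, key=lambda f: f.onset_ms)
    labels = _fixation_aois(fixes, aois)
    visits = compute_visits(events, aois)

    rows = []
    for idx, aoi in enumerate(aois):
        ffd = np.nan
        tfd = 0.0
        fc = 0
        for f, lab in zip(fixes, labels):
            if lab != idx:
                continue
            tfd += _overlap(f.onset_ms, f.end_ms, window)
            if _in_window(f.onset_ms, window):
                if fc == 0:
                    ffd = _overlap(f.onset_ms, f.end_ms, window)
                fc += 1
        vd = 0.0
        vc = 0
        for v in visits:
            if v.aoi_index != idx:
                continue
            vd += _overlap(v.onset_ms, v.end_ms, window)
            if _in_window(v.onset_ms, window):
                vc += 1
        rows.append(
            {
                "aoi_index": idx,
                "aoi_label": aoi.label,
                "ffd_ms": ffd,
                "tfd_s": tfd / 1000.0,
                "vd_s": vd / 1000.0,
                "fc": fc,
                "vc": vc,
            }
        )
    return pd.DataFrame(rows)


def trial_metrics(
    events: EventLists,
    aois: list[AOI],
    response_time_ms: float,
) -> pd.DataFrame:
    """Early/late/total metric rows for one trial, concatenated."""
    early, late = bin_early_late(response_time_ms)
    frames = []
    for name, win in (
        ("early", early),
        ("late", late),
        ("total", (0.0, max(response_time_ms, EARLY_SPLIT_MS))),
    ):
        if win is None:
            continue
        df = compute_metrics(events, aois, win)
        df.insert(0, "window", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
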