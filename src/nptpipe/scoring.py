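"""Noise-pareidolia-test response scoring and signal-detection sensitivity.

Each trial is a forced face/no-face judgement. Crossing the stimulus truth
with the report gives four categories:

* Face        — face present, face reported (hit)
* Missed      — face present, no face reported (miss)
* Pareidolia  — no face present, face reported (false alarm; the
  phenomenon of interest)
* Noise       — no face present, no face reported (correct rejection)

Sensitivity is summarised by an unequal-variance d-prime

    d_a = sqrt(2 / (1 + s^2)) * (z(H) - s * z(F))

with hit rate H, false-alarm rate F and noise/signal SD ratio ``s``; s = 1
reduces to the classical d' = z(H) - z(F). Extreme rates are handled with
the log-linear correction (0.5 added to every cell, 1 to every
denominator), which keeps d' finite for all integer counts.

Patients are dichotomized on their *original* paper-based NPT pareidolia
count: 0-1 -> non-pareidolic (PDnP), >=2 -> pareidolic (PDP). The
modified-test score is never used for grouping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = [
    "CATEGORIES",
    "TrialRecord",
    "SubjectScore",
    "classify_response",
    "score_subject",
    "dprime",
    "dprime_from_rates",
    "dichotomize",
]

CATEGORIES = ("Face", "Noise", "Pareidolia", "Missed")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation with the subject's report."""

    subject_id: str
    trial_index: int
    stimulus_id: str
    face_present: bool
    reported_face: bool
    response_time_ms: float
    group: str = ""

    @property
    def category(self) -> str:
        return classify_response(self.face_present, self.reported_face)


@dataclass(frozen=True)
class SubjectScore:
    subject_id: str
    group: str
    counts: dict
    hit_rate: float  # NaN when no face trials were seen
    fa_rate: float
    d_prime: float


def classify_response(face_present: bool, reported_face: bool) -> str:
    """Map (stimulus truth, report) to the four-way response category."""
    if face_present:
        return "Face" if reported_face else "Missed"
    return "Pareidolia" if reported_face else "Noise"


def dprime_from_rates(hit_rate: float, fa_rate: float, variance_ratio: float = 1.0) -> float:
    """Unequal-variance d_a from already-corrected rates (must be in (0, 1))."""
    if variance_ratio <= 0:
        raise ValueError("variance ratio must be positive")
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must be strictly inside (0, 1); apply a correction first")
    s = variance_ratio
    return math.sqrt(2.0 / (1.0 + s * s)) * (norm.ppf(hit_rate) - s * norm.ppf(fa_rate))


def dprime(
    n_hit: int,
    n_miss: int,
    n_fa: int,
    n_cr: int,
    variance_ratio: float = 1.0,
    correction: str = "loglinear",
) -> float:
    """d_a from raw category counts.

    ``correction='loglinear'`` (default) always adds 0.5 to each cell and 1
    to each denominator; ``'none'`` uses the raw rates and raises on
    extremes.
    """
    if min(n_hit, n_miss, n_fa, n_cr) < 0:
        raise ValueError("counts must be non-negative")
    if correction == "loglinear":
        H = (n_hit + 0.5) / (n_hit + n_miss + 1.0)
        F = (n_fa + 0.5) / (n_fa + n_cr + 1.0)
    elif correction == "none":
        if n_hit + n_miss == 0 or n_fa + n_cr == 0:
            raise ValueError("empty signal or noise trials")
        H = n_hit / (n_hit + n_miss)
        F = n_fa / (n_fa + n_cr)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return dprime_from_rates(H, F, variance_ratio)


def score_subject(
    trials: list[TrialRecord] | pd.DataFrame,
    variance_ratio: float = 1.0,
) -> SubjectScore:
    """Category counts, rates and d' for one subject's session.

    Partial sessions are scored on the trials available, without
    imputation. With no face (or no noise) trials the corresponding rate is
    NaN; d' still computes through the log-linear correction.
    """
    if isinstance(trials, pd.DataFrame):
        recs = [
            TrialRecord(
                str(r.subject_id), int(r.trial_index), str(r.stimulus_id),
                bool(r.face_present), bool(r.reported_face),
                float(r.response_time_ms), str(getattr(r, "group", "")),
            )
            for r in trials.itertuples()
        ]
    else:
        recs = list(trials)
    counts = {c: 0 for c in CATEGORIES}
    for r in recs:
        counts[r.category] += 1
    n_sig = counts["Face"] + counts["Missed"]
    n_noise = counts["Pareidolia"] + counts["Noise"]
    hit_rate = counts["Face"] / n_sig if n_sig else float("nan")
    fa_rate = counts["Pareidolia"] / n_noise if n_noise else float("nan")
    d = dprime(counts["Face"], counts["Missed"], counts["Pareidolia"], counts["Noise"],
               variance_ratio=variance_ratio)
    sid = recs[0].subject_id if recs else ""
    grp = recs[0].group if recs else ""
    return SubjectScore(sid, grp, counts, hit_rate, fa_rate, d)


def dichotomize(original_npt_pareidolia_count: int) -> str:
    """PDnP for an original-NPT pareidolia count of 0-1, PDP for >= 2."""
    if original_npt_pareidolia_count < 0:
        raise ValueError("pareidolia count must be non-negative")
    return "PDP" if original_npt_pareidolia_count >= 2 else "PDnP"
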