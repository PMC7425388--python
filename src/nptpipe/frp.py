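"""Saccade-onset-locked presaccadic potential extraction.

The analysis object is the fixation that precedes a saccade: EEG is epoched
from -200 to +50 ms around the onset of the *following* saccade, baseline
corrected over [-200, -170) ms, and summarised as the mean amplitude over
[-100, -20) ms averaged across an electrode group (frontal: F3, Fz, F4,
FC1, FC2; parietal: P3, Pz, P4, PO3, PO4). The final 20 ms before onset are
excluded to keep the ocular spike potential out of the measurement window.

Fixations enter the analysis only if they pass five validity rules
(duration 200-2000 ms; following saccade < 80 ms; onset at least 700 ms
after stimulus onset; saccade onset at or before the verbal response; no
blink within +/-300 ms of saccade onset), survive a Mahalanobis-distance
trial-matching step at the empirical 95th percentile, and their epoch stays
within +/-80 uV on the analysed channels. Saccades split into short (< 4
deg) and long (>= 4 deg; exactly 4 deg is assigned long — the boundary
itself is a configurable convention). Response categories with fewer than
50 surviving epochs are excluded per subject; the rest are randomly
subsampled to a common trial count before grand averaging.

All windows are half-open ``[a, b)`` in samples: at 500 Hz an epoch holds
exactly 125 samples and the -20 ms edge sample is excluded from the
amplitude window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .events import EventLists

logger = logging.getLogger(__name__)

__all__ = [
    "EpochConfig",
    "ElectrodeMontage",
    "ValidFixation",
    "Epoch",
    "select_valid_fixations",
    "classify_saccade_size",
    "mahalanobis_match",
    "extract_epochs",
    "reject_artifacts",
    "baseline_correct",
    "mean_amplitude",
    "match_trial_counts",
    "grand_average",
    "amplitude_table",
]


@dataclass(frozen=True)
class EpochConfig:
    """Windows (ms relative to saccade onset), thresholds and conventions."""

    epoch_window_ms: tuple[float, float] = (-200.0, 50.0)
    baseline_window_ms: tuple[float, float] = (-200.0, -170.0)
    amplitude_window_ms: tuple[float, float] = (-100.0, -20.0)
    rejection_uv: float = 80.0
    min_trials: int = 50
    saccade_size_boundary_deg: float = 4.0
    spike_guard_ms: float = 20.0
    min_fixation_ms: float = 200.0
    max_fixation_ms: float = 2000.0
    max_saccade_ms: float = 80.0
    stimulus_onset_exclusion_ms: float = 700.0
    blink_guard_ms: float = 300.0
    mahalanobis_percentile: float = 95.0

    def __post_init__(self) -> None:
        e0, e1 = self.epoch_window_ms
        for w in (self.baseline_window_ms, self.amplitude_window_ms):
            if not (e0 <= w[0] < w[1] <= e1):
                raise ValueError(f"window {w} must lie within the epoch window")
        if self.amplitude_window_ms[1] > -self.spike_guard_ms:
            raise ValueError("amplitude window must end at or before the spike guard")


@dataclass(frozen=True)
class ElectrodeMontage:
    frontal: tuple[str, ...] = ("F3", "Fz", "F4", "FC1", "FC2")
    parietal: tuple[str, ...] = ("P3", "Pz", "P4", "PO3", "PO4")

    def __post_init__(self) -> None:
        if set(self.frontal) & set(self.parietal):
            raise ValueError("frontal and parietal groups must be disjoint")

    @property
    def groups(self) -> dict[str, tuple[str, ...]]:
        return {"frontal": self.frontal, "parietal": self.parietal}

    @property
    def all_channels(self) -> tuple[str, ...]:
        return self.frontal + self.parietal


@dataclass(frozen=True)
class ValidFixation:
    """A fixation admitted to EEG analysis, keyed by its following saccade."""

    subject_id: str
    trial_index: int
    category: str
    fixation_onset_ms: float  # session clock
    fixation_duration_ms: float
    saccade_onset_ms: float  # session clock; epoch time zero
    saccade_duration_ms: float
    saccade_amplitude_deg: float
    size_class: str  # "short" | "long"


@dataclass
class Epoch:
    """One saccade-locked EEG excerpt (channels x samples, uV)."""

    data: np.ndarray
    times_ms: np.ndarray  # relative to saccade onset
    labels: list[str]
    category: str
    size_class: str
    subject_id: str
    trial_index: int
    baseline_corrected: bool = False


def classify_saccade_size(amplitude_deg: float, boundary_deg: float = 4.0) -> str:
    """``short`` below the boundary, ``long`` at or above it."""
    if amplitude_deg < 0:
        raise ValueError("saccade amplitude must be non-negative")
    return "short" if amplitude_deg < boundary_deg else "long"


def select_valid_fixations(
    events_by_trial: dict[int, EventLists],
    trial_records: list,
    config: EpochConfig = EpochConfig(),
    trial_onsets_ms: dict[int, float] | None = None,
) -> list[ValidFixation]:
    """Apply the five validity rules to every fixation-saccade pair.

    ``events_by_trial`` maps trial index to trial-relative event lists;
    ``trial_onsets_ms`` maps trial index to session-clock stimulus onset
    (default 0, i.e. session clock == trial clock).
    """
    out: list[ValidFixation] = []
    records = {r.trial_index: r for r in trial_records}
    for trial_index, ev in sorted(events_by_trial.items()):
        rec = records.get(trial_index)
        if rec is None:
            continue
        onset0 = (trial_onsets_ms or {}).get(trial_index, 0.0)
        fixes = sorted(ev.fixations, key=lambda f: f.onset_ms)
        saccs = sorted(ev.saccades, key=lambda s: s.onset_ms)
        for f in fixes:
            sac = next((s for s in saccs if s.onset_ms >= f.end_ms), None)
            if sac is None:
                continue
            dur_ok = config.min_fixation_ms <= f.duration_ms <= config.max_fixation_ms
            sac_ok = sac.duration_ms < config.max_saccade_ms
            onset_ok = f.onset_ms >= config.stimulus_onset_exclusion_ms
            resp_ok = sac.onset_ms <= rec.response_time_ms
            g = config.blink_guard_ms
            blink_ok = not any(
                b.onset_ms <= sac.onset_ms + g and b.end_ms >= sac.onset_ms - g
                for b in ev.blinks
            )
            if dur_ok and sac_ok and onset_ok and resp_ok and blink_ok:
                out.append(
                    ValidFixation(
                        subject_id=rec.subject_id,
                        trial_index=trial_index,
                        category=rec.category,
                        fixation_onset_ms=onset0 + f.onset_ms,
                        fixation_duration_ms=f.duration_ms,
                        saccade_onset_ms=onset0 + sac.onset_ms,
                        saccade_duration_ms=sac.duration_ms,
                        saccade_amplitude_deg=sac.amplitude_deg,
                        size_class=classify_saccade_size(
                            sac.amplitude_deg, config.saccade_size_boundary_deg
                        ),
                    )
                )
    return out


def mahalanobis_match(
    fixations: list[ValidFixation],
    features: tuple[str, ...] = ("saccade_amplitude_deg", "fixation_duration_ms"),
    percentile: float = 95.0,
) -> list[ValidFixation]:
    """Drop fixations above the empirical Mahalanobis-distance percentile.

    Distances are taken to the pooled mean/covariance of the feature
    vectors (default: saccade amplitude and fixation duration). Raises on a
    singular feature covariance, naming the collinear features.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    X = np.array([[getattr(f, feat) for feat in features] for f in fixations], dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} fixations for {p} features")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < p or np.linalg.cond(cov) > 1e12:
        raise ValueError(
            "singular feature covariance — features "
            f"{features} are collinear or constant"
        )
    inv = np.linalg.inv(cov)
    diff = X - mu
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    cut = np.percentile(d2, percentile)
    return [f for f, d in zip(fixations, d2) if d <= cut]


def mahalanobis_match_per_subject(
    fixations: list[ValidFixation],
    features: tuple[str, ...] = ("saccade_amplitude_deg", "fixation_duration_ms"),
    percentile: float = 95.0,
) -> list[ValidFixation]:
    """Per-subject variant: the percentile cut is computed within subject."""
    out: list[ValidFixation] = []
    subjects = sorted({f.subject_id for f in fixations})
    for sid in subjects:
        sub = [f for f in fixations if f.subject_id == sid]
        out.extend(mahalanobis_match(sub, features, percentile))
    return out


def extract_epochs(
    rec: EEGRecording,
    fixations: list[ValidFixation],
    config: EpochConfig = EpochConfig(),
    montage: ElectrodeMontage | None = None,
) -> list[Epoch]:
    """One saccade-onset-locked epoch per valid fixation.

    Samples cover ``[epoch_start, epoch_end)`` at the recording rate
    (125 samples for -200..+50 ms at 500 Hz). Epochs exceeding the
    recording bounds are skipped and counted in the log.
    """
    e0, e1 = config.epoch_window_ms
    n_samp = int(round((e1 - e0) * rec.sfreq / 1000.0))
    labels = list(montage.all_channels) if montage is not None else list(rec.labels)
    picked = rec.pick(labels)
    times = e0 + np.arange(n_samp) / rec.sfreq * 1000.0
    epochs: list[Epoch] = []
    skipped = 0
    for f in fixations:
        start_ms = f.saccade_onset_ms + e0
        i0 = int(round((start_ms - rec.start_ms) * rec.sfreq / 1000.0))
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            skipped += 1
            continue
        epochs.append(
            Epoch(
                data=picked.data[:, i0:i0 + n_samp].copy(),
                times_ms=times.copy(),
                labels=labels,
                category=f.category,
                size_class=f.size_class,
                subject_id=f.subject_id,
                trial_index=f.trial_index,
            )
        )
    if skipped:
        logger.info("extract_epochs: skipped %d epochs outside recording bounds", skipped)
    return epochs


def reject_artifacts(epochs: list[Epoch], threshold_uv: float = 80.0) -> list[Epoch]:
    """Drop epochs with any |sample| above the threshold on analysed channels."""
    kept = [e for e in epochs if np.max(np.abs(e.data)) <= threshold_uv]
    if len(kept) < len(epochs):
        logger.info("reject_artifacts: dropped %d/%d epochs", len(epochs) - len(kept), len(epochs))
    return kept


def _window_mask(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times_ms >= window[0]) & (times_ms < window[1])


def baseline_correct(epoch: Epoch, window_ms: tuple[float, float] | None = None) -> Epoch:
    """Subtract each channel's mean over the baseline window."""
    window_ms = window_ms or (-200.0, -170.0)
    mask = _window_mask(epoch.times_ms, window_ms)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    data = epoch.data - epoch.data[:, mask].mean(axis=1, keepdims=True)
    return Epoch(data, epoch.times_ms.copy(), list(epoch.labels), epoch.category,
                 epoch.size_class, epoch.subject_id, epoch.trial_index,
                 baseline_corrected=True)


def mean_amplitude(
    epoch: Epoch,
    group_channels: tuple[str, ...],
    window_ms: tuple[float, float] | None = None,
) -> float:
    """Mean over the amplitude window, averaged across the electrode group."""
    window_ms = window_ms or (-100.0, -20.0)
    for ch in group_channels:
        if ch not in epoch.labels:
            raise ValueError(f"channel {ch!r} missing from epoch")
    idx = [epoch.labels.index(ch) for ch in group_channels]
    mask = _window_mask(epoch.times_ms, window_ms)
    return float(epoch.data[np.ix_(idx, np.flatnonzero(mask))].mean())


def match_trial_counts(
    epochs_by_category: dict[str, list[Epoch]],
    min_trials: int = 50,
    seed: int | np.random.Generator = 0,
) -> dict[str, list[Epoch]]:
    """Equalize trial counts across response categories (per subject).

    Categories with fewer than ``min_trials`` epochs are excluded; the
    remaining categories are subsampled without replacement, with the given
    seed, down to the smallest remaining count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept = {c: eps for c, eps in epochs_by_category.items() if len(eps) >= min_trials}
    if not kept:
        return {}
    target = min(len(eps) for eps in kept.values())
    out: dict[str, list[Epoch]] = {}
    for cat in sorted(kept):
        eps = kept[cat]
        if len(eps) == target:
            out[cat] = list(eps)
        else:
            idx = rng.choice(len(eps), size=target, replace=False)
            out[cat] = [eps[i] for i in sorted(idx)]
    return out


def grand_average(epochs: list[Epoch]) -> Epoch:
    """Pointwise mean across epochs (per channel)."""
    if not epochs:
        raise ValueError("grand_average needs at least one epoch")
    ref = epochs[0]
    for e in epochs[1:]:
        if e.data.shape != ref.data.shape or e.labels != ref.labels:
            raise ValueError("epochs must share shape and channel labels")
    data = np.mean([e.data for e in epochs], axis=0)
    return Epoch(data, ref.times_ms.copy(), list(ref.labels), ref.category,
                 ref.size_class, ref.subject_id, -1, ref.baseline_corrected)


def amplitude_table(
    epochs: list[Epoch],
    montage: ElectrodeMontage = ElectrodeMontage(),
    config: EpochConfig = EpochConfig(),
) -> pd.DataFrame:
    """Per (subject, category, size class, electrode group) mean amplitudes.

    Epochs must already be baseline corrected. Returns columns
    ``subject_id, category, size_class, electrode_group, amplitude_uv,
    n_trials``.
    """
    rows = []
    keys = sorted({(e.subject_id, e.category, e.size_class) for e in epochs})
    for sid, cat, size in keys:
        sel = [e for e in epochs
               if (e.subject_id, e.category, e.size_class) == (sid, cat, size)]
        for gname, chans in montage.groups.items():
            amps = [mean_amplitude(e, chans, config.amplitude_window_ms) for e in sel]
            rows.append(
                {
                    "subject_id": sid,
                    "category": cat,
                    "size_class": size,
                    "electrode_group": gname,
                    "amplitude_uv": float(np.mean(amps)),
                    "n_trials": len(sel),
                }
            )
    return pd.DataFrame(rows)
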