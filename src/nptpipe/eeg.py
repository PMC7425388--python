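"""EEG container and deterministic conditioning.

The recording model is a channels x samples matrix in microvolts with a
sampling rate and a session-clock start time. Conditioning follows a fixed
order — average re-reference, 2-40 Hz zero-phase band-pass, downsample to
500 Hz — with an optional externally supplied artefact-removal hook between
filtering and downsampling (e.g. an ICA-based cleaner); by default the hook
is a no-op and artefact protection comes from the blink-exclusion and
amplitude-rejection rules applied at the epoch level.

The band-pass is a 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero-phase, so the slow presaccadic ramp is not
phase-distorted. Downsampling is plain decimation: the 40 Hz low-pass has
already removed everything above the target Nyquist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "average_reference",
    "bandpass",
    "downsample",
    "preprocess",
    "read_eeg_csv",
    "write_eeg_csv",
]


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples, microvolts."""

    labels: list[str]
    data: np.ndarray
    sfreq: float
    start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must equal channel count")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sfreq * 1000.0

    def pick(self, labels: list[str]) -> "EEGRecording":
        """Channel subset, in the requested order."""
        idx = []
        for lab in labels:
            if lab not in self.labels:
                raise ValueError(f"channel {lab!r} not in recording")
            idx.append(self.labels.index(lab))
        return EEGRecording(list(labels), self.data[idx].copy(), self.sfreq, self.start_ms)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample mean across channels (common average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def bandpass(rec: EEGRecording, lo_hz: float = 2.0, hi_hz: float = 40.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyq = rec.sfreq / 2.0
    if not 0 < lo_hz < hi_hz:
        raise ValueError("need 0 < lo < hi")
    if hi_hz >= nyq:
        raise ValueError(f"upper edge {hi_hz} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=rec.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def downsample(rec: EEGRecording, target_hz: float = 500.0) -> EEGRecording:
    """Integer-factor decimation; identity when already at the target rate."""
    ratio = rec.sfreq / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"sampling rate {rec.sfreq} is not an integer multiple of {target_hz}")
    k = int(round(ratio))
    if k == 1:
        return replace(rec, data=rec.data.copy())
    return EEGRecording(list(rec.labels), rec.data[:, ::k].copy(), target_hz, rec.start_ms)


def preprocess(
    rec: EEGRecording,
    lo_hz: float = 2.0,
    hi_hz: float = 40.0,
    target_hz: float = 500.0,
    artifact_hook: Callable[[EEGRecording], EEGRecording] | None = None,
) -> EEGRecording:
    """Reference -> band-pass -> (hook) -> downsample, in that fixed order."""
    rec = average_reference(rec)
    rec = bandpass(rec, lo_hz, hi_hz)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    return downsample(rec, target_hz)


def write_eeg_csv(rec: EEGRecording, path) -> None:
    """Headered CSV matrix: comment header, then one row per sample."""
    with open(path, "w") as fh:
        fh.write(f"# sfreq_hz={rec.sfreq!r}\n")
        fh.write(f"# start_ms={rec.start_ms!r}\n")
        fh.write("# channels=" + ",".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.6f")


def read_eeg_csv(path) -> EEGRecording:
    meta = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    labels = meta["channels"].split(",")
    return EEGRecording(labels, data.T, float(meta["sfreq_hz"]), float(meta["start_ms"]))
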