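"""Synthetic noise-pareidolia-test sessions with known ground truth.

Every downstream stage of the pipeline is verifiable against sessions
generated here: an 80-image stimulus set (20 with an embedded face) with
non-overlapping ellipse/polygon AOIs, per-group response behaviour,
alternating fixation/saccade gaze streams sampled at 120 Hz, and
multichannel EEG carrying a slow saccade-locked presaccadic ramp, an ocular
spike potential at saccade onset, high-amplitude blink artefacts and
1/f-plus-white background noise.

Coordinates are stimulus-relative pixels in the 700 x 700 px image area.
Gaze event boundaries snap to the 120 Hz sample grid so event detection can
be checked against ground truth exactly.

Amplitude convention
--------------------
A configured effect amplitude is the *measured* presaccadic window
statistic: the baseline-corrected mean over the amplitude window after the
standard conditioning chain (average reference; 2-40 Hz zero-phase
band-pass). The generator calibrates the height of the injected linear
ramp by the discrete sampling factor and the conditioning filter's unit
response on an isolated template, so a configured 1.0 uV effect is
recovered as 1.0 uV by the pipeline, not as a filter-attenuated fraction
of a nominal peak. Effects are injected as spatially zero-mean patterns
(+1 on the five target-group electrodes, balanced on the remainder), the
natural space for average-referenced EEG, which makes re-referencing
exactly transparent to the effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .aoi import AOI, STIMULUS_SIZE_PX, Stimulus, StimulusSet
from .eeg import EEGRecording
from .events import BlinkEvent, EventLists, FixationEvent, SaccadeEvent
from .frp import ElectrodeMontage, EpochConfig
from .geometry import ScreenGeometry, pixels_to_degrees
from .scoring import TrialRecord, classify_response

__all__ = [
    "BIOSEMI_32",
    "GroupProfile",
    "EEGParams",
    "SimConfig",
    "SubjectSession",
    "SessionData",
    "generate_stimulus_set",
    "simulate_responses",
    "simulate_gaze",
    "simulate_eeg",
    "simulate_session",
    "DEFAULT_EFFECTS",
    "ramp_unit_gain",
]

BIOSEMI_32 = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

# Group-level presaccadic effect targets (uV), emulating the reported
# pattern: parietal positivity for faces, parietal negativity for noise,
# and a frontal positivity for pareidolias confined to the pareidolic
# patient group.
DEFAULT_EFFECTS: dict[tuple[str, str, str], float] = {
    ("HC", "Face", "parietal"): 0.5,
    ("PDnP", "Face", "parietal"): 0.5,
    ("PDP", "Face", "parietal"): 0.5,
    ("HC", "Noise", "parietal"): -0.93,
    ("PDnP", "Noise", "parietal"): -0.41,
    ("PDP", "Noise", "parietal"): -0.38,
    ("PDnP", "Pareidolia", "frontal"): -0.27,
    ("PDP", "Pareidolia", "frontal"): 0.9,
}


@dataclass(frozen=True)
class GroupProfile:
    """Behavioural knobs for one subject group."""

    hit_rate: float = 0.9
    pareidolia_rate: float = 0.02
    fixation_mean_ms: float = 400.0
    fixation_sd_ms: float = 80.0
    response_median_s: float = 9.0
    response_sigma: float = 0.25  # lognormal spread of response times
    blink_rate_hz: float = 0.1
    p_short_saccade: float = 0.45  # within-AOI refixation probability
    p_target_aoi: float = 0.7  # long saccades aimed at an AOI vs anywhere

    def __post_init__(self) -> None:
        for r in (self.hit_rate, self.pareidolia_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("response rates must be in [0, 1]")


DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "HC": GroupProfile(hit_rate=0.9, pareidolia_rate=0.02, fixation_mean_ms=380.0,
                       response_median_s=8.9),
    "PDnP": GroupProfile(hit_rate=0.8, pareidolia_rate=0.02, fixation_mean_ms=420.0,
                         response_median_s=9.2),
    "PDP": GroupProfile(hit_rate=0.8, pareidolia_rate=0.4, fixation_mean_ms=450.0,
                        response_median_s=9.2),
}


@dataclass(frozen=True)
class EEGParams:
    sfreq: float = 500.0
    channels: tuple[str, ...] = BIOSEMI_32
    noise_sd_uv: float = 5.0
    pink_exponent: float = 1.0
    white_fraction: float = 0.5  # fraction of noise power that is white
    spike_amp_uv: float = 5.0
    spike_sigma_ms: float = 4.0
    blink_peak_uv: float = 150.0
    blink_duration_ms: float = 200.0
    # Conditioning chain the amplitude convention is calibrated against;
    # None disables the filter stage in the calibration.
    conditioning_band_hz: tuple[float, float] | None = (2.0, 40.0)
    conditioning_order: int = 4

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic session (defaults = study conditions)."""

    n_images: int = 80
    n_face_images: int = 20
    groups: tuple[tuple[str, int], ...] = (("HC", 12), ("PDnP", 11), ("PDP", 10))
    profiles: dict[str, GroupProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    eeg: EEGParams = field(default_factory=EEGParams)
    effect_spec: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    montage: ElectrodeMontage = field(default_factory=ElectrodeMontage)
    gaze_fs: float = 120.0
    fixation_cross_ms: float = 2000.0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    synthesize_gaze_samples: bool = True
    synthesize_eeg: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_face_images <= self.n_images:
            raise ValueError("need 0 <= n_face_images <= n_images")
        for grp, _cat, egroup in self.effect_spec:
            if egroup not in self.montage.groups:
                raise ValueError(f"unknown electrode group {egroup!r} in effect_spec")


@dataclass
class SubjectSession:
    subject_id: str
    group: str
    trials: list[TrialRecord]
    trial_onsets_ms: dict[int, float]  # session-clock stimulus onsets
    true_events: dict[int, EventLists]  # trial-relative
    gaze: dict[int, pd.DataFrame]  # trial-relative sample streams
    eeg: EEGRecording | None = None
    true_saccade_effects: pd.DataFrame | None = None  # session clock, per saccade


@dataclass
class SessionData:
    config: SimConfig
    stimulus_set: StimulusSet
    subjects: list[SubjectSession]


# ---------------------------------------------------------------------------
# Stimuli


def generate_stimulus_set(
    n_images: int,
    n_face_images: int,
    seed: int | np.random.Generator = 0,
) -> StimulusSet:
    """Stimuli with non-overlapping AOIs on a 700 x 700 px area.

    Face images carry exactly one off-centre target ellipse plus noise
    polygons; every image carries at least one polygon noise AOI. AOIs are
    placed in disjoint cells of a 3 x 3 grid, which guarantees zero overlap.
    """
    if n_images < 0 or n_face_images < 0:
        raise ValueError("counts must be non-negative")
    if n_face_images > n_images:
        raise ValueError("n_face_images cannot exceed n_images")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    face_flags = np.zeros(n_images, dtype=bool)
    face_flags[:n_face_images] = True
    rng.shuffle(face_flags)

    cell = STIMULUS_SIZE_PX / 3.0
    centres = [((i + 0.5) * cell, (j + 0.5) * cell) for j in range(3) for i in range(3)]
    off_centre = [k for k in range(9) if k != 4]

    stimuli = []
    for i, face in enumerate(face_flags):
        aois: list[AOI] = []
        cells = list(off_centre)
        rng.shuffle(cells)
        if face:
            cx, cy = centres[cells.pop()]
            cx += rng.uniform(-15, 15)
            cy += rng.uniform(-15, 15)
            aois.append(AOI("target", "ellipse",
                            params=(cx, cy, rng.uniform(50, 70), rng.uniform(42, 60),
                                    rng.uniform(0, 180))))
        for _ in range(int(rng.integers(2, 4))):
            cx, cy = centres[cells.pop()]
            cx += rng.uniform(-10, 10)
            cy += rng.uniform(-10, 10)
            n_vert = int(rng.integers(5, 8))
            # evenly spaced angles with bounded jitter keep the star simple
            angles = (2 * math.pi * np.arange(n_vert) / n_vert
                      + rng.uniform(-0.3, 0.3, n_vert) + rng.uniform(0, 2 * math.pi))
            radii = rng.uniform(45, 85, n_vert)
            verts = tuple(
                (cx + r * math.cos(a), cy + r * math.sin(a))
                for a, r in zip(angles, radii)
            )
            aois.append(AOI("noise", "polygon", vertices=verts))
        stimuli.append(Stimulus(f"stim{i:03d}", bool(face), aois))
    return StimulusSet(stimuli)


# ---------------------------------------------------------------------------
# Responses


def simulate_responses(
    profile: GroupProfile,
    stimulus_set: StimulusSet,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sub00",
    group: str = "",
) -> list[TrialRecord]:
    """One forced-choice report and response time per stimulus."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = []
    for idx, stim in enumerate(stimulus_set):
        p_face = profile.hit_rate if stim.face_present else profile.pareidolia_rate
        reported = bool(rng.random() < p_face)
        rt = float(np.clip(
            rng.lognormal(math.log(profile.response_median_s * 1000.0),
                          profile.response_sigma),
            2000.0, 30000.0,
        ))
        trials.append(TrialRecord(subject_id, idx, stim.stimulus_id, stim.face_present,
                                  reported, rt, group))
    return trials


# ---------------------------------------------------------------------------
# Gaze


def _snap(ms: float, dt: float) -> float:
    return round(ms / dt) * dt


def simulate_gaze(
    profile: GroupProfile,
    stimulus: Stimulus,
    response_time_ms: float,
    seed: int | np.random.Generator = 0,
    gaze_fs: float = 120.0,
    geometry: ScreenGeometry | None = None,
    jitter_px: float = 1.0,
    make_samples: bool = True,
) -> tuple[pd.DataFrame | None, EventLists]:
    """Alternating fixation/saccade gaze for one trial, plus ground truth.

    Returns ``(samples, events)``; samples is None when ``make_samples`` is
    False. Event boundaries lie on the sample grid. Short saccades are
    refixations near the current position (< 4 deg); long saccades jump to
    a random AOI (or a random location), so both size classes occur.
    """
    if response_time_ms <= 0:
        raise ValueError("response time must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geometry = geometry or ScreenGeometry()
    dt = 1000.0 / gaze_fs
    size = STIMULUS_SIZE_PX

    def random_point() -> tuple[float, float]:
        return (float(rng.uniform(40, size - 40)), float(rng.uniform(40, size - 40)))

    def aoi_point() -> tuple[float, float]:
        if stimulus.aois and rng.random() < profile.p_target_aoi:
            a = stimulus.aois[int(rng.integers(len(stimulus.aois)))]
            if a.shape == "ellipse":
                cx, cy = a.params[0], a.params[1]
            else:
                xs = [v[0] for v in a.vertices]
                ys = [v[1] for v in a.vertices]
                cx, cy = float(np.mean(xs)), float(np.mean(ys))
            return (cx + float(rng.uniform(-15, 15)), cy + float(rng.uniform(-15, 15)))
        return random_point()

    events = EventLists()
    pos = (size / 2.0, size / 2.0)
    t = 0.0
    while t < response_time_ms - dt:
        dur = _snap(float(np.clip(rng.normal(profile.fixation_mean_ms,
                                             profile.fixation_sd_ms), 150.0, 1200.0)), dt)
        dur = min(dur, _snap(response_time_ms - t, dt))
        if dur < 2 * dt:
            break
        events.fixations.append(FixationEvent(t, dur, pos[0], pos[1]))
        t += dur
        if t >= response_time_ms - 3 * dt:
            break
        if rng.random() < profile.p_short_saccade:
            # short saccade: small displacement, capped below ~4 deg
            ang = rng.uniform(0, 2 * math.pi)
            dist = float(rng.uniform(45, 170))
            nxt = (float(np.clip(pos[0] + dist * math.cos(ang), 5, size - 5)),
                   float(np.clip(pos[1] + dist * math.sin(ang), 5, size - 5)))
        else:
            nxt = aoi_point()
            for _ in range(10):  # keep the sweep fast enough to segment
                if math.hypot(nxt[0] - pos[0], nxt[1] - pos[1]) >= 45:
                    break
                nxt = random_point()
        amp = pixels_to_degrees(math.hypot(nxt[0] - pos[0], nxt[1] - pos[1]), geometry)
        # duration scales with amplitude (main-sequence-like), so the sweep
        # velocity always clears an I-VT threshold of 30 deg/s
        sac_dur = _snap(float(np.clip(2.2 * amp + 21.0, 2 * dt, 75.0)), dt)
        sac_dur = max(sac_dur, 2 * dt)
        events.saccades.append(SaccadeEvent(t, sac_dur, amp))
        t += sac_dur
        pos = nxt

    # Blinks: Poisson arrivals over the trial; overlapping blinks merged.
    n_blinks = int(rng.poisson(profile.blink_rate_hz * response_time_ms / 1000.0)) \
        if response_time_ms > 400 else 0
    raw = sorted(
        (_snap(float(rng.uniform(0, response_time_ms - 260)), dt),
         _snap(float(rng.uniform(100, 250)), dt))
        for _ in range(n_blinks)
    )
    for onset, dur in raw:
        if events.blinks and onset <= events.blinks[-1].end_ms:
            last = events.blinks[-1]
            events.blinks[-1] = BlinkEvent(last.onset_ms,
                                           max(last.end_ms, onset + dur) - last.onset_ms)
        else:
            events.blinks.append(BlinkEvent(onset, dur))

    samples = _render_samples(events, response_time_ms, dt, jitter_px, rng) \
        if make_samples else None
    return samples, events


def _render_samples(events: EventLists, response_time_ms: float, dt: float,
                    jitter_px: float, rng: np.random.Generator) -> pd.DataFrame:
    n = int(response_time_ms / dt) + 1
    t = np.arange(n) * dt
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    fixes = events.fixations
    saccs = events.saccades
    for f in fixes:
        m = (t >= f.onset_ms - dt / 2) & (t <= f.end_ms + dt / 2)
        k = int(m.sum())
        x[m] = f.x_px + rng.normal(0, jitter_px, k)
        y[m] = f.y_px + rng.normal(0, jitter_px, k)
    for i, s in enumerate(saccs):
        pre = next((f for f in reversed(fixes) if f.end_ms <= s.onset_ms + dt / 2), None)
        post = next((f for f in fixes if f.onset_ms >= s.end_ms - dt / 2), None)
        if pre is None or post is None:
            continue
        m = (t > s.onset_ms + dt / 2) & (t < s.end_ms - dt / 2)
        if m.any():
            frac = (t[m] - s.onset_ms) / s.duration_ms
            x[m] = pre.x_px + frac * (post.x_px - pre.x_px)
            y[m] = pre.y_px + frac * (post.y_px - pre.y_px)
    # forward/backward fill any unassigned samples (trailing edge)
    ser_x = pd.Series(x).ffill().bfill()
    ser_y = pd.Series(y).ffill().bfill()
    valid = np.ones(n, dtype=int)
    for b in events.blinks:
        valid[(t >= b.onset_ms) & (t <= b.end_ms)] = 0
    return pd.DataFrame({"t_ms": t, "x_px": ser_x, "y_px": ser_y, "valid": valid})


# ---------------------------------------------------------------------------
# EEG


def _pink_noise(n_channels: int, n_samples: int, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def ramp_unit_gain(
    params: EEGParams,
    epoch_config: EpochConfig = EpochConfig(),
) -> float:
    """Measured window statistic of a unit-height presaccadic ramp.

    Builds one isolated linear ramp (0 at -200 ms to 1 at -20 ms before a
    nominal saccade onset) in a long quiet buffer, applies the conditioning
    band-pass if configured, and evaluates the baseline-corrected mean over
    the amplitude window. The generator divides configured amplitudes by
    this gain, making the convention 'amplitude = measured statistic'.
    """
    fs = params.sfreq
    n = int(10 * fs)
    onset = n // 2
    e0, e1 = epoch_config.epoch_window_ms
    r0 = onset + int(round(e0 * fs / 1000.0))
    ramp0 = onset + int(round(-200.0 * fs / 1000.0))
    ramp1 = onset + int(round(-20.0 * fs / 1000.0))
    buf = np.zeros(n)
    buf[ramp0:ramp1] = np.linspace(0.0, 1.0, ramp1 - ramp0, endpoint=False)
    if params.conditioning_band_hz is not None:
        sos = signal.butter(params.conditioning_order, params.conditioning_band_hz,
                            btype="bandpass", fs=fs, output="sos")
        buf = signal.sosfiltfilt(sos, buf)
    n_ep = int(round((e1 - e0) * fs / 1000.0))
    times = e0 + np.arange(n_ep) / fs * 1000.0
    ep = buf[r0:r0 + n_ep]
    b = epoch_config.baseline_window_ms
    a = epoch_config.amplitude_window_ms
    bmask = (times >= b[0]) & (times < b[1])
    amask = (times >= a[0]) & (times < a[1])
    return float(ep[amask].mean() - ep[bmask].mean())


def _group_pattern(channels: tuple[str, ...], members: tuple[str, ...]) -> np.ndarray:
    """Spatially zero-mean topography: +1 on members, balanced elsewhere."""
    pat = np.zeros(len(channels))
    idx = [channels.index(c) for c in members]
    pat[idx] = 1.0
    rest = [i for i in range(len(channels)) if i not in idx]
    pat[rest] = -len(idx) / len(rest)
    return pat


def simulate_eeg(
    saccade_effects: list[tuple[float, dict[str, float]]],
    blink_onsets_ms: list[float],
    duration_ms: float,
    params: EEGParams = EEGParams(),
    montage: ElectrodeMontage = ElectrodeMontage(),
    seed: int | np.random.Generator = 0,
    epoch_config: EpochConfig = EpochConfig(),
    start_ms: float = 0.0,
) -> EEGRecording:
    """Continuous synthetic EEG (channels x samples, uV).

    ``saccade_effects`` is a list of (saccade onset in session-clock ms,
    {electrode group -> configured amplitude in uV}). Each saccade gets a
    linear presaccadic ramp over [-200, -20) ms (height calibrated, see
    module docstring) and a brief Gaussian spike potential at onset. Each
    blink adds a half-cosine artefact on the four frontopolar channels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.sfreq
    chans = params.channels
    for _, eff in saccade_effects:
        for g in eff:
            if g not in montage.groups:
                raise ValueError(f"unknown electrode group {g!r}")
            for ch in montage.groups[g]:
                if ch not in chans:
                    raise ValueError(f"montage channel {ch!r} not simulated")
    n = int(round(duration_ms * fs / 1000.0))
    data = np.zeros((len(chans), n))

    if params.noise_sd_uv > 0:
        wf = params.white_fraction
        noise = np.zeros((len(chans), n))
        if wf > 0:
            noise += math.sqrt(wf) * rng.standard_normal((len(chans), n))
        if wf < 1:
            noise += math.sqrt(1 - wf) * _pink_noise(len(chans), n,
                                                     params.pink_exponent, rng)
        data += params.noise_sd_uv * noise

    gain = ramp_unit_gain(params, epoch_config)
    patterns = {g: _group_pattern(chans, members) for g, members in montage.groups.items()}

    spike_pat = _group_pattern(chans, tuple(c for c in ("Fp1", "Fp2", "AF3", "AF4")
                                            if c in chans))
    sig_samp = params.spike_sigma_ms * fs / 1000.0
    half = int(round(3 * sig_samp))
    spike_kernel = params.spike_amp_uv * np.exp(
        -0.5 * ((np.arange(-half, half + 1)) / sig_samp) ** 2)

    for t0, eff in saccade_effects:
        onset = int(round((t0 - start_ms) * fs / 1000.0))
        r0 = onset + int(round(-200.0 * fs / 1000.0))
        r1 = onset + int(round(-20.0 * fs / 1000.0))
        if r0 < 0 or onset + half + 1 > n:
            continue
        ramp = np.linspace(0.0, 1.0, r1 - r0, endpoint=False)
        for g, amp in eff.items():
            data[:, r0:r1] += np.outer(patterns[g], (amp / gain) * ramp)
        if params.spike_amp_uv != 0:
            data[:, onset - half:onset + half + 1] += np.outer(spike_pat, spike_kernel)

    if params.blink_peak_uv != 0:
        blink_chans = [i for i, c in enumerate(chans) if c in ("Fp1", "Fp2", "AF3", "AF4")]
        nb = int(round(params.blink_duration_ms * fs / 1000.0))
        kernel = params.blink_peak_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(nb) / nb))
        for tb in blink_onsets_ms:
            b0 = int(round((tb - start_ms) * fs / 1000.0))
            if b0 < 0 or b0 + nb > n:
                continue
            data[np.ix_(blink_chans, range(b0, b0 + nb))] += kernel
    return EEGRecording(list(chans), data, fs, start_ms)


# ---------------------------------------------------------------------------
# Whole sessions


def simulate_session(config: SimConfig = SimConfig()) -> SessionData:
    """Generate the complete multi-subject session described by ``config``.

    Reproducible: identical config (including seed) gives bit-identical
    output. Each subject receives independent responses, gaze and EEG from
    a seed sequence spawned off ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    stim_rng = np.random.default_rng(root.spawn(1)[0])
    stimulus_set = generate_stimulus_set(config.n_images, config.n_face_images, stim_rng)

    subjects: list[SubjectSession] = []
    counter = 0
    for group, n_sub in config.groups:
        profile = config.profiles[group]
        for _ in range(n_sub):
            sid = f"sub{counter:02d}"
            rng = np.random.default_rng(root.spawn(1)[0])
            trials = simulate_responses(profile, stimulus_set, rng, sid, group)

            onsets: dict[int, float] = {}
            true_events: dict[int, EventLists] = {}
            gaze: dict[int, pd.DataFrame] = {}
            clock = 500.0  # lead-in before the first fixation cross
            sac_effects: list[tuple[float, dict[str, float]]] = []
            blink_onsets: list[float] = []
            eff_rows = []
            for rec in trials:
                clock += config.fixation_cross_ms
                onsets[rec.trial_index] = clock
                samples, ev = simulate_gaze(
                    profile, stimulus_set.get(rec.stimulus_id), rec.response_time_ms,
                    rng, config.gaze_fs, config.geometry,
                    make_samples=config.synthesize_gaze_samples,
                )
                true_events[rec.trial_index] = ev
                if samples is not None:
                    gaze[rec.trial_index] = samples
                cat = rec.category
                eff = {
                    g: a for (grp, c, g), a in config.effect_spec.items()
                    if grp == group and c == cat
                }
                for s in ev.saccades:
                    sac_effects.append((clock + s.onset_ms, eff))
                    eff_rows.append({"trial_index": rec.trial_index,
                                     "saccade_onset_ms": clock + s.onset_ms,
                                     "category": cat,
                                     **{f"amp_{g}": a for g, a in eff.items()}})
                blink_onsets.extend(clock + b.onset_ms for b in ev.blinks)
                clock += rec.response_time_ms

            eeg = None
            if config.synthesize_eeg:
                eeg = simulate_eeg(
                    sac_effects, blink_onsets, clock + 500.0, config.eeg,
                    config.montage, rng, start_ms=0.0,
                )
            subjects.append(
                SubjectSession(sid, group, trials, onsets, true_events, gaze, eeg,
                               pd.DataFrame(eff_rows))
            )
            counter += 1
    return SessionData(config, stimulus_set, subjects)
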