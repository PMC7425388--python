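"""Valid-fixation selection, epoching, baseline, amplitudes, trial matching."""

import dataclasses

import numpy as np
import pytest

from nptpipe.eeg import EEGRecording
from nptpipe.events import BlinkEvent, EventLists, FixationEvent, SaccadeEvent
from nptpipe.frp import (
    ElectrodeMontage,
    Epoch,
    EpochConfig,
    ValidFixation,
    baseline_correct,
    classify_saccade_size,
    extract_epochs,
    grand_average,
    mahalanobis_match,
    match_trial_counts,
    mean_amplitude,
    reject_artifacts,
    select_valid_fixations,
)
from nptpipe.scoring import TrialRecord
from nptpipe.simulate import GroupProfile, generate_stimulus_set, simulate_gaze


def make_trial(trial_index=0, rt=9000.0, face=False, reported=False):
    return TrialRecord("s0", trial_index, f"stim{trial_index:03d}", face, reported, rt)


def fixation_chain(fix_onset, fix_dur, sac_dur=40.0, amp=2.0, blink_at=None):
    ev = EventLists()
    ev.fixations = [FixationEvent(fix_onset, fix_dur, 100, 100)]
    ev.saccades = [SaccadeEvent(fix_onset + fix_dur, sac_dur, amp)]
    if blink_at is not None:
        ev.blinks = [BlinkEvent(blink_at, 150.0)]
    return ev


class TestSelectValidFixations:
    # Independent oracle: the five rules coded as separate predicates.
    @staticmethod
    def rule_duration(f, s, cfg):
        return cfg.min_fixation_ms <= f.duration_ms <= cfg.max_fixation_ms

    @staticmethod
    def rule_saccade(f, s, cfg):
        return s.duration_ms < cfg.max_saccade_ms

    @staticmethod
    def rule_onset(f, s, cfg):
        return f.onset_ms >= cfg.stimulus_onset_exclusion_ms

    @staticmethod
    def rule_response(f, s, cfg, rt):
        return s.onset_ms <= rt

    @staticmethod
    def rule_blink(f, s, cfg, blinks):
        return all(b.end_ms < s.onset_ms - cfg.blink_guard_ms
                   or b.onset_ms > s.onset_ms + cfg.blink_guard_ms for b in blinks)

    def oracle(self, ev, rt, cfg):
        kept = []
        fixes = sorted(ev.fixations, key=lambda f: f.onset_ms)
        for f in fixes:
            s = next((s for s in sorted(ev.saccades, key=lambda s: s.onset_ms)
                      if s.onset_ms >= f.end_ms), None)
            if s is None:
                continue
            if (self.rule_duration(f, s, cfg) and self.rule_saccade(f, s, cfg)
                    and self.rule_onset(f, s, cfg) and self.rule_response(f, s, cfg, rt)
                    and self.rule_blink(f, s, cfg, ev.blinks)):
                kept.append((f.onset_ms, s.onset_ms))
        return kept

    def test_one_violation_per_rule(self, epoch_config):
        cfg = epoch_config
        cases = {
            "ok": fixation_chain(1000, 400),
            "too_short": fixation_chain(1000, 150),
            "too_long": fixation_chain(1000, 2500),
            "slow_saccade": fixation_chain(1000, 400, sac_dur=90.0),
            "too_early": fixation_chain(300, 350),
            "after_response": fixation_chain(8900, 400),
            "blink_near_saccade": fixation_chain(1000, 400, blink_at=1350.0),
        }
        for name, ev in cases.items():
            out = select_valid_fixations({0: ev}, [make_trial(rt=9000)], cfg)
            expected = self.oracle(ev, 9000, cfg)
            assert len(out) == len(expected), name
            assert (len(out) == 1) == (name == "ok"), name

    def test_closed_duration_bounds(self, epoch_config):
        for dur, ok in ((199.0, False), (200.0, True), (2000.0, True), (2001.0, False)):
            ev = fixation_chain(1000, dur)
            out = select_valid_fixations({0: ev}, [make_trial()], epoch_config)
            assert bool(out) == ok

    def test_everything_before_onset_exclusion_empty(self, epoch_config):
        ev = fixation_chain(100, 300)
        assert select_valid_fixations({0: ev}, [make_trial()], epoch_config) == []

    def test_matches_oracle_on_random_sessions(self, epoch_config, rng):
        stimuli = generate_stimulus_set(4, 1, rng)
        profile = GroupProfile(blink_rate_hz=0.3)
        for k, stim in enumerate(stimuli):
            rt = float(rng.uniform(5000, 11000))
            _, ev = simulate_gaze(profile, stim, rt, rng, make_samples=False)
            out = select_valid_fixations({k: ev}, [make_trial(k, rt)], epoch_config)
            expected = self.oracle(ev, rt, epoch_config)
            assert [(v.fixation_onset_ms, v.saccade_onset_ms) for v in out] == expected

    def test_session_clock_offsets_applied(self, epoch_config):
        ev = fixation_chain(1000, 400)
        out = select_valid_fixations({0: ev}, [make_trial()], epoch_config,
                                     trial_onsets_ms={0: 20000.0})
        assert out[0].saccade_onset_ms == pytest.approx(21400.0)


class TestClassifySaccadeSize:
    @pytest.mark.parametrize("amp,expected", [
        (3.9, "short"), (4.0, "long"), (12.0, "long"), (0.0, "short"),
    ])
    def test_boundary(self, amp, expected):
        assert classify_saccade_size(amp) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_saccade_size(-0.1)


def vf(i, amp, dur, cat="Noise", subject="s0"):
    return ValidFixation(subject, i, cat, 1000.0 * i, dur, 1000.0 * i + dur,
                         40.0, amp, classify_saccade_size(amp))


class TestMahalanobisMatch:
    def test_removal_fraction(self, rng):
        n = 10_000
        amps = rng.normal(5, 2, n).clip(0.1)
        durs = rng.normal(400, 80, n)
        fixes = [vf(i, a, d) for i, (a, d) in enumerate(zip(amps, durs))]
        kept = mahalanobis_match(fixes)
        removed = n - len(kept)
        assert abs(removed / n - 0.05) <= 1.0 / np.sqrt(n)

    def test_distances_match_quadratic_form_loop(self, rng):
        n = 300
        X = rng.normal(size=(n, 2)) * [1.2, 50.0] + [6.0, 400.0]
        X[:, 0] = np.abs(X[:, 0])
        fixes = [vf(i, x[0], x[1]) for i, x in enumerate(X)]
        kept = mahalanobis_match(fixes, percentile=90.0)
        # oracle: explicit per-row quadratic form
        mu = X.mean(axis=0)
        cov_inv = np.linalg.inv(np.cov(X, rowvar=False))
        d2 = np.array([ (x - mu) @ cov_inv @ (x - mu) for x in X ])
        cut = np.percentile(d2, 90.0)
        expected = [f for f, d in zip(fixes, d2) if d <= cut]
        assert [k.trial_index for k in kept] == [e.trial_index for e in expected]

    def test_singular_covariance_names_features(self):
        fixes = [vf(i, 3.0, 400.0) for i in range(20)]
        with pytest.raises(ValueError, match="saccade_amplitude_deg"):
            mahalanobis_match(fixes)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_match([vf(0, 1.0, 300.0)])


def ramp_epoch(amplitude=1.0, sfreq=500.0, n_channels=2, constant=None):
    """Epoch whose channels carry a linear ramp 0 -> amplitude over [-200, -20)."""
    n = int(round(250 * sfreq / 1000))
    times = -200.0 + np.arange(n) / sfreq * 1000.0
    tr = np.zeros(n)
    ramp_mask = (times >= -200) & (times < -20)
    tr[ramp_mask] = np.linspace(0, 1, ramp_mask.sum(), endpoint=False) * amplitude
    tr[times >= -20] = 0.0
    if constant is not None:
        tr = np.full(n, float(constant))
    data = np.tile(tr, (n_channels, 1))
    return Epoch(data, times, [f"c{i}" for i in range(n_channels)], "Noise",
                 "short", "s0", 0)


class TestExtractEpochs:
    def test_125_samples_at_500hz(self, montage):
        labels = list(montage.all_channels)
        rec = EEGRecording(labels, np.zeros((10, 5000)), 500.0)
        fixes = [vf(3, 2.0, 400.0)]  # saccade at 3400 ms
        eps = extract_epochs(rec, fixes, montage=montage)
        assert len(eps) == 1
        assert eps[0].data.shape == (10, 125)
        assert eps[0].times_ms[0] == pytest.approx(-200.0)
        assert eps[0].times_ms[-1] == pytest.approx(48.0)

    def test_epoch_at_recording_start_skipped(self, montage):
        labels = list(montage.all_channels)
        rec = EEGRecording(labels, np.zeros((10, 500)), 500.0)
        fixes = [ValidFixation("s0", 0, "Noise", 0.0, 100.0, 100.0, 40.0, 2.0, "short")]
        assert extract_epochs(rec, fixes, montage=montage) == []


class TestRejectArtifacts:
    def test_threshold_is_exclusive_above(self):
        over = ramp_epoch(constant=0.0)
        over.data[0, 5] = 81.0
        under = ramp_epoch(constant=0.0)
        under.data[0, 5] = 79.9
        kept = reject_artifacts([over, under], 80.0)
        assert kept == [under]


class TestBaselineAndAmplitude:
    def test_constant_epoch_zeroed(self):
        out = baseline_correct(ramp_epoch(constant=3.3))
        assert np.allclose(out.data, 0.0)
        assert out.baseline_corrected

    def test_baseline_window_mean_vanishes(self, rng):
        ep = ramp_epoch()
        ep.data += rng.normal(size=ep.data.shape)
        out = baseline_correct(ep)
        mask = (out.times_ms >= -200) & (out.times_ms < -170)
        assert np.abs(out.data[:, mask].mean(axis=1)).max() < 1e-12

    def test_linear_ramp_closed_form(self):
        """Analytic window means of the discrete ramp (500 Hz sampling)."""
        A = 2.0
        out = baseline_correct(ramp_epoch(A))
        got = mean_amplitude(out, ("c0", "c1"))
        # discrete ramp r_k = A*k/90 on the 90 samples covering [-200,-20);
        # baseline samples k=0..14, amplitude-window samples k=50..89
        expected = A * (np.mean(np.arange(50, 90)) - np.mean(np.arange(15))) / 90.0
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(A * 125.0 / 180.0 * (139 - 14) / 125.0)

    def test_amplitude_equals_hand_loop(self, rng):
        ep = ramp_epoch()
        ep.data = rng.normal(size=ep.data.shape)
        got = mean_amplitude(ep, ("c0",), (-100.0, -20.0))
        total = 0.0
        count = 0
        for j, t in enumerate(ep.times_ms):
            if -100 <= t < -20:
                total += ep.data[0, j]
                count += 1
        assert got == pytest.approx(total / count, rel=1e-12)

    def test_zero_epoch_amplitude_zero(self):
        assert mean_amplitude(ramp_epoch(constant=0.0), ("c0",)) == 0.0

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mean_amplitude(ramp_epoch(), ("F3",))


class TestMatchTrialCounts:
    def make(self, counts):
        return {cat: [ramp_epoch() for _ in range(n)] for cat, n in counts.items()}

    def test_small_category_excluded_and_rest_equalized(self):
        out = match_trial_counts(self.make({"Face": 120, "Noise": 300, "Pareidolia": 30}),
                                 min_trials=50, seed=0)
        assert set(out) == {"Face", "Noise"}
        assert len(out["Face"]) == 120 and len(out["Noise"]) == 120

    def test_equal_counts_identity(self):
        src = self.make({"Face": 60, "Noise": 60})
        out = match_trial_counts(src, min_trials=50, seed=0)
        assert out["Face"] == src["Face"] and out["Noise"] == src["Noise"]

    def test_same_seed_same_subset(self):
        src = self.make({"Face": 80, "Noise": 200})
        a = match_trial_counts(src, seed=42)
        b = match_trial_counts(src, seed=42)
        assert [id(e) for e in a["Noise"]] == [id(e) for e in b["Noise"]]

    def test_all_below_minimum_gives_empty(self):
        assert match_trial_counts(self.make({"Face": 10}), min_trials=50) == {}


class TestGrandAverage:
    def test_single_epoch_identity(self):
        ep = ramp_epoch()
        avg = grand_average([ep])
        assert np.array_equal(avg.data, ep.data)

    def test_mean_of_amplitudes(self):
        eps = [baseline_correct(ramp_epoch(1.0 * 180 / 125)),
               baseline_correct(ramp_epoch(3.0 * 180 / 125))]
        avg = grand_average(eps)
        assert mean_amplitude(avg, ("c0", "c1")) == pytest.approx(2.0, rel=1e-9)

    def test_linearity_against_per_epoch_mean(self, rng):
        eps = []
        for _ in range(7):
            e = ramp_epoch()
            e.data = rng.normal(size=e.data.shape)
            eps.append(e)
        avg_amp = mean_amplitude(grand_average(eps), ("c0",))
        per = np.mean([mean_amplitude(e, ("c0",)) for e in eps])
        assert avg_amp == pytest.approx(per, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grand_average([])


def test_epoch_config_window_validation():
    with pytest.raises(ValueError):
        EpochConfig(baseline_window_ms=(-300.0, -250.0))
    with pytest.raises(ValueError):
        EpochConfig(amplitude_window_ms=(-100.0, -10.0))
    with pytest.raises(ValueError):
        ElectrodeMontage(frontal=("Pz",))
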