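# Methods

This note documents the models, conventions and design choices behind
`nptpipe`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data tests do and do not show.

## Task and data model

A session presents `n_images` stimuli (default 80, of which 20 contain an
embedded two-tone face) for a forced face/no-face judgement with a verbal
response; each stimulus is preceded by a 2-s fixation cross. Gaze is
sampled at 120 Hz in stimulus-relative pixels over a 700 × 700 px image
area (viewing distance 800 mm, pixel pitch 0.2766 mm/px — a 24″ 16:9 panel;
the nominal resolution is carried as metadata only). EEG is a 32-channel
recording in µV referenced arbitrarily; all streams share a session clock
in milliseconds, with per-trial stimulus onsets recorded in the trial
table rather than inferred from hardware triggers.

## Gaze events and AOI metrics

Event detection is I-VT: inter-sample angular velocity below 30°/s groups
samples into fixations (minimum 60 ms; centroid = mean position), above it
into saccades (amplitude = start-to-end angular distance through
`2·atan(px·pitch / 2d)`), and runs of invalid samples of at least 50 ms
become blinks. These defaults are explicit substitutes for an undisclosed
vendor algorithm, and are configurable.

Visits (dwells) span from the first fixation inside an AOI to the end of
the last consecutive fixation inside it, including saccades between them.
Analysis windows are half-open `[t0, t1)` ms: early search `[0, 5000)`,
late search `[5000, response]`. An event straddling the 5-s boundary
contributes its in-window portion to each window's duration metrics
(FFD/TFD/VD) but counts once, in the window containing its onset, for the
count metrics (FC/VC). This keeps durations and counts exactly conserved:
early + late = whole-trial, which the tests assert at 1e-9 s. An AOI never
fixated in a window gets FFD = missing (not 0), so averages run over
visited AOIs only.

## Response scoring

The four categories are the cross of stimulus truth and report. d-prime
uses the unequal-variance form `d_a = sqrt(2/(1+s²))·(z(H) − s·z(F))` with
configurable slope `s` (default 1, the classical d′): the variance ratio
used in the original clinical scoring is not recoverable, so it is surfaced
as a parameter rather than hard-coded. Extreme rates are corrected
log-linearly (0.5 per cell, 1 per denominator) — chosen over 1/(2N)
clamping; one convention had to be fixed, and the log-linear form keeps d′
finite and defined for every integer count. Partial sessions are scored on
available trials without imputation. Dichotomization into PDnP/PDP uses
only the original paper-based NPT pareidolia count (0–1 vs ≥2), never the
modified-test score.

## EEG conditioning

Fixed order: common average reference → 2–40 Hz band-pass → optional
artefact-removal hook → decimation to 500 Hz. The band-pass is a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`): the filter family and
order of the original analysis are unreported, and a zero-phase IIR is the
conservative choice because the presaccadic ramp must not be phase-shifted.
Decimation is plain subsampling, valid because the 40 Hz edge is far below
the 250 Hz post-decimation Nyquist. ICA-based artefact removal is out of
scope; the hook accepts any external cleaning function, and the pipeline's
artefact protection comes from the blink-exclusion rule and the ±80 µV
epoch rejection. EEG files are headered CSV matrices (sampling rate, start
time, channel labels, then one row per sample), which round-trip exactly
and need no binary container.

## Presaccadic analysis conventions

All epoch windows are half-open in samples; at 500 Hz the −200…+50 ms
epoch holds exactly 125 samples and the −20 ms edge sample is excluded
from the −100…−20 ms amplitude window, honouring the 20-ms spike-potential
guard. Boundary conventions, stated because the source rules leave ties
open: fixation-duration bounds are closed (`[200, 2000]` ms), saccade
duration strictly < 80 ms, and a saccade of exactly 4.0° is classified
*long*. The Mahalanobis matching features default to (saccade amplitude,
fixation duration); the percentile cut (95th, empirical) is applied per
subject, with a pooled variant available. The < 50-trial category exclusion
is applied per subject, so a group in which a category is rare (e.g.
pareidolias in healthy controls) drops out of that category's averages by
rule rather than by hard-coding. Artefact rejection is applied to the ten
analysed electrodes by default (configurable to all channels).

## Synthetic sessions: what they emulate

The generator produces, per subject: a stimulus set with one off-centre
target ellipse per face image plus 2–3 noise polygons placed in disjoint
cells of a 3 × 3 grid (overlap exactly zero by construction); Bernoulli
responses at group-dependent hit/pareidolia rates with log-normal response
times (defaults emulate the reported group medians: HC ≈ 1 pareidolia and
2 misses, PDnP ≈ 1 and 4, PDP ≈ 24 and 4, response medians 8.9–9.2 s);
alternating fixation/saccade gaze with normal fixation durations
(group-dependent mean 380–450 ms, SD 80 ms), a mixture of short
refixations (< 4°) and long AOI-targeted jumps, saccade durations scaled
with amplitude so every sweep clears the velocity threshold, and Poisson
blinks (0.1 /s) rendered as invalid-sample gaps; and EEG as 1/f-plus-white
noise (default SD 5 µV, exponent 1, half the power white) carrying a linear
presaccadic ramp before every saccade, a Gaussian spike potential
(σ = 4 ms) at onset, and 200-ms half-cosine blink artefacts (150 µV peak)
on the frontopolar channels. Event boundaries snap to the 120 Hz grid so
detection can be compared with ground truth. Dwell and gaze parameters are
simulation knobs chosen at plausible values, not estimates of the reported
group tables.

**Amplitude convention.** A configured effect amplitude is defined as the
*measured* presaccadic statistic — the baseline-corrected mean over
−100…−20 ms after standard conditioning — not the nominal ramp peak. The
generator divides the injected ramp height by (i) the exact discrete
sampling factor of the baseline/amplitude windows (125/180 at 500 Hz) and
(ii) the conditioning filter's unit response, measured once on an isolated
template. Effects are injected as spatially zero-mean patterns (+1 on the
five target-group electrodes, −5/27 on the remaining 27), the natural
space for average-referenced EEG, which makes re-referencing exactly
transparent to the effect. Consequences worth knowing: with filtering
disabled and zero noise the pipeline recovers configured amplitudes to
float precision (asserted); with the 2–40 Hz filter active, ringing from
neighbouring ramps adds a small positive bias (~3–5% of the amplitude in
the recovery experiments), and a frontal effect induces a −5/27-scaled
apparent amplitude on the parietal group (and vice versa) — the price of
exact spatial zero-mean.

**What passing tests do not show.** The generator has no saccade main
sequence beyond a linear duration–amplitude rule, no smooth pursuit, no
central-fixation bias, no volume-conduction head model, no heteroscedastic
between-subject effect variability, and its noise is stationary. Recovery
of embedded effects therefore demonstrates the correctness of the signal
chain, not robustness to every physiological artefact in real recordings.

## Statistical layer

The mixed ANOVA (between: group; within: eye-tracker variable) is computed
by `pingouin.mixed_anova`; least-square means equal unweighted cell means
in the balanced within design and are reported with pooled-error SEMs;
pairwise group contrasts within each variable level use Welch t-tests with
Holm–Šidák adjustment. The MANOVA path screens the (frontal, parietal)
correlation against the moderate band r = 0.3–0.6 — violations warn but do
not abort, since the band is an assumption check, not a validity
condition — removes multivariate outliers at the χ²(0.975) Mahalanobis
cut, tests Wilks' λ, and only on significance runs univariate two-way
ANOVAs; residuals failing a Lilliefors-corrected KS test are re-tested
with aligned-rank-transform ANOVA (plain rank-transform available).
Dunn's post-hoc z-tests use tie-corrected rank variance. Null-calibration
tests assert 5% ± 2% type-I error for all three omnibus tests on 500
simulated null datasets each.

**Sample-size computation.** "Minimum detectable mean level" is read as
the difference between the extreme group means with the remaining group at
the midpoint — the convention of standard sample-size software and the
least favourable configuration for a given range. With level 0.3, residual
SD 0.15, α = 0.05 and power 0.95, the smallest per-group n whose
noncentral-F power reaches the target is 9 (power 0.955; n = 8 gives
0.938), cross-checked by Monte-Carlo simulation. Alternative conventions
(equally spaced means; SD of means) are available as options because the
original computation's software and convention are unstated.

## Problem sizes used in tests

The default test suite runs on deliberately small sessions (2–4 subjects,
6–14 images) except where a property needs volume: the validity-filter
equivalence check uses 50 sessions of ≥1000 fixations; the effect-recovery
experiment uses 2 patient groups × 6 subjects × ~200 pareidolia epochs per
subject at noise SD 5 µV across 20 seeds (the ±0.2 µV acceptance band then
sits at more than 3 standard errors of the group-cell mean, chosen by this
power argument at design time); the Mahalanobis fraction check uses 10 000
bivariate-normal samples; the null calibrations use 500 datasets per test.

## Known limitations

- The validity filter assumes each fixation is followed by at most one
  relevant saccade and pairs each fixation with the first saccade starting
  at or after its end; co-occurring event streams with overlapping
  modalities are not resolved beyond that rule.
- `pixels_to_degrees` treats displacements as centred on the line of
  sight; eccentricity-dependent foreshortening is ignored (sub-percent
  error at NPT image eccentricities).
- The ART fallback covers the two-factor between-subjects layout used for
  the amplitude ANOVAs; it is not a general mixed-model rank procedure.
- EDF/BDF ingestion is not implemented; recordings enter as headered CSV
  matrices (or directly as in-memory arrays).
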