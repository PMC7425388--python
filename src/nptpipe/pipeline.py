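"""End-to-end orchestration: simulate -> validate -> metrics -> score -> frp -> stats.

All file I/O lives here. Streams are written in session-clock ms with a
per-trial stimulus-onset table in the trial metadata, so every stage can
convert between trial-relative and session-relative time explicitly. A run
manifest (JSON) records, per stage, the parameters used, the SHA-256 of
every output file and the exclusion counts, and a rerun with identical
config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eeg as eegmod
from . import frp as frpmod
from . import stats as statsmod
from .aoi import read_aoi_json, write_aoi_json
from .events import detect_events, read_gaze_tsv, write_gaze_tsv
from .frp import ElectrodeMontage, EpochConfig
from .geometry import ScreenGeometry
from .metrics import trial_metrics
from .scoring import TrialRecord, score_subject
from .simulate import SimConfig, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_run_config"]

TRIAL_COLUMNS = ("subject_id", "trial_index", "stimulus_id", "face_present",
                 "reported_face", "response_time_ms", "group", "stimulus_onset_ms")


@dataclass
class RunConfig:
    output_dir: str = "nptpipe_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    montage: ElectrodeMontage = field(default_factory=ElectrodeMontage)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    velocity_threshold_deg_s: float = 30.0
    min_fixation_ms: float = 60.0
    mahalanobis_scope: str = "per-subject"  # or "pooled"
    write_eeg: bool = True
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    sim_kwargs = raw.pop("sim", {}) or {}
    if "groups" in sim_kwargs:
        sim_kwargs["groups"] = tuple((g, int(n)) for g, n in sim_kwargs["groups"].items())
    if sim_kwargs:
        cfg.sim = dataclasses.replace(SimConfig(), **sim_kwargs)
    epoch_kwargs = raw.pop("epoch", {}) or {}
    if epoch_kwargs:
        cfg.epoch = dataclasses.replace(EpochConfig(), **{
            k: tuple(v) if isinstance(v, list) else v for k, v in epoch_kwargs.items()})
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(cfg, key, val)
    cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.entries: list[dict] = []

    def add(self, stage: str, params: dict, outputs: list[Path], extra: dict | None = None):
        self.entries.append(
            {
                "stage": stage,
                "params": params,
                "outputs": {p.name: _sha256(p) for p in outputs},
                **(extra or {}),
            }
        )
        self.write()

    def fail(self, stage: str, error: str):
        self.entries.append({"stage": stage, "failed": True, "error": error})
        self.write()

    def write(self):
        self.path.write_text(json.dumps(self.entries, indent=1, default=str))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    session = simulate_session(cfg.sim)
    write_aoi_json(session.stimulus_set, outdir / "aois.json")
    gaze_dir = outdir / "gaze"
    gaze_dir.mkdir(exist_ok=True)
    rows = []
    truth = {}
    outputs = [outdir / "aois.json"]
    for sub in session.subjects:
        for rec in sub.trials:
            rows.append({
                "subject_id": rec.subject_id, "trial_index": rec.trial_index,
                "stimulus_id": rec.stimulus_id, "face_present": int(rec.face_present),
                "reported_face": int(rec.reported_face),
                "response_time_ms": rec.response_time_ms, "group": rec.group,
                "stimulus_onset_ms": sub.trial_onsets_ms[rec.trial_index],
            })
        for tix, stream in sub.gaze.items():
            p = gaze_dir / f"{sub.subject_id}_trial{tix:03d}.tsv"
            write_gaze_tsv(stream, p)
        if sub.eeg is not None and cfg.write_eeg:
            p = outdir / f"eeg_{sub.subject_id}.csv"
            eegmod.write_eeg_csv(sub.eeg, p)
            outputs.append(p)
        truth[sub.subject_id] = {
            "group": sub.group,
            "n_fixations": int(sum(len(ev.fixations) for ev in sub.true_events.values())),
            "n_saccades": int(sum(len(ev.saccades) for ev in sub.true_events.values())),
            "n_blinks": int(sum(len(ev.blinks) for ev in sub.true_events.values())),
            "category_counts": dict(score_subject(sub.trials).counts),
        }
    trials = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    trials.to_csv(outdir / "trials.csv", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    outputs += [outdir / "trials.csv", outdir / "ground_truth.json"]
    manifest.add("simulate", {"seed": cfg.sim.seed, "n_images": cfg.sim.n_images,
                              "n_face_images": cfg.sim.n_face_images,
                              "groups": dict(cfg.sim.groups)}, outputs)


def validate_inputs(outdir: Path) -> dict:
    """Schema and time-alignment checks; findings go in the report."""
    findings: list[str] = []
    trials_path = outdir / "trials.csv"
    if not trials_path.exists():
        return {"ok": False, "findings": [f"missing {trials_path}"]}
    trials = pd.read_csv(trials_path)
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            findings.append(f"trials.csv missing column {col!r}")
    try:
        read_aoi_json(outdir / "aois.json")
    except Exception as exc:  # noqa: BLE001 - report, don't abort
        findings.append(f"aois.json: {exc}")

    eeg_spans = {}
    for p in sorted(outdir.glob("eeg_*.csv")):
        try:
            rec = eegmod.read_eeg_csv(p)
            eeg_spans[p.stem.replace("eeg_", "")] = (rec.start_ms,
                                                     rec.start_ms + rec.duration_ms)
        except Exception as exc:  # noqa: BLE001
            findings.append(f"{p.name}: {exc}")
    if not findings or all("missing column" not in f for f in findings):
        for row in trials.itertuples():
            p = outdir / "gaze" / f"{row.subject_id}_trial{row.trial_index:03d}.tsv"
            if p.exists():
                try:
                    g = read_gaze_tsv(p)
                    if np.any(np.diff(g["t_ms"].to_numpy()) < 0):
                        findings.append(f"{p.name}: timestamps decrease")
                except ValueError as exc:
                    findings.append(f"{p.name}: {exc}")
            span = eeg_spans.get(row.subject_id)
            if span is not None:
                t1 = row.stimulus_onset_ms + row.response_time_ms
                if not (span[0] <= row.stimulus_onset_ms and t1 <= span[1]):
                    findings.append(
                        f"EEG for {row.subject_id} does not cover trial "
                        f"{row.trial_index} ({row.stimulus_onset_ms:.0f}-{t1:.0f} ms)")
    return {"ok": not findings, "findings": findings}


def stage_metrics(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    trials = pd.read_csv(outdir / "trials.csv")
    stimulus_set = read_aoi_json(outdir / "aois.json")
    frames = []
    for row in trials.itertuples():
        p = outdir / "gaze" / f"{row.subject_id}_trial{row.trial_index:03d}.tsv"
        if not p.exists():
            continue
        stream = read_gaze_tsv(p)
        ev = detect_events(stream, cfg.velocity_threshold_deg_s, cfg.min_fixation_ms,
                           cfg.geometry)
        stim = stimulus_set.get(row.stimulus_id)
        df = trial_metrics(ev, stim.aois, float(row.response_time_ms))
        df.insert(0, "group", row.group)
        df.insert(0, "trial_index", row.trial_index)
        df.insert(0, "subject_id", row.subject_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(outdir / "metrics.csv", index=False)
    manifest.add("metrics", {"velocity_threshold_deg_s": cfg.velocity_threshold_deg_s,
                             "min_fixation_ms": cfg.min_fixation_ms},
                 [outdir / "metrics.csv"])


def stage_score(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    trials = pd.read_csv(outdir / "trials.csv")
    rows = []
    for sid, sub in trials.groupby("subject_id"):
        score = score_subject(sub)
        rows.append({"subject_id": sid, "group": score.group, **score.counts,
                     "hit_rate": score.hit_rate, "fa_rate": score.fa_rate,
                     "d_prime": score.d_prime})
    pd.DataFrame(rows).to_csv(outdir / "scores.csv", index=False)
    manifest.add("score", {}, [outdir / "scores.csv"])


def stage_frp(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    trials = pd.read_csv(outdir / "trials.csv")
    tables = []
    exclusions = {}
    rng = np.random.default_rng(cfg.seed + 1)
    for sid, sub in trials.groupby("subject_id"):
        eeg_path = outdir / f"eeg_{sid}.csv"
        if not eeg_path.exists():
            continue
        raw = eegmod.read_eeg_csv(eeg_path)
        rec = eegmod.preprocess(raw)
        records = [
            TrialRecord(str(r.subject_id), int(r.trial_index), str(r.stimulus_id),
                        bool(r.face_present), bool(r.reported_face),
                        float(r.response_time_ms), str(r.group))
            for r in sub.itertuples()
        ]
        onsets = {int(r.trial_index): float(r.stimulus_onset_ms) for r in sub.itertuples()}
        events = {}
        for r in sub.itertuples():
            p = outdir / "gaze" / f"{sid}_trial{r.trial_index:03d}.tsv"
            if p.exists():
                events[int(r.trial_index)] = detect_events(
                    read_gaze_tsv(p), cfg.velocity_threshold_deg_s,
                    cfg.min_fixation_ms, cfg.geometry)
        valid = frpmod.select_valid_fixations(events, records, cfg.epoch, onsets)
        n_valid = len(valid)
        try:
            # the loop is per subject, so the per-subject scope is implicit;
            # the pooled scope is available through frp.mahalanobis_match on
            # the concatenated table
            valid = frpmod.mahalanobis_match(
                valid, percentile=cfg.epoch.mahalanobis_percentile)
        except ValueError:
            logger.warning("Mahalanobis matching skipped for %s (degenerate features)", sid)
        epochs = frpmod.extract_epochs(rec, valid, cfg.epoch, cfg.montage)
        surv = frpmod.reject_artifacts(epochs, cfg.epoch.rejection_uv)
        by_cat: dict[str, list] = {}
        for e in surv:
            by_cat.setdefault(e.category, []).append(e)
        matched = frpmod.match_trial_counts(by_cat, cfg.epoch.min_trials, rng)
        corrected = [frpmod.baseline_correct(e, cfg.epoch.baseline_window_ms)
                     for eps in matched.values() for e in eps]
        exclusions[sid] = {
            "valid_fixations": n_valid, "after_matching": len(valid),
            "epochs": len(epochs), "after_rejection": len(surv),
            "categories_kept": sorted(matched),
        }
        if corrected:
            tables.append(frpmod.amplitude_table(corrected, cfg.montage, cfg.epoch))
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    table.to_csv(outdir / "amplitudes.csv", index=False)
    (outdir / "frp_exclusions.json").write_text(json.dumps(exclusions, indent=1))
    manifest.add("frp", {"min_trials": cfg.epoch.min_trials,
                         "rejection_uv": cfg.epoch.rejection_uv},
                 [outdir / "amplitudes.csv", outdir / "frp_exclusions.json"],
                 {"exclusions": exclusions})


def stage_stats(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    results: dict = {}
    metrics = pd.read_csv(outdir / "metrics.csv")
    # duration metrics, early window, per response category: mixed ANOVA
    trials = pd.read_csv(outdir / "trials.csv")
    cat_map = {}
    for r in trials.itertuples():
        face = "Face" if r.reported_face else "Missed"
        noise = "Pareidolia" if r.reported_face else "Noise"
        cat_map[(r.subject_id, r.trial_index)] = face if r.face_present else noise
    metrics["category"] = [cat_map.get((r.subject_id, r.trial_index))
                           for r in metrics.itertuples()]
    early = metrics[metrics["window"] == "early"]
    long_rows = []
    for r in early.itertuples():
        for var, col in (("TFD", "tfd_s"), ("VD", "vd_s"), ("FFD", "ffd_ms")):
            val = getattr(r, col)
            if pd.notna(val):
                long_rows.append({"subject_id": r.subject_id, "group": r.group,
                                  "category": r.category, "variable": var, "value": val})
    dur = pd.DataFrame(long_rows)
    results["rm_anova_early_durations"] = {}
    for cat, sub in dur.groupby("category"):
        cell = (sub.groupby(["subject_id", "group", "variable"])["value"]
                .mean().reset_index())
        if cell.groupby("variable")["subject_id"].nunique().min() < 3:
            continue
        if cell["group"].nunique() < 2:
            continue
        try:
            res = statsmod.rm_anova(cell)
        except ValueError:
            continue
        results["rm_anova_early_durations"][cat] = res.effects.to_dict("records")

    amp_path = outdir / "amplitudes.csv"
    if amp_path.exists():
        amp = pd.read_csv(amp_path)
        if not amp.empty:
            groups = trials.drop_duplicates("subject_id").set_index("subject_id")["group"]
            amp["group"] = amp["subject_id"].map(groups)
            wide = amp.pivot_table(index=["subject_id", "group", "category", "size_class"],
                                   columns="electrode_group",
                                   values="amplitude_uv").reset_index()
            results["manova"] = {}
            for cat, sub in wide.groupby("category"):
                if len(sub) < 6 or sub["group"].nunique() < 2 \
                        or {"frontal", "parietal"} - set(sub.columns):
                    continue
                try:
                    mres = statsmod.manova_then_univariate(sub)
                except Exception as exc:  # noqa: BLE001
                    results["manova"][cat] = {"error": str(exc)}
                    continue
                results["manova"][cat] = {
                    "wilks_lambda": mres.wilks_lambda, "F": mres.F,
                    "df": [mres.df1, mres.df2], "p": mres.p,
                    "univariate": {dv: tab.to_dict("records")
                                   for dv, tab in mres.univariate.items()},
                }

    (outdir / "stats.json").write_text(json.dumps(results, indent=1, default=float))
    report = _plain_report(results)
    (outdir / "report.txt").write_text(report)
    manifest.add("stats", {}, [outdir / "stats.json", outdir / "report.txt"])


def _plain_report(results: dict) -> str:
    lines = ["nptpipe statistical report", "=" * 30, ""]
    for cat, effs in results.get("rm_anova_early_durations", {}).items():
        lines.append(f"Early-search duration metrics - {cat}")
        for e in effs:
            lines.append(f"  {e['Source']:<12} F({e['df1']:.0f},{e['df2']:.0f}) = "
                         f"{e['F']:.2f}, p = {e['p']:.4f}")
        lines.append("")
    for cat, m in results.get("manova", {}).items():
        if "error" in m:
            lines.append(f"Presaccadic amplitudes - {cat}: {m['error']}")
            continue
        lines.append(f"Presaccadic amplitudes - {cat}: Wilks' lambda = "
                     f"{m['wilks_lambda']:.2f}, F({m['df'][0]:.0f},{m['df'][1]:.0f}) = "
                     f"{m['F']:.2f}, p = {m['p']:.4f}")
    return "\n".join(lines) + "\n"


STAGES = {
    "simulate": stage_simulate,
    "metrics": stage_metrics,
    "score": stage_score,
    "frp": stage_frp,
    "stats": stage_stats,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in fixed order; return the manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest = _Manifest(outdir)
    order = [s for s in STAGES if stages is None or s in stages]
    if stages is not None and "validate" in stages:
        report = validate_inputs(outdir)
        (outdir / "validation.json").write_text(json.dumps(report, indent=1))
    for name in order:
        try:
            STAGES[name](cfg, outdir, manifest)
        except Exception as exc:
            manifest.fail(name, repr(exc))
            raise
    return {"entries": manifest.entries, "output_dir": str(outdir)}
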