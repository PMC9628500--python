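"""Configuration-driven end-to-end orchestration.

Stages: synthesize sessions -> extract epochs -> EEG spectral indices +
SNR quality + EDA decomposition -> tidy trial-measure table -> per-measure
hierarchical fits with planned contrasts -> report tables, group
directional tests, diagnostics JSON and a run log.  Every number in a
report table comes from a row of an intermediate CSV; fixed seeds make
whole runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, eda, quality, spectral, synth
from .design import DesignSpec
from .io import Session, extract_epochs, write_session

logger = logging.getLogger(__name__)

#: measures modelled with the full hierarchical contrasts machinery
CONTRAST_MEASURES = ("arousal", "valence", "FA", "FMT", "TBR", "FAA",
                     "SCL", "ISCR")
#: per-participant scalars tested for a walking-group effect
GROUP_MEASURES = ("SNR", "SCL", "ISCR", "nSCR", "presence")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults."""

    seed: int = 0
    out_dir: str = "mobiphys_out"
    n_per_group: int = 20
    write_sessions: bool = False

    # design
    video_duration_s: float = 64.0
    fade_s: float = 2.0
    isi_duration_s: float = 60.0

    # generators
    eeg_rate_hz: float = 500.0
    eeg_background_uv: float = 8.0
    eda_rate_hz: float = 128.0

    # spectral
    psd_window_s: float = 1.0
    psd_overlap_s: float = 0.25
    psd_resolution_hz: float = 0.5

    # cleaning
    bandpass_low_hz: float = 1.0
    bandpass_high_hz: float = 40.0
    line_freq_hz: float = 50.0
    artifact_z_thresh: float = 4.0

    # CDA
    cda_tau_init: tuple[float, float] = (3.75, 1.0)
    cda_optimize_tau: bool = True
    nscr_threshold_us: float = 0.05

    # model / sampler
    chains: int = 2
    iterations: int = 1000
    warmup: int = 500
    likelihood: str = "student"

    measures: tuple[str, ...] = CONTRAST_MEASURES

    def design(self) -> DesignSpec:
        return DesignSpec(video_duration_s=self.video_duration_s,
                          fade_s=self.fade_s,
                          isi_duration_s=self.isi_duration_s)

    def model_spec(self) -> bayes.ModelSpec:
        return bayes.ModelSpec(chains=self.chains, iterations=self.iterations,
                               warmup=self.warmup, likelihood=self.likelihood)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cda_tau_init" in raw:
            raw["cda_tau_init"] = tuple(raw["cda_tau_init"])
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["cda_tau_init"] = list(self.cda_tau_init)
        d["measures"] = list(self.measures)
        return yaml.safe_dump(d, sort_keys=False)


def validate_config(config: PipelineConfig) -> list[str]:
    """Report (not raise) out-of-range values and cross-field violations."""
    issues: list[str] = []
    if config.n_per_group < 2:
        issues.append("n_per_group must be at least 2")
    if config.video_duration_s <= 0:
        issues.append("video_duration_s must be positive")
    if config.isi_duration_s <= 0:
        issues.append("isi_duration_s must be positive")
    if config.fade_s < 0 or 2 * config.fade_s >= config.video_duration_s:
        issues.append("fade_s must be nonnegative and shorter than the video")
    nyq = config.eeg_rate_hz / 2
    if config.bandpass_high_hz >= nyq:
        issues.append(f"bandpass_high_hz {config.bandpass_high_hz} is not "
                      f"below Nyquist {nyq}")
    for band, (lo, hi) in spectral.BANDS.items():
        if hi > nyq:
            issues.append(f"{band} band upper edge {hi} Hz above Nyquist {nyq}")
    if config.eda_rate_hz < 16:
        issues.append("eda_rate_hz must be at least 16")
    if not 0 < config.warmup < config.iterations:
        issues.append("warmup must lie strictly between 0 and iterations")
    if config.likelihood not in ("student", "normal"):
        issues.append(f"unknown likelihood {config.likelihood!r}")
    t1, t2 = config.cda_tau_init
    if t1 <= 0 or t2 <= 0 or t1 == t2:
        issues.append("cda_tau_init taus must be positive and distinct")
    unknown = set(config.measures) - set(CONTRAST_MEASURES)
    if unknown:
        issues.append(f"unknown measures: {sorted(unknown)}")
    return issues


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage


def _log_stage(stage: str, t0: float, **counts) -> None:
    info = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.1fs %s", stage, time.time() - t0, info)


def synthesize_cohort(config: PipelineConfig) -> list[tuple[Session, synth.GroundTruth]]:
    """Generate the full cohort; alternating counterbalance order per group."""
    eeg_p = synth.EEGGenParams(rate=config.eeg_rate_hz,
                               background_scale_uv=config.eeg_background_uv)
    eda_p = synth.EDAGenParams(rate=config.eda_rate_hz)
    sam_p = synth.SAMGenParams()
    ss = np.random.SeedSequence(config.seed)
    out = []
    pid = 0
    for group in ("standing", "walking"):
        for i in range(config.n_per_group):
            pid += 1
            order = "forward" if i % 2 == 0 else "reverse"
            design = DesignSpec(video_duration_s=config.video_duration_s,
                                fade_s=config.fade_s,
                                isi_duration_s=config.isi_duration_s,
                                order=order)
            seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
            out.append(synth.generate_session(
                design, group, eeg_p, eda_p, sam_p, seed=seed,
                participant=f"P{pid:03d}"))
    return out


def session_measures(session: Session, config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Trial-measure rows and per-participant scalars for one session."""
    design = DesignSpec(video_duration_s=config.video_duration_s,
                        fade_s=config.fade_s,
                        isi_duration_s=config.isi_duration_s,
                        order=session.meta.get("schedule", "forward"))
    epochs = extract_epochs(session, design)
    meta = session.meta
    base = dict(participant=str(meta.get("participant")),
                group=str(meta.get("group")),
                schedule=str(meta.get("schedule")))

    rows = []
    # SAM ratings (raw 1-9 per trial)
    for r in session.sam.itertuples():
        for measure, val in (("arousal", r.arousal), ("valence", r.valence)):
            rows.append({**base, "condition": r.condition,
                         "occurrence": r.occurrence, "trial": r.trial,
                         "measure": measure, "value": float(val)})

    # EEG indices (already ISI-normalized by the percent-baseline correction)
    indices = spectral.eeg_indices(session, design, epochs,
                                   window_s=config.psd_window_s,
                                   overlap_s=config.psd_overlap_s,
                                   resolution_hz=config.psd_resolution_hz)
    for r in indices.itertuples():
        for measure in ("FA", "FMT", "TBR", "FAA"):
            rows.append({**base, "condition": r.condition,
                         "occurrence": r.occurrence, "trial": r.trial,
                         "measure": measure, "value": getattr(r, measure)})

    # EDA measures (video minus ISI per trial)
    comps = eda.analyze_eda(session.require("eda"),
                            optimize=config.cda_optimize_tau,
                            tau_init=config.cda_tau_init,
                            amp_threshold_us=config.nscr_threshold_us)
    emeas = eda.eda_trial_measures(comps, epochs.videos() + epochs.isis(),
                                   amp_threshold_us=config.nscr_threshold_us)
    diffs = emeas[emeas.role == "video_minus_isi"]
    for r in diffs.itertuples():
        for measure in ("SCL", "ISCR"):
            rows.append({**base, "condition": r.condition,
                         "occurrence": r.occurrence, "trial": r.trial,
                         "measure": measure, "value": getattr(r, measure)})

    # participant-level scalars for the group tests: SNR uses the mean
    # baseline-minus-ISI difference; the EDA scalars use raw video-window
    # levels (a constant walking offset cancels in video-minus-ISI diffs)
    snr = quality.session_snr(session, epochs,
                              low=config.bandpass_low_hz,
                              high=config.bandpass_high_hz,
                              line_freq=config.line_freq_hz,
                              z_thresh=config.artifact_z_thresh)
    vids = emeas[emeas.role == "video"]
    scalars = {
        **base,
        "SNR": float(snr["snr_diff_db"].mean()),
        "SCL": float(vids["SCL"].mean()),
        "ISCR": float(vids["ISCR"].mean()),
        "nSCR": float(vids["nSCR"].mean()),
        "presence": float(meta.get("presence_score", np.nan)),
    }
    return pd.DataFrame(rows), scalars


def run_pipeline(config: PipelineConfig) -> dict:
    """Run synth -> measures -> stats -> report; return output paths."""
    issues = validate_config(config)
    if issues:
        raise StageError("config", ValueError("; ".join(issues)))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    try:
        cohort = synthesize_cohort(config)
    except Exception as exc:
        raise StageError("synth", exc) from exc
    _log_stage("synth", t0, sessions=len(cohort))

    t0 = time.time()
    trial_frames, scalar_rows = [], []
    try:
        for session, _gt in cohort:
            tf, scalars = session_measures(session, config)
            trial_frames.append(tf)
            scalar_rows.append(scalars)
            if config.write_sessions:
                write_session(session, out_dir / "sessions"
                              / str(session.meta["participant"]))
    except Exception as exc:
        raise StageError("measures", exc) from exc
    trial_table = pd.concat(trial_frames, ignore_index=True)
    scalar_table = pd.DataFrame(scalar_rows)
    trial_path = out_dir / "trial_measures.csv"
    trial_table.to_csv(trial_path, index=False)
    scalar_table.to_csv(out_dir / "participant_scalars.csv", index=False)
    _log_stage("measures", t0, rows=len(trial_table))

    t0 = time.time()
    outputs = {"trial_measures": str(trial_path)}
    diagnostics: dict = {}
    spec = config.model_spec()
    try:
        stat_seed = np.random.SeedSequence([config.seed, 7])
        for measure, sub in zip(
                config.measures,
                (trial_table[trial_table.measure == m] for m in config.measures)):
            sub = sub.rename(columns={"value": "value"})
            seed = int(stat_seed.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
            post = bayes.fit_hierarchical(sub, spec, seed=seed)
            results = bayes.planned_contrasts(post)
            df = bayes.render_table(results)
            path = out_dir / f"contrasts_{measure}.csv"
            df.to_csv(path, index=False)
            (out_dir / f"contrasts_{measure}.md").write_text(
                bayes.render_table(results, markdown=True))
            outputs[f"contrasts_{measure}"] = str(path)
            diagnostics[measure] = post.diagnostics
        # Table-1-style group tests
        group_rows = []
        for m in GROUP_MEASURES:
            seed = int(stat_seed.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
            gp = bayes.fit_group_model(scalar_table[m].to_numpy(),
                                       scalar_table["group"].to_numpy(),
                                       spec, seed=seed)
            res = gp.directional_test(">")
            group_rows.append({
                "Measure": m, "Hypothesis": "(GroupWalking) > 0",
                "Estimate": round(res["estimate"], 3),
                "Est.Error": round(res["est_error"], 3),
                "95% CI": f"[{res['ci_low']:.3f}, {res['ci_high']:.3f}]",
                "Evid.Ratio": ("Inf" if math.isinf(res["evidence_ratio"])
                               else round(res["evidence_ratio"], 2)),
                "Post.Prob": round(res["post_prob"], 2),
                "Star": "*" if res["star"] else "",
            })
        group_df = pd.DataFrame(group_rows)
        group_path = out_dir / "group_tests.csv"
        group_df.to_csv(group_path, index=False)
        outputs["group_tests"] = str(group_path)
    except Exception as exc:
        raise StageError("stats", exc) from exc
    _log_stage("stats", t0, measures=len(config.measures))

    (out_dir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=1))
    run_log = {"seed": config.seed, "n_per_group": config.n_per_group,
               "config": yaml.safe_load(config.to_yaml())}
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    outputs["diagnostics"] = str(out_dir / "diagnostics.json")
    return outputs
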