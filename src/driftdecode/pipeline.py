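"""End-to-end orchestration: simulate -> preprocess -> localize -> GLM ->
decode -> eye analyses, with a JSON/TSV report bundle.

A :class:`PipelineConfig` plus its seed determines every output bit; all
stage seeds are derived deterministically from the config seed.  Reports
are plain JSON/TSV tables mirroring the per-ROI decoding panels and the
eye-movement control analyses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import ConditionLabel, StimulusSpec, ILLUSION_CONDITIONS
from .preprocess import (
    VoxelTimeSeries,
    average_localizer_runs,
    highpass_filter,
    to_percent_signal,
)
from .localizer import cosine_fit, select_voxels, VoxelSelection
from .glm import (
    deconvolve_fir,
    estimate_roi_hrf,
    estimate_betas_session,
    BetaMatrix,
)
from .decode import (
    illusion_decoding,
    illusion_permutation_null,
    loro_cv,
    path_decoding,
    permutation_null,
    DecodingResult,
)
from .synthdata import (
    EffectConfig,
    NoiseConfig,
    OculomotorConfig,
    RoiConfig,
    Session,
    default_rois,
    simulate_session,
    target_trajectory,
)
from .eyetrack import (
    detect_saccades,
    eye_svm_decode,
    repair_and_center,
    saccade_stats,
    segment_traversals,
    SAMPLE_HZ,
)

__all__ = ["PipelineConfig", "run_experiment", "analyze_session", "preprocess_run"]

log = logging.getLogger("driftdecode")


@dataclass
class PipelineConfig:
    """Fully serializable description of one simulated experiment run."""

    expt_id: int = 2
    n_runs: int = 8
    seed: int = 0
    rois: list = field(default_factory=default_rois)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    oculomotor: OculomotorConfig = field(default_factory=OculomotorConfig)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    r_threshold: float = 0.2
    phase_window: float = float(np.pi / 2)
    r2_percentile: float = 50.0
    n_perm: int = 1000
    with_eye: bool | None = None

    def to_yaml(self, path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        payload = {
            "expt_id": self.expt_id,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "rois": [plain(r) for r in self.rois],
            "effects": plain(self.effects),
            "noise": plain(self.noise),
            "oculomotor": plain(self.oculomotor),
            "stimulus": plain(self.stimulus),
            "r_threshold": self.r_threshold,
            "phase_window": self.phase_window,
            "r2_percentile": self.r2_percentile,
            "n_perm": self.n_perm,
            "with_eye": self.with_eye,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        kwargs = dict(d)
        if "rois" in d:
            kwargs["rois"] = [RoiConfig(**r) for r in d["rois"]]
        if "effects" in d:
            kwargs["effects"] = EffectConfig(**d["effects"])
        if "noise" in d:
            kwargs["noise"] = NoiseConfig(**d["noise"])
        if "oculomotor" in d:
            oc = dict(d["oculomotor"])
            if "microsaccade_amp_range" in oc:
                oc["microsaccade_amp_range"] = tuple(oc["microsaccade_amp_range"])
            kwargs["oculomotor"] = OculomotorConfig(**oc)
        if "stimulus" in d:
            kwargs["stimulus"] = StimulusSpec(**d["stimulus"])
        return cls(**kwargs)


def preprocess_run(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Raw -> percent signal -> 0.01 Hz high-pass."""
    return highpass_filter(to_percent_signal(ts))


def _result_payload(res) -> dict:
    if isinstance(res, DecodingResult):
        return {
            "accuracy": res.accuracy,
            "threshold_95": res.threshold_95,
            "p_value": res.p_value,
            "significant": bool(res.significant),
            "n_exemplars": res.n_exemplars,
        }
    return {"accuracy": float(res)}


def analyze_session(
    session: Session,
    r_threshold: float = 0.2,
    phase_window: float | None = float(np.pi / 2),
    r2_percentile: float = 50.0,
    n_perm: int = 0,
    seed: int = 0,
    spec: StimulusSpec | None = None,
) -> dict:
    """Run the full analysis on one (simulated or loaded) session.

    With ``n_perm`` = 0 only cross-validated accuracies are computed;
    with ``n_perm`` > 0 each decoding analysis additionally gets a
    permutation null, 95th-percentile threshold, and one-tailed p-value.

    Returns a nested report dict: per-ROI illusion/path decoding (plus the
    pursuit-voxel control), the estimated per-ROI HRFs, localizer voxel
    counts, and (for sessions with eye traces) the three eye decoding
    analyses and microsaccade statistics.
    """
    spec = spec or StimulusSpec()
    log.info("preprocessing %d task runs", len(session.task_runs))
    task = [preprocess_run(ts) for ts in session.task_runs]
    schedules = session.task_schedules

    stim_loc = [preprocess_run(ts) for ts in session.stim_localizer_runs]
    eye_loc = [preprocess_run(ts) for ts in session.eye_localizer_runs]
    stim_avg = average_localizer_runs(stim_loc)
    eye_avg = average_localizer_runs(eye_loc)
    stim_map = cosine_fit(stim_avg)
    eye_map = cosine_fit(eye_avg)
    stim_sel = select_voxels(
        stim_map, r_threshold, phase_window, source="stimulus_localizer"
    )
    pursuit_sel = select_voxels(
        eye_map,
        r_threshold,
        phase_window,
        exclude=stim_sel,
        source="pursuit_localizer_excl_stimulus",
    )
    log.info(
        "localizers selected %d stimulus voxels, %d pursuit-only voxels",
        len(stim_sel),
        len(pursuit_sel),
    )

    roi_labels = task[0].roi_labels
    expt = session.expt_id
    report: dict = {
        "expt_id": expt,
        "version": __version__,
        "seed": seed,
        "n_runs": len(task),
        "localizer": {
            "n_stimulus_voxels": int(len(stim_sel)),
            "n_pursuit_only_voxels": int(len(pursuit_sel)),
        },
        "rois": {},
    }
    rng = np.random.default_rng(seed)

    for roi in sorted(set(roi_labels)):
        roi_idx = np.flatnonzero(roi_labels == roi)
        roi_means = [ts.data[roi_idx].mean(axis=0) for ts in task]
        hrfs = deconvolve_fir(roi_means, schedules)
        hrf = estimate_roi_hrf(hrfs)
        roi_runs = [
            dataclasses.replace(ts, data=ts.data[roi_idx], roi_labels=ts.roi_labels[roi_idx])
            for ts in task
        ]
        betas = estimate_betas_session(roi_runs, schedules, hrf)
        # selections are in session-wide voxel indices; map to ROI-local
        stim_vox = np.flatnonzero(np.isin(roi_idx, stim_sel.indices))
        pursuit_vox = np.flatnonzero(np.isin(roi_idx, pursuit_sel.indices))
        roi_report: dict = {
            "hrf": hrf.values.tolist(),
            "n_stimulus_voxels": int(stim_vox.size),
            "n_pursuit_only_voxels": int(pursuit_vox.size),
        }

        def run_decode(kind, vox, _betas=betas):
            if vox.size < 4:
                return None
            sub = _betas.subset_voxels(vox)
            s = int(rng.integers(2**31))
            if kind == "illusion":
                if n_perm:
                    return illusion_permutation_null(
                        sub, n_perm=n_perm, seed=s, percentile=r2_percentile
                    )
                return illusion_decoding(sub, percentile=r2_percentile)
            if kind == "path":
                if n_perm:
                    return permutation_null(
                        sub,
                        (ConditionLabel.LEFT_ILLUSION, ConditionLabel.RIGHT_ILLUSION),
                        n_perm=n_perm,
                        seed=s,
                        percentile=r2_percentile,
                    )
                return path_decoding(sub, percentile=r2_percentile)
            if kind == "local":
                pair = (ConditionLabel.LOCAL_LR, ConditionLabel.LOCAL_RL)
                if n_perm:
                    return permutation_null(
                        sub, pair, n_perm=n_perm, seed=s, percentile=r2_percentile
                    )
                return loro_cv(sub, pair, percentile=r2_percentile)
            raise ValueError(kind)

        if expt in (1, 2):
            res = run_decode("illusion", stim_vox)
            if res is not None:
                roi_report["illusion"] = _result_payload(res)
        res = run_decode("path", stim_vox)
        if res is not None:
            roi_report["path"] = _result_payload(res)
        res = run_decode("path", pursuit_vox)
        if res is not None:
            roi_report["path_pursuit_voxels"] = _result_payload(res)
        if expt in (3, 4):
            res = run_decode("local", stim_vox)
            if res is not None:
                roi_report["local_motion"] = _result_payload(res)
        report["rois"][str(roi)] = roi_report
        log.info("ROI %s analyzed (%d stimulus voxels)", roi, stim_vox.size)

    if session.eye_traces:
        report["eye"] = _analyze_eye(
            session, spec, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    return report


def _analyze_eye(session: Session, spec: StimulusSpec, n_perm: int, seed: int) -> dict:
    import pandas as pd

    traces = [repair_and_center(tr) for tr in session.eye_traces]
    out: dict = {}
    for segment in ("illusion", "fixation", "local_motion"):
        exemplars = []
        for tr, sch in zip(traces, session.task_schedules):
            exemplars.extend(segment_traversals(tr, sch, spec, segment=segment))
        if n_perm:
            res = eye_svm_decode(exemplars, n_perm=n_perm, seed=seed)
            out[segment] = _result_payload(res)
        else:
            from .eyetrack import _svm_loro

            feats = np.stack([e.features for e in exemplars])
            labels = np.array([e.label for e in exemplars], dtype=object)
            runs = np.array([e.run_id for e in exemplars])
            out[segment] = {"accuracy": _svm_loro(feats, labels, runs)}
        out[segment]["n_exemplars"] = len(exemplars)

    rows = []
    for tr, sch in zip(traces, session.task_schedules):
        target = target_trajectory(sch, spec)
        events = detect_saccades(tr, target=target)
        t_block = [
            (b.onset_s * 1000.0, (b.onset_s + b.duration_s) * 1000.0, b.condition)
            for b in sch.stimulus_blocks()
        ]
        for ev in events:
            for t0, t1, cond in t_block:
                if t0 <= ev.onset_ms < t1:
                    rows.append(
                        {
                            "subject": tr.run_id,
                            "condition": cond,
                            "amplitude": ev.amplitude,
                            "direction": ev.direction,
                        }
                    )
                    break
    if rows:
        stats = saccade_stats(pd.DataFrame(rows))
        anova = stats["anova"]
        out["saccades"] = {
            "n_events": len(rows),
            "anova": None
            if anova is None
            else {
                "F_illusion": float(anova.loc["C(illusion)", "F"]),
                "p_illusion": float(anova.loc["C(illusion)", "PR(>F)"]),
                "F_direction": float(anova.loc["C(dir_class)", "F"]),
                "p_direction": float(anova.loc["C(dir_class)", "PR(>F)"]),
                "F_interaction": float(anova.loc["C(illusion):C(dir_class)", "F"]),
                "p_interaction": float(anova.loc["C(illusion):C(dir_class)", "PR(>F)"]),
            },
        }
    return out


def run_experiment(config: PipelineConfig, out_dir=None) -> dict:
    """Simulate a session per the config and run the full analysis.

    Writes ``report.json``, the config as YAML, and per-run schedule TSVs
    into ``out_dir`` when given.  Deterministic: rerunning with the same
    config yields a byte-identical report.
    """
    log.info("run_experiment: expt %s, %d runs, seed %d",
             config.expt_id, config.n_runs, config.seed)
    try:
        session = simulate_session(
            config.expt_id,
            config.n_runs,
            seed=config.seed,
            rois=config.rois,
            effects=config.effects,
            noise=config.noise,
            ocfg=config.oculomotor,
            spec=config.stimulus,
            with_eye=config.with_eye,
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[simulate] {exc}") from exc
    try:
        report = analyze_session(
            session,
            r_threshold=config.r_threshold,
            phase_window=config.phase_window,
            r2_percentile=config.r2_percentile,
            n_perm=config.n_perm,
            seed=config.seed,
            spec=config.stimulus,
        )
    except Exception as exc:
        raise RuntimeError(f"[analyze] {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        for i, sch in enumerate(session.task_schedules):
            sch.to_tsv(out / f"run{i:02d}_schedule.tsv")
            sch.write_manifest(out / f"run{i:02d}_manifest.json")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("report written to %s", out / "report.json")
    return report
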