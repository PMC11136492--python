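"""Synthetic BOLD sessions and eye traces with known ground truth.

The generator stands in for the scanner: it produces block-design voxel
time series in four regions of interest (EVC, LO, V3A/B, hMT+) with the
statistical structure the analysis assumes, and 1000 Hz pursuit eye traces
with blinks, catch-up saccades and microsaccades.  Every effect the
pipeline is meant to detect is injected explicitly:

* ``illusion_gain`` — a per-ROI amplitude increase of illusion blocks
  over the control condition (a univariate effect, zeroed in EVC when the
  subject attends fixation rather than the stimulus);
* ``path_pattern_sd`` — a fixed per-voxel zero-mean signed map added to
  leftward blocks and subtracted from rightward blocks (a multivoxel
  pattern effect, the substrate of drift-path decoding), standing in for
  the perceived-eccentricity shift of the two drift paths without
  modeling retinotopy explicitly;
* ``condition_bias`` — a horizontal eye-position offset per illusion
  condition (zero under the null, reproducing the absence of oculomotor
  condition information).

Under the all-zero effect configuration the conditions are statistically
exchangeable, so downstream decoding is calibrated at chance.  The
generating block response (a canonical difference-of-gammas shape
convolved with the 12 s block) and all injected amplitudes are returned
alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import (
    ConditionLabel,
    ILLUSION_CONDITIONS,
    PURSUIT_CONDITIONS,
    STIMULUS_CONDITIONS,
    RunSchedule,
    StimulusSpec,
    build_run_schedule,
    envelope_elevation,
)
from .eyetrack import EyeTrace, SAMPLE_HZ
from .glm import HRF, canonical_block_hrf
from .preprocess import VoxelTimeSeries

__all__ = [
    "RoiConfig",
    "EffectConfig",
    "NoiseConfig",
    "OculomotorConfig",
    "VoxelPopulation",
    "Session",
    "default_rois",
    "make_voxel_population",
    "simulate_bold_run",
    "simulate_session",
    "simulate_eye_run",
]

ROI_NAMES = ("EVC", "LO", "V3AB", "hMT")

N_STIM_LOCALIZER_RUNS = 3
N_EYE_LOCALIZER_RUNS = 2


@dataclass(frozen=True)
class RoiConfig:
    """Size and responsiveness of one simulated ROI.

    ``localizer_responsive_fraction`` of the voxels respond to the visual
    stimulus (and are the carriers of all condition effects);
    ``pursuit_responsive_fraction`` respond during pursuit eye movements
    (a diffuse population that may overlap the stimulus-responsive one).
    ``response_amplitude`` is the evoked block response of a responsive
    voxel in percent signal.
    """

    name: str
    n_voxels: int = 40
    baseline: float = 1000.0
    localizer_responsive_fraction: float = 0.5
    pursuit_responsive_fraction: float = 0.5
    response_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_voxels < 20:
            raise ValueError("each ROI needs at least 20 voxels")
        if not 0 <= self.localizer_responsive_fraction <= 1:
            raise ValueError("localizer_responsive_fraction must be in [0, 1]")
        if self.name not in ROI_NAMES:
            raise ValueError(f"ROI name must be one of {ROI_NAMES}")


def default_rois() -> list[RoiConfig]:
    """The four combined ROIs at simulation scale (EVC is the largest)."""
    return [
        RoiConfig("EVC", n_voxels=80),
        RoiConfig("LO", n_voxels=50),
        RoiConfig("V3AB", n_voxels=50),
        RoiConfig("hMT", n_voxels=40),
    ]


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth condition effects, percent signal.

    ``illusion_gain[roi]`` is the amplitude difference between illusion
    and control blocks; ``path_pattern_sd[roi]`` the SD of the per-voxel
    signed left/right pattern map.  ``attend_fixation`` zeroes the EVC
    illusion gain, emulating the removal of stimulus-directed attention.
    The default is the global null (all zeros).
    """

    illusion_gain: dict = field(default_factory=dict)
    path_pattern_sd: dict = field(default_factory=dict)
    attend_fixation: bool = False

    def __post_init__(self) -> None:
        for d in (self.illusion_gain, self.path_pattern_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"effect for {k} must be >= 0")

    def gain(self, roi: str) -> float:
        g = self.illusion_gain.get(roi, 0.0)
        if self.attend_fixation and roi == "EVC":
            return 0.0
        return g

    def pattern_sd(self, roi: str) -> float:
        return self.path_pattern_sd.get(roi, 0.0)

    @classmethod
    def study_effects(cls, attend_fixation: bool = False) -> "EffectConfig":
        """Effect configuration mirroring the study's findings: an
        illusion-vs-control amplitude gain in every ROI and a drift-path
        pattern only in hMT+."""
        return cls(
            illusion_gain={r: 0.3 for r in ROI_NAMES},
            path_pattern_sd={"hMT": 0.3},
            attend_fixation=attend_fixation,
        )


@dataclass(frozen=True)
class NoiseConfig:
    """AR(1) voxel noise plus slow sinusoidal drift, percent signal.

    ``white_sd`` is the stationary SD of the AR(1) process; the drift
    period sits below the 0.01 Hz high-pass cutoff so the filter stage is
    exercised.  Zero everywhere gives noiseless data.
    """

    white_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    drift_period: float = 128.0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if min(self.white_sd, self.drift_amplitude, self.drift_period) < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(white_sd=0.0, ar1_coef=0.0, drift_amplitude=0.0)


@dataclass(frozen=True)
class OculomotorConfig:
    """Parameters of the simulated pursuit/fixation oculomotor behaviour.

    ``condition_bias`` is a horizontal gaze offset added during illusion
    blocks (positive rightward for the rightward drift path); it is zero
    under the null, in which case the traces carry no condition
    information.
    """

    pursuit_gain: float = 0.95
    catchup_rate: float = 2.0  # Hz
    microsaccade_rate: float = 1.0  # Hz, during fixation
    microsaccade_amp_range: tuple = (0.1, 0.6)  # deg
    blink_rate: float = 0.1  # Hz
    blink_duration_ms: float = 150.0
    tracker_noise_sd: float = 0.02  # deg
    condition_bias: float = 0.0  # deg
    saccade_duration_ms: float = 20.0

    @classmethod
    def none(cls) -> "OculomotorConfig":
        """Perfect noiseless pursuit: gain 1, no saccades, blinks or noise."""
        return cls(
            pursuit_gain=1.0,
            catchup_rate=0.0,
            microsaccade_rate=0.0,
            blink_rate=0.0,
            tracker_noise_sd=0.0,
            condition_bias=0.0,
        )


@dataclass
class VoxelPopulation:
    """Fixed per-session voxel properties shared by all runs."""

    roi_labels: np.ndarray
    baseline: np.ndarray
    stim_responsive: np.ndarray  # bool
    pursuit_responsive: np.ndarray  # bool
    response_amplitude: np.ndarray
    pattern_map: np.ndarray  # signed left/right map (0 where inert)

    @property
    def n_voxels(self) -> int:
        return self.roi_labels.size


def make_voxel_population(
    rois: list[RoiConfig], effects: EffectConfig, seed: int
) -> VoxelPopulation:
    """Draw the session-level voxel properties (responsive sets, pattern map)."""
    rng = np.random.default_rng(seed)
    labels, baseline, stim, pursuit, amp, pattern = [], [], [], [], [], []
    for roi in rois:
        n = roi.n_voxels
        labels += [roi.name] * n
        baseline += [roi.baseline] * n
        s = np.zeros(n, bool)
        s[: int(round(roi.localizer_responsive_fraction * n))] = True
        p = np.zeros(n, bool)
        p[rng.permutation(n)[: int(round(roi.pursuit_responsive_fraction * n))]] = True
        stim.append(s)
        pursuit.append(p)
        amp.append(np.full(n, roi.response_amplitude))
        pm = rng.normal(0.0, effects.pattern_sd(roi.name) or 0.0, size=n)
        pm[~s] = 0.0  # pattern information lives in stimulus-responsive voxels
        if effects.pattern_sd(roi.name) == 0:
            pm[:] = 0.0
        pattern.append(pm)
    return VoxelPopulation(
        roi_labels=np.array(labels),
        baseline=np.array(baseline, float),
        stim_responsive=np.concatenate(stim),
        pursuit_responsive=np.concatenate(pursuit),
        response_amplitude=np.concatenate(amp),
        pattern_map=np.concatenate(pattern),
    )


def _block_amplitudes(
    population: VoxelPopulation, effects: EffectConfig, schedule: RunSchedule
) -> np.ndarray:
    """Ground-truth evoked amplitude (percent signal) per voxel per
    stimulus block."""
    blocks = schedule.stimulus_blocks()
    amps = np.zeros((population.n_voxels, len(blocks)))
    for j, block in enumerate(blocks):
        c = block.condition
        a = np.zeros(population.n_voxels)
        if c in STIMULUS_CONDITIONS or c is ConditionLabel.STIMULUS_ON:
            a[population.stim_responsive] += population.response_amplitude[
                population.stim_responsive
            ]
        if c in PURSUIT_CONDITIONS:
            a[population.pursuit_responsive] += 0.5 * population.response_amplitude[
                population.pursuit_responsive
            ]
        if c in ILLUSION_CONDITIONS:
            for roi in np.unique(population.roi_labels):
                sel = (population.roi_labels == roi) & population.stim_responsive
                a[sel] += effects.gain(str(roi))
            sign = 1.0 if c is ConditionLabel.LEFT_ILLUSION else -1.0
            a += sign * population.pattern_map
        amps[:, j] = a
    return amps


def simulate_bold_run(
    schedule: RunSchedule,
    rois: list[RoiConfig],
    effects: EffectConfig,
    noise: NoiseConfig,
    hrf_truth: HRF,
    seed: int,
    population: VoxelPopulation | None = None,
):
    """Simulate one run's raw voxel time series.

    Each voxel's neural block amplitude (localizer-driven base response
    plus condition effects plus pattern term) is convolved with the
    ground-truth block HRF on the TR grid; AR(1) noise and sinusoidal
    drift are added, and the result is expressed in raw scanner units
    around the ROI baseline (percent-signal conversion is the pipeline's
    job).  Bit-identical for identical seeds.

    Returns
    -------
    (VoxelTimeSeries, ground-truth amplitude matrix voxels x blocks)
    """
    if abs(hrf_truth.tr - schedule.tr) > 1e-9:
        raise ValueError("hrf_truth sampling must match the schedule TR")
    if population is None:
        population = make_voxel_population(rois, effects, seed)
    rng = np.random.default_rng(seed)
    n_vox, n_vol = population.n_voxels, schedule.n_volumes
    amps = _block_amplitudes(population, effects, schedule)

    signal = np.zeros((n_vox, n_vol))
    for j, block in enumerate(schedule.stimulus_blocks()):
        onset = schedule.onset_volume(block)
        n = min(len(hrf_truth), n_vol - onset)
        signal[:, onset : onset + n] += np.outer(amps[:, j], hrf_truth.values[:n])

    if noise.white_sd > 0:
        innov_sd = noise.white_sd * np.sqrt(1.0 - noise.ar1_coef**2)
        eps = rng.normal(0.0, innov_sd, size=(n_vox, n_vol))
        ar = np.empty_like(eps)
        ar[:, 0] = rng.normal(0.0, noise.white_sd, size=n_vox)
        for t in range(1, n_vol):
            ar[:, t] = noise.ar1_coef * ar[:, t - 1] + eps[:, t]
        signal = signal + ar
    if noise.drift_amplitude > 0:
        t = np.arange(n_vol) * schedule.tr
        phases = rng.uniform(0, 2 * np.pi, size=n_vox)
        signal = signal + noise.drift_amplitude * np.sin(
            2 * np.pi * t / noise.drift_period + phases[:, None]
        )

    raw = population.baseline[:, None] * (1.0 + signal / 100.0)
    ts = VoxelTimeSeries(
        data=raw,
        tr=schedule.tr,
        run_id=schedule.seed if schedule.seed is not None else 0,
        roi_labels=population.roi_labels,
        units="raw",
    )
    return ts, amps


@dataclass
class Session:
    """One simulated scanning session: task runs plus localizers."""

    expt_id: int
    task_runs: list
    task_schedules: list
    stim_localizer_runs: list
    eye_localizer_runs: list
    stim_localizer_schedule: RunSchedule
    eye_localizer_schedule: RunSchedule
    population: VoxelPopulation
    hrf_truth: HRF
    ground_truth_amplitudes: list
    eye_traces: list | None = None


def simulate_session(
    expt_id: int,
    n_runs: int,
    seed: int,
    rois: list[RoiConfig] | None = None,
    effects: EffectConfig | None = None,
    noise: NoiseConfig | None = None,
    ocfg: OculomotorConfig | None = None,
    spec: StimulusSpec | None = None,
    hrf_truth: HRF | None = None,
    with_eye: bool | None = None,
) -> Session:
    """Simulate a full scanning session.

    The session comprises ``n_runs`` task runs (288 s each, block order
    re-randomized per run), three stimulus-only localizer runs and two
    eye-movement localizer runs (252 s each).  For experiment 4 (or when
    ``with_eye`` is true) a concurrent eye trace is generated per task
    run.  All randomness derives from ``seed``.
    """
    if n_runs < 2:
        raise ValueError("leave-one-run-out decoding needs at least 2 runs")
    rois = rois if rois is not None else default_rois()
    effects = effects if effects is not None else EffectConfig()
    noise = noise if noise is not None else NoiseConfig()
    spec = spec or StimulusSpec()
    hrf_truth = hrf_truth or canonical_block_hrf()
    if with_eye is None:
        with_eye = expt_id == 4
    ocfg = ocfg if ocfg is not None else OculomotorConfig()

    root = np.random.SeedSequence(seed)
    pop_seed, *run_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(1 + n_runs + 5 + n_runs)
    ]
    population = make_voxel_population(rois, effects, pop_seed)

    task_runs, task_schedules, truths = [], [], []
    for i in range(n_runs):
        sch = build_run_schedule(expt_id, seed=run_seeds[i])
        ts, amps = simulate_bold_run(
            sch, rois, effects, noise, hrf_truth, run_seeds[i], population
        )
        ts.run_id = i
        task_runs.append(ts)
        task_schedules.append(sch)
        truths.append(amps)

    stim_sch = build_run_schedule("stim_localizer")
    eye_sch = build_run_schedule("eye_localizer")
    loc_seeds = run_seeds[n_runs : n_runs + 5]
    stim_loc, eye_loc = [], []
    for k in range(N_STIM_LOCALIZER_RUNS):
        ts, _ = simulate_bold_run(
            stim_sch, rois, effects, noise, hrf_truth, loc_seeds[k], population
        )
        ts.run_id = f"stim_loc_{k}"
        stim_loc.append(ts)
    for k in range(N_EYE_LOCALIZER_RUNS):
        ts, _ = simulate_bold_run(
            eye_sch, rois, effects, noise, hrf_truth, loc_seeds[3 + k], population
        )
        ts.run_id = f"eye_loc_{k}"
        eye_loc.append(ts)

    eye_traces = None
    if with_eye:
        eye_seeds = run_seeds[n_runs + 5 :]
        eye_traces = []
        for i, sch in enumerate(task_schedules):
            tr = simulate_eye_run(sch, spec, ocfg, eye_seeds[i])
            tr.run_id = i
            eye_traces.append(tr)

    return Session(
        expt_id=expt_id,
        task_runs=task_runs,
        task_schedules=task_schedules,
        stim_localizer_runs=stim_loc,
        eye_localizer_runs=eye_loc,
        stim_localizer_schedule=stim_sch,
        eye_localizer_schedule=eye_sch,
        population=population,
        hrf_truth=hrf_truth,
        ground_truth_amplitudes=truths,
        eye_traces=eye_traces,
    )


def _smooth_step(n: int) -> np.ndarray:
    """Raised-cosine position profile from 0 to 1 over n samples."""
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n + 1) / n))


def target_trajectory(schedule: RunSchedule, spec: StimulusSpec) -> np.ndarray:
    """Vertical pursuit-target position at 1000 Hz over the whole run."""
    n = int(round(schedule.duration_s * SAMPLE_HZ))
    t = np.arange(n) / SAMPLE_HZ
    # between pursuit blocks the target rests at the path's lower endpoint,
    # so pursuit onsets are continuous
    el = np.full(n, -spec.path_length / 2.0)
    for block in schedule.blocks:
        if block.condition not in PURSUIT_CONDITIONS:
            continue
        sel = (t >= block.onset_s) & (t < block.onset_s + block.duration_s)
        el[sel] = envelope_elevation(spec, t[sel] - block.onset_s)
    return el


def simulate_eye_run(
    schedule: RunSchedule,
    spec: StimulusSpec,
    ocfg: OculomotorConfig,
    seed: int,
) -> EyeTrace:
    """Simulate one run's 1000 Hz two-channel gaze trace.

    During pursuit, elevation follows the target at ``pursuit_gain``; the
    accumulated lag ``(1 - gain) x target displacement since the last
    correction`` is eliminated by Poisson-timed catch-up saccades
    (raised-cosine steps of ~20 ms).  Microsaccades occur during fixation
    at ``microsaccade_rate``; blinks mask ~150 ms gaps; tracker noise is
    white.  ``condition_bias`` shifts azimuth during illusion blocks
    (rightward positive for the rightward drift path).
    """
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration_s * SAMPLE_HZ))
    target = target_trajectory(schedule, spec)
    az = np.zeros(n)
    el = np.zeros(n)
    sac_len = max(int(round(ocfg.saccade_duration_ms * SAMPLE_HZ / 1000.0)), 2)

    pursuit_mask = np.zeros(n, bool)
    t = np.arange(n) / SAMPLE_HZ
    for block in schedule.blocks:
        sel = (t >= block.onset_s) & (t < block.onset_s + block.duration_s)
        if block.condition in PURSUIT_CONDITIONS:
            pursuit_mask[sel] = True
        if ocfg.condition_bias and block.condition in ILLUSION_CONDITIONS:
            sign = 1.0 if block.condition is ConditionLabel.RIGHT_ILLUSION else -1.0
            az[sel] += sign * ocfg.condition_bias

    # pursuit with catch-up corrections: between corrections the eye moves
    # at gain x target velocity; each Poisson-timed catch-up saccade
    # eliminates the lag accumulated since the previous correction
    if ocfg.catchup_rate > 0 and pursuit_mask.any():
        pool = np.flatnonzero(pursuit_mask)
        n_events = min(rng.poisson(ocfg.catchup_rate * pool.size / SAMPLE_HZ), pool.size)
        event_idx = np.sort(rng.choice(pool, size=n_events, replace=False))
    else:
        event_idx = np.array([], int)
    eye_el = target[0] + ocfg.pursuit_gain * (target - target[0])
    catchups = []
    last = 0
    for idx in event_idx:
        # lag accumulated since the last correction
        lag = (1.0 - ocfg.pursuit_gain) * (target[idx] - target[last])
        step = np.zeros(n - idx)
        prof = _smooth_step(min(sac_len, n - idx))
        step[: prof.size] = prof * lag
        step[prof.size :] = lag
        eye_el[idx:] += step
        catchups.append({"index": int(idx), "lag": float(lag)})
        last = idx
    el += eye_el

    microsaccades = []
    # microsaccades during fixation
    if ocfg.microsaccade_rate > 0:
        fix_idx = np.flatnonzero(~pursuit_mask)
        n_ms = rng.poisson(ocfg.microsaccade_rate * fix_idx.size / SAMPLE_HZ)
        if n_ms:
            for idx in np.sort(rng.choice(fix_idx, size=n_ms, replace=False)):
                amp = rng.uniform(*ocfg.microsaccade_amp_range)
                ang = rng.uniform(0, 2 * np.pi)
                prof = _smooth_step(min(sac_len, n - idx))
                step = np.concatenate([prof, np.ones(n - idx - prof.size)])
                # step out and (after ~200 ms) back, keeping fixation stable
                az[idx:] += amp * np.cos(ang) * step
                el[idx:] += amp * np.sin(ang) * step
                back = min(idx + 200, n - 1)
                prof2 = _smooth_step(min(sac_len, n - back))
                step2 = np.concatenate([prof2, np.ones(n - back - prof2.size)])
                az[back:] -= amp * np.cos(ang) * step2
                el[back:] -= amp * np.sin(ang) * step2
                microsaccades.append(
                    {"index": int(idx), "amplitude": float(amp), "direction": float(ang)}
                )

    if ocfg.tracker_noise_sd > 0:
        az += rng.normal(0, ocfg.tracker_noise_sd, n)
        el += rng.normal(0, ocfg.tracker_noise_sd, n)

    blink_mask = np.zeros(n, bool)
    if ocfg.blink_rate > 0:
        n_blinks = rng.poisson(ocfg.blink_rate * n / SAMPLE_HZ)
        blen = int(round(ocfg.blink_duration_ms * SAMPLE_HZ / 1000.0))
        for idx in rng.integers(0, max(n - blen, 1), size=n_blinks):
            blink_mask[idx : idx + blen] = True
            az[idx : idx + blen] = 0.0
            el[idx : idx + blen] = 0.0

    return EyeTrace(
        az=az,
        el=el,
        blink_mask=blink_mask,
        run_id=0,
        ground_truth={"catchups": catchups, "microsaccades": microsaccades},
    )
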