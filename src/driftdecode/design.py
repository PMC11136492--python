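"""Stimulus kinematics and experimental designs for the double-drift illusion.

The double-drift (curveball) stimulus is a Gabor whose Gaussian envelope
travels along a vertical path in the periphery while its carrier grating
drifts orthogonally.  The conjunction of envelope (global) and carrier
(local) motion shifts the perceived path by up to ~45 deg away from the
veridical trajectory, even during smooth pursuit that stabilises the
stimulus on the retina.

This module generates:

* the veridical envelope trajectory and carrier phase for every condition
  (:func:`gabor_trajectory`),
* a parametric model of the perceived path given a judged illusion angle
  (:func:`perceived_path`),
* the block/run schedules of the four block-design experiments and the two
  phase-encoded localizers (:func:`build_run_schedule`).

All positions are in degrees of visual angle, all times in seconds.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConditionLabel",
    "StimulusSpec",
    "Block",
    "RunSchedule",
    "TrajectorySamples",
    "gabor_trajectory",
    "perceived_path",
    "build_run_schedule",
    "TR_DEFAULT",
]

#: Volume repetition time of the scanning protocol, seconds.
TR_DEFAULT = 1.5

#: Duration of every block in the task experiments, seconds.
BLOCK_S = 12.0

#: Duration of each half-cycle of the localizer alternation, seconds.
LOCALIZER_HALF_CYCLE_S = 9.0

#: Number of on/off cycles per localizer run.
LOCALIZER_CYCLES = 14

#: Update rate of the randomised carrier direction in the no-illusion
#: control, Hz.
CARRIER_RESAMPLE_HZ = 60.0


class ConditionLabel(enum.StrEnum):
    """Block conditions across all experiments.

    ``LEFT_ILLUSION``/``RIGHT_ILLUSION`` are the two double-drift
    conditions; ``NO_ILLUSION`` is the motion-energy-matched control with
    carrier direction resampled at 60 Hz.  ``LOCAL_LR``/``LOCAL_RL`` are the
    local-motion-only controls (stationary envelope, no pursuit) with the
    same carrier sequences as the left/right illusions.  ``STIMULUS_ON`` and
    ``PURSUIT`` label the on half-cycles of the stimulus-only and
    eye-movement localizers.
    """

    LEFT_ILLUSION = "LEFT_ILLUSION"
    RIGHT_ILLUSION = "RIGHT_ILLUSION"
    NO_ILLUSION = "NO_ILLUSION"
    LOCAL_LR = "LOCAL_LR"
    LOCAL_RL = "LOCAL_RL"
    FIXATION = "FIXATION"
    STIMULUS_ON = "STIMULUS_ON"
    PURSUIT = "PURSUIT"


#: Conditions during which a visual stimulus is displayed.
STIMULUS_CONDITIONS = frozenset(
    {
        ConditionLabel.LEFT_ILLUSION,
        ConditionLabel.RIGHT_ILLUSION,
        ConditionLabel.NO_ILLUSION,
        ConditionLabel.LOCAL_LR,
        ConditionLabel.LOCAL_RL,
    }
)

#: Conditions during which the pursuit target moves (the eyes pursue).
PURSUIT_CONDITIONS = frozenset(
    {
        ConditionLabel.LEFT_ILLUSION,
        ConditionLabel.RIGHT_ILLUSION,
        ConditionLabel.NO_ILLUSION,
        ConditionLabel.PURSUIT,
    }
)

#: The two illusory drift-path conditions.
ILLUSION_CONDITIONS = frozenset(
    {ConditionLabel.LEFT_ILLUSION, ConditionLabel.RIGHT_ILLUSION}
)

_EXPT12_CONDITIONS = (
    ConditionLabel.LEFT_ILLUSION,
    ConditionLabel.RIGHT_ILLUSION,
    ConditionLabel.NO_ILLUSION,
)
_EXPT34_CONDITIONS = (
    ConditionLabel.LEFT_ILLUSION,
    ConditionLabel.RIGHT_ILLUSION,
    ConditionLabel.LOCAL_LR,
    ConditionLabel.LOCAL_RL,
)

TASK_EXPTS = (1, 2, 3, 4)
LOCALIZER_EXPTS = ("stim_localizer", "eye_localizer")


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and kinematics of the double-drift Gabor.

    Parameters
    ----------
    grating_sf:
        Carrier spatial frequency, cycles/deg.
    envelope_sd:
        Standard deviation of the Gaussian envelope, deg.
    path_length:
        Length of the vertical envelope path, deg.
    traversal_duration:
        Duration of one full up-down traversal, s (750 ms up + 750 ms
        down by default; 8 traversals tile a 12 s block).
    internal_tf:
        Temporal frequency of the carrier drift, Hz.
    eccentricity:
        Horizontal offset of the Gabor from the pursuit target, deg
        (positive: stimulus in the right visual field).
    smoothing_window:
        Duration of the raised-cosine velocity ramp applied at each path
        endpoint so that pursuit can follow the direction reversals, s.
    """

    grating_sf: float = 1.0
    envelope_sd: float = 1.0
    path_length: float = 8.0
    traversal_duration: float = 1.5
    internal_tf: float = 6.66
    eccentricity: float = 10.5
    smoothing_window: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "grating_sf",
            "envelope_sd",
            "path_length",
            "traversal_duration",
            "internal_tf",
            "eccentricity",
            "smoothing_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"StimulusSpec.{name} must be strictly positive")
        if self.smoothing_window >= self.traversal_duration / 2:
            raise ValueError("smoothing_window must be shorter than one half-traversal")

    @property
    def leg_duration(self) -> float:
        """Duration of a single up or down leg, s."""
        return self.traversal_duration / 2.0

    @property
    def mean_speed(self) -> float:
        """Mean vertical envelope speed over a leg, deg/s."""
        return self.path_length / self.leg_duration


@dataclass(frozen=True)
class Block:
    condition: ConditionLabel
    onset_s: float
    duration_s: float


@dataclass
class RunSchedule:
    """Ordered condition blocks on a TR grid — the temporal skeleton of a run."""

    blocks: list[Block]
    tr: float
    n_volumes: int
    expt_id: int | str
    seed: int | None = None

    def __post_init__(self) -> None:
        t = 0.0
        for b in self.blocks:
            if abs(b.onset_s - t) > 1e-9:
                raise ValueError("blocks must tile the run with no gaps or overlaps")
            if abs(b.onset_s / self.tr - round(b.onset_s / self.tr)) > 1e-9:
                raise ValueError("block onsets must be multiples of TR")
            t = b.onset_s + b.duration_s
        if abs(t - self.n_volumes * self.tr) > 1e-9:
            raise ValueError("blocks must tile exactly n_volumes * tr seconds")

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr

    def stimulus_blocks(self) -> list[Block]:
        """Blocks during which a stimulus (or pursuit target motion) is on,
        i.e. everything except FIXATION."""
        return [b for b in self.blocks if b.condition is not ConditionLabel.FIXATION]

    def onset_volume(self, block: Block) -> int:
        return int(round(block.onset_s / self.tr))

    def condition_counts(self) -> dict[ConditionLabel, int]:
        counts: dict[ConditionLabel, int] = {}
        for b in self.blocks:
            counts[b.condition] = counts.get(b.condition, 0) + 1
        return counts

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the block table as TSV (condition, onset_s, duration_s)."""
        with open(path, "w") as fh:
            fh.write("condition\tonset_s\tduration_s\n")
            for b in self.blocks:
                fh.write(f"{b.condition.value}\t{b.onset_s:g}\t{b.duration_s:g}\n")

    def manifest(self) -> dict:
        return {
            "expt_id": self.expt_id,
            "tr": self.tr,
            "n_volumes": self.n_volumes,
            "seed": self.seed,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)

    @classmethod
    def from_tsv(cls, path, tr: float, expt_id, seed: int | None = None) -> "RunSchedule":
        blocks = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["condition", "onset_s", "duration_s"]:
                raise ValueError(f"unexpected schedule header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                cond, onset, dur = line.rstrip("\n").split("\t")[:3]
                blocks.append(Block(ConditionLabel(cond), float(onset), float(dur)))
        total = blocks[-1].onset_s + blocks[-1].duration_s
        return cls(blocks, tr, int(round(total / tr)), expt_id, seed)


@dataclass
class TrajectorySamples:
    """Sampled stimulus kinematics over a time grid within one block."""

    t: np.ndarray
    veridical_x: np.ndarray
    veridical_y: np.ndarray
    carrier_phase: np.ndarray
    carrier_direction: np.ndarray  # signed unit drift direction (+1 right, -1 left)

    def veridical_xy(self) -> np.ndarray:
        return np.column_stack([self.veridical_x, self.veridical_y])


def _leg_position(u: np.ndarray, leg: float, tau: float, length: float) -> np.ndarray:
    """Distance travelled along one leg at leg-time ``u``.

    The velocity profile is constant with raised-cosine on/off ramps of
    duration ``tau``, so that speed is zero exactly at the reversals.  The
    plateau speed is ``length / (leg - tau)``, which makes the displacement
    over the full leg equal ``length``.
    """
    v = length / (leg - tau)
    pos = np.empty_like(u, dtype=float)
    a = u < tau
    b = (u >= tau) & (u <= leg - tau)
    c = u > leg - tau
    pos[a] = 0.5 * v * (u[a] - (tau / np.pi) * np.sin(np.pi * u[a] / tau))
    pos[b] = 0.5 * v * tau + v * (u[b] - tau)
    w = u[c] - (leg - tau)
    pos[c] = (
        0.5 * v * tau
        + v * (leg - 2 * tau)
        + 0.5 * v * (w + (tau / np.pi) * np.sin(np.pi * w / tau))
    )
    return pos


def envelope_elevation(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """Vertical envelope position at block time ``t``, deg, centred on 0.

    The path starts at the bottom endpoint (-path_length/2), rises to the
    top over one leg, and returns; it is periodic with period
    ``traversal_duration``.
    """
    t = np.asarray(t, dtype=float)
    leg = spec.leg_duration
    u = np.mod(t, spec.traversal_duration)
    up = u < leg
    y = np.empty_like(u)
    y[up] = _leg_position(u[up], leg, spec.smoothing_window, spec.path_length)
    y[~up] = spec.path_length - _leg_position(
        u[~up] - leg, leg, spec.smoothing_window, spec.path_length
    )
    return y - spec.path_length / 2.0


def _leg_index(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """0 during up legs, 1 during down legs."""
    u = np.mod(np.asarray(t, dtype=float), spec.traversal_duration)
    return (u >= spec.leg_duration).astype(int)


def _deterministic_carrier_direction(
    spec: StimulusSpec, condition: ConditionLabel, t: np.ndarray
) -> np.ndarray:
    """Signed carrier drift direction for the non-random conditions.

    Left illusion: carrier drifts leftward (-1) on the up leg, rightward on
    the down leg; right illusion is the mirror image.  The local-motion
    controls reuse the illusion conditions' carrier sequences.
    """
    leg = _leg_index(spec, t)
    if condition in (ConditionLabel.LEFT_ILLUSION, ConditionLabel.LOCAL_LR):
        return np.where(leg == 0, -1.0, 1.0)
    if condition in (ConditionLabel.RIGHT_ILLUSION, ConditionLabel.LOCAL_RL):
        return np.where(leg == 0, 1.0, -1.0)
    raise ValueError(f"no deterministic carrier direction for {condition}")


def gabor_trajectory(
    spec: StimulusSpec,
    condition: ConditionLabel,
    t_grid: np.ndarray,
    seed: int = 0,
) -> TrajectorySamples:
    """Veridical envelope trajectory and carrier phase within one block.

    Parameters
    ----------
    spec:
        Stimulus geometry and kinematics.
    condition:
        A stimulus condition; FIXATION has no trajectory and raises.
    t_grid:
        Sample times within the block, s from block onset.
    seed:
        Seeds the 60 Hz carrier-direction resampling of the NO_ILLUSION
        control; ignored for the deterministic conditions.

    Returns
    -------
    TrajectorySamples
        Envelope x/y (deg, x relative to the pursuit target), unwrapped
        carrier phase (rad) and the signed carrier drift direction.

    Notes
    -----
    The carrier advances at ``internal_tf`` cycles/s in the signed drift
    direction, which reverses at each path endpoint, so the net signed
    carrier displacement over one full traversal is zero for the illusion
    conditions.  In the local-motion controls the envelope is stationary at
    the path midpoint while the carrier sequence is unchanged.
    """
    if condition not in STIMULUS_CONDITIONS:
        raise ValueError(f"no trajectory defined for condition {condition}")
    t = np.asarray(t_grid, dtype=float)

    if condition is ConditionLabel.NO_ILLUSION:
        # piecewise-constant random direction, resampled at 60 Hz
        rng = np.random.default_rng(seed)
        t_max = float(t.max()) if t.size else 0.0
        n_bins = int(np.floor(t_max * CARRIER_RESAMPLE_HZ)) + 1
        signs = rng.choice([-1.0, 1.0], size=n_bins)
        dt_bin = 1.0 / CARRIER_RESAMPLE_HZ
        # cumulative signed time at each bin start
        cum = np.concatenate([[0.0], np.cumsum(signs) * dt_bin])
        bins = np.minimum((t / dt_bin).astype(int), n_bins - 1)
        signed_time = cum[bins] + signs[bins] * (t - bins * dt_bin)
        direction = signs[bins]
        phase = 2 * np.pi * spec.internal_tf * signed_time
    else:
        direction = _deterministic_carrier_direction(spec, condition, t)
        leg = spec.leg_duration
        n_legs = np.floor(t / leg)
        u = t - n_legs * leg
        # legs alternate sign, so completed legs cancel pairwise
        s0 = direction - 0.0  # sign of current leg
        # signed time within the current leg plus net of completed legs
        completed = np.where(np.mod(n_legs, 2) == 1, -s0 * leg, 0.0)
        signed_time = completed + s0 * u
        # completed pairs contribute zero; odd leg count leaves one leg of
        # the *previous* sign = -s0, already accounted above
        phase = 2 * np.pi * spec.internal_tf * signed_time

    if condition in (ConditionLabel.LOCAL_LR, ConditionLabel.LOCAL_RL):
        y = np.zeros_like(t)
    else:
        y = envelope_elevation(spec, t)
    x = np.full_like(t, spec.eccentricity)
    return TrajectorySamples(t, x, y, phase, direction)


def perceived_path(
    spec: StimulusSpec,
    condition: ConditionLabel,
    illusion_angle: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Model of the perceived stimulus path given a judged illusion angle.

    The percept is modelled as a constant-angle deflection of the physical
    path: lateral offset accumulates at ``tan(angle)`` times the vertical
    speed, with sign set by the condition, and reverses with each leg so the
    perceived path closes on itself every up-down cycle.  A rightward drift
    path therefore spends the whole traversal at or beyond the veridical
    eccentricity, a leftward path at or inside it.

    Parameters
    ----------
    illusion_angle:
        Judged angle between perceived and physical path, deg, in [0, 60].

    Returns
    -------
    (n, 2) array of perceived x/y positions, deg.
    """
    if not 0 <= illusion_angle <= 60:
        raise ValueError("illusion_angle must be in [0, 60] deg")
    t = np.asarray(t_grid, dtype=float)
    y = envelope_elevation(spec, t)
    if condition is ConditionLabel.RIGHT_ILLUSION:
        sign = 1.0
    elif condition is ConditionLabel.LEFT_ILLUSION:
        sign = -1.0
    else:
        sign = 0.0
    # offset proportional to distance travelled from the bottom endpoint:
    # grows over the up leg, unwinds over the down leg -> closed cycle
    offset = sign * np.tan(np.deg2rad(illusion_angle)) * (y + spec.path_length / 2.0)
    x = spec.eccentricity + offset
    return np.column_stack([x, y])


def _interleaved_schedule(
    conditions: tuple[ConditionLabel, ...],
    repeats: int,
    seed: int,
    tr: float,
    expt_id,
) -> RunSchedule:
    rng = np.random.default_rng(seed)
    order = list(np.repeat(np.arange(len(conditions)), repeats))
    order = [conditions[i] for i in rng.permutation(order)]
    blocks: list[Block] = []
    t = 0.0
    for cond in order:
        blocks.append(Block(ConditionLabel.FIXATION, t, BLOCK_S))
        t += BLOCK_S
        blocks.append(Block(cond, t, BLOCK_S))
        t += BLOCK_S
    n_volumes = int(round(t / tr))
    return RunSchedule(blocks, tr, n_volumes, expt_id, seed)


def _localizer_schedule(on_label: ConditionLabel, tr: float, expt_id) -> RunSchedule:
    blocks: list[Block] = []
    t = 0.0
    for _ in range(LOCALIZER_CYCLES):
        blocks.append(Block(on_label, t, LOCALIZER_HALF_CYCLE_S))
        t += LOCALIZER_HALF_CYCLE_S
        blocks.append(Block(ConditionLabel.FIXATION, t, LOCALIZER_HALF_CYCLE_S))
        t += LOCALIZER_HALF_CYCLE_S
    return RunSchedule(blocks, tr, int(round(t / tr)), expt_id, None)


def build_run_schedule(expt_id, seed: int = 0, tr: float = TR_DEFAULT) -> RunSchedule:
    """Build the block schedule of one run.

    Experiments 1/2: 288 s runs of four blocks of each of three conditions
    (left illusion, right illusion, no-illusion control), each 12 s stimulus
    block preceded by a 12 s fixation block, in randomized order.
    Experiments 3/4: 288 s runs of three blocks of each of four conditions
    (the two illusions plus the two local-motion controls).  Localizers:
    fixed 14-cycle alternations of 9 s on / 9 s off, 252 s.

    Deterministic given ``seed``; the localizer schedules ignore it.
    """
    if expt_id in (1, 2):
        return _interleaved_schedule(_EXPT12_CONDITIONS, 4, seed, tr, expt_id)
    if expt_id in (3, 4):
        return _interleaved_schedule(_EXPT34_CONDITIONS, 3, seed, tr, expt_id)
    if expt_id == "stim_localizer":
        return _localizer_schedule(ConditionLabel.STIMULUS_ON, tr, expt_id)
    if expt_id == "eye_localizer":
        return _localizer_schedule(ConditionLabel.PURSUIT, tr, expt_id)
    raise ValueError(f"unknown expt_id: {expt_id!r}")
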