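"""Eye-trace preprocessing, microsaccade statistics, and eye decoding.

These are the oculomotor control analyses: if the illusion altered smooth
pursuit or saccadic behaviour, condition information might be present in
the eye traces themselves.  The module provides

* blink repair and per-run mean centering (no temporal smoothing),
* velocity-threshold (Engbert-Kliegl) saccade/microsaccade detection,
  operating on pursuit-velocity residuals during pursuit,
* amplitude/direction histograms and a two-way ANOVA
  (illusion-vs-control x direction) on per-subject mean amplitudes,
* traversal-wise segmentation of the traces into labeled exemplars and
  linear-SVM decoding with leave-one-run-out cross-validation and a
  permutation null, mirroring the BOLD decoding analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import (
    ConditionLabel,
    ILLUSION_CONDITIONS,
    RunSchedule,
    StimulusSpec,
)
from .decode import DecodingResult, permute_labels_within_runs

__all__ = [
    "EyeTrace",
    "SaccadeEvent",
    "EyeExemplar",
    "repair_and_center",
    "detect_saccades",
    "saccade_stats",
    "segment_traversals",
    "eye_svm_decode",
    "read_asc_samples",
]

SAMPLE_HZ = 1000.0


@dataclass
class EyeTrace:
    """Two-channel gaze trace at 1000 Hz with a blink/dropout mask."""

    az: np.ndarray  # deg
    el: np.ndarray  # deg
    blink_mask: np.ndarray  # True where data missing
    run_id: int | str = 0
    #: generator ground truth (event times/sizes) for recovery tests;
    #: never written to disk
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.az = np.asarray(self.az, dtype=float)
        self.el = np.asarray(self.el, dtype=float)
        self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if not (self.az.shape == self.el.shape == self.blink_mask.shape):
            raise ValueError("az, el and blink_mask must have equal length")

    @property
    def n_samples(self) -> int:
        return self.az.size

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.n_samples, dtype=float)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_ms\taz_deg\tel_deg\tblink\n")
            for i in range(self.n_samples):
                fh.write(
                    f"{i}\t{self.az[i]:.6g}\t{self.el[i]:.6g}\t{int(self.blink_mask[i])}\n"
                )

    @classmethod
    def from_tsv(cls, path, run_id=0) -> "EyeTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            az=df["az_deg"].to_numpy(),
            el=df["el_deg"].to_numpy(),
            blink_mask=df["blink"].to_numpy().astype(bool),
            run_id=run_id,
        )


def read_asc_samples(path, run_id=0) -> EyeTrace:
    """Import shim for EyeLink ASC sample lines (t, x, y, pupil).

    Non-sample lines (events, messages) are ignored; samples with missing
    position ('.') are masked as blinks.
    """
    az, el, mask = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue
            try:
                x, y = float(parts[1]), float(parts[2])
                az.append(x)
                el.append(y)
                mask.append(False)
            except (ValueError, IndexError):
                az.append(0.0)
                el.append(0.0)
                mask.append(True)
    return EyeTrace(np.array(az), np.array(el), np.array(mask), run_id)


@dataclass
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude: float  # deg
    direction: float  # radians

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class EyeExemplar:
    """One traversal's concatenated azimuth+elevation feature vector."""

    features: np.ndarray
    label: ConditionLabel
    run_id: int | str
    segment: str = "illusion"


def _fill_gaps(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return x.copy()
    if mask.all():
        raise ValueError("trace contains no valid samples")
    idx = np.arange(x.size)
    # np.interp extends with the nearest valid value at the boundaries
    return np.interp(idx, idx[~mask], x[~mask])


def repair_and_center(trace: EyeTrace) -> EyeTrace:
    """Linearly interpolate blink gaps and mean-center each channel.

    Gaps at the trace boundary are extended from the nearest valid sample.
    No temporal smoothing is applied.
    """
    az = _fill_gaps(trace.az, trace.blink_mask)
    el = _fill_gaps(trace.el, trace.blink_mask)
    return replace(trace, az=az - az.mean(), el=el - el.mean())


def _velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """5-point central-difference velocity estimate."""
    if x.size < 5:
        raise ValueError("trace shorter than the differentiation window")
    v = np.zeros_like(x)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    return v


def _median_sd(v: np.ndarray) -> float:
    """Median-based velocity SD (robust to the saccades themselves)."""
    sd = np.sqrt(np.median(v**2) - np.median(v) ** 2)
    if sd <= 0:
        sd = np.sqrt(np.mean(v**2)) or 1e-12
    return sd


def detect_saccades(
    trace: EyeTrace,
    lam: float = 6.0,
    min_dur_ms: float = 6.0,
    target: np.ndarray | None = None,
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection (Engbert-Kliegl style).

    Velocities are computed by 5-point differentiation; per channel, a
    threshold at ``lam`` times the median-based velocity SD defines an
    elliptic criterion, and supra-threshold runs of at least
    ``min_dur_ms`` are events.  During pursuit, pass the known target
    position profile (1-D elevation, or 2 x n for both channels); it is
    differentiated with the same operator and subtracted, so detection
    operates on pursuit residuals and catch-up saccades stand out.

    Event amplitude is the displacement from just before onset to just
    after offset (a 3-sample guard band compensates threshold trimming of
    the saccade's slow tails).
    """
    dt = 1.0 / SAMPLE_HZ
    vx = _velocity(trace.az, dt)
    vy = _velocity(trace.el, dt)
    if target is not None:
        tgt = np.asarray(target, dtype=float)
        if tgt.ndim == 1:
            vy = vy - _velocity(tgt, dt)
        else:
            vx = vx - _velocity(tgt[0], dt)
            vy = vy - _velocity(tgt[1], dt)
    eta_x = lam * _median_sd(vx)
    eta_y = lam * _median_sd(vy)
    crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
    events: list[SaccadeEvent] = []
    min_len = int(round(min_dur_ms * SAMPLE_HZ / 1000.0))
    pad = 3
    i = 0
    n = crit.size
    while i < n:
        if crit[i]:
            j = i
            while j < n and crit[j]:
                j += 1
            if j - i >= min_len:
                a = max(i - pad, 0)
                b = min(j - 1 + pad, n - 1)
                dx = trace.az[b] - trace.az[a]
                dy = trace.el[b] - trace.el[a]
                events.append(
                    SaccadeEvent(
                        onset_ms=i * 1000.0 / SAMPLE_HZ,
                        offset_ms=(j - 1) * 1000.0 / SAMPLE_HZ,
                        amplitude=float(np.hypot(dx, dy)),
                        direction=float(np.arctan2(dy, dx)),
                    )
                )
            i = j
        else:
            i += 1
    return events


def saccade_stats(
    events: pd.DataFrame,
    n_direction_bins: int = 8,
    dependent: str = "amplitude",
):
    """Histograms and a two-way ANOVA over saccade events.

    Parameters
    ----------
    events:
        DataFrame with columns ``subject``, ``condition`` (a
        ConditionLabel or its value), ``amplitude`` (deg) and
        ``direction`` (radians).
    n_direction_bins:
        Number of polar bins for the direction histogram.
    dependent:
        ANOVA dependent variable: per-subject mean ``"amplitude"`` or
        saccade ``"count"`` per cell.

    Returns
    -------
    dict with ``direction_hist`` (counts per polar bin, per condition),
    ``amplitude_hist`` (counts per amplitude bin, per condition), and
    ``anova`` (statsmodels two-way ANOVA table over factors
    illusion-vs-control and saccade direction class), or ``anova=None``
    with a warning when a design cell is empty.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = events.copy()
    df["condition"] = df["condition"].map(
        lambda c: c.value if isinstance(c, ConditionLabel) else str(c)
    )
    illusion_names = {c.value for c in ILLUSION_CONDITIONS}
    df["illusion"] = np.where(df["condition"].isin(illusion_names), "illusion", "control")
    df["dir_class"] = np.where(np.cos(df["direction"]) >= 0, "rightward", "leftward")

    edges = np.linspace(-np.pi, np.pi, n_direction_bins + 1)
    direction_hist = {
        cond: np.histogram(np.angle(np.exp(1j * g["direction"])), bins=edges)[0]
        for cond, g in df.groupby("condition")
    }
    amp_edges = np.linspace(0, max(df["amplitude"].max(), 1e-6), 21)
    amplitude_hist = {
        cond: np.histogram(g["amplitude"], bins=amp_edges)[0]
        for cond, g in df.groupby("condition")
    }

    if dependent == "amplitude":
        cell = (
            df.groupby(["subject", "illusion", "dir_class"])["amplitude"]
            .mean()
            .reset_index(name="y")
        )
    elif dependent == "count":
        cell = (
            df.groupby(["subject", "illusion", "dir_class"])["amplitude"]
            .size()
            .reset_index(name="y")
        )
    else:
        raise ValueError("dependent must be 'amplitude' or 'count'")

    n_cells = cell.groupby(["illusion", "dir_class"]).size()
    anova = None
    if len(n_cells) < 4:
        warnings.warn("empty design cell; ANOVA skipped", stacklevel=2)
    else:
        model = ols("y ~ C(illusion) * C(dir_class)", data=cell).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    return {
        "direction_hist": direction_hist,
        "direction_bin_edges": edges,
        "amplitude_hist": amplitude_hist,
        "amplitude_bin_edges": amp_edges,
        "anova": anova,
    }


_SEGMENT_SOURCES = {
    "illusion": ILLUSION_CONDITIONS,
    "local_motion": frozenset({ConditionLabel.LOCAL_LR, ConditionLabel.LOCAL_RL}),
}


def segment_traversals(
    trace: EyeTrace,
    schedule: RunSchedule,
    spec: StimulusSpec | None = None,
    per_run: int = 6,
    segment: str = "illusion",
) -> list[EyeExemplar]:
    """Cut traversal-length exemplars out of one run's trace.

    For ``segment="illusion"`` (or ``"local_motion"``), one
    traversal-duration window is taken from the start of each matching
    block, up to ``per_run`` exemplars per run, each labeled by its
    block's condition.  For ``segment="fixation"`` the window is taken
    from the fixation block preceding each illusion block and labeled by
    that upcoming illusion condition (the trial's fixation portion).
    Each exemplar's feature vector is the azimuth and elevation samples
    concatenated (2 x traversal_duration x 1000 values).
    """
    spec = spec or StimulusSpec()
    win = int(round(spec.traversal_duration * SAMPLE_HZ))
    exemplars: list[EyeExemplar] = []
    if segment == "fixation":
        blocks = schedule.blocks
        sources = []
        for i, b in enumerate(blocks):
            if b.condition in ILLUSION_CONDITIONS and i > 0 and \
                    blocks[i - 1].condition is ConditionLabel.FIXATION:
                sources.append((blocks[i - 1], b.condition))
    elif segment in _SEGMENT_SOURCES:
        sources = [
            (b, b.condition)
            for b in schedule.stimulus_blocks()
            if b.condition in _SEGMENT_SOURCES[segment]
        ]
    else:
        raise ValueError(f"unknown segment {segment!r}")

    for block, label in sources[:per_run]:
        start = int(round(block.onset_s * SAMPLE_HZ))
        if start + win > trace.n_samples or win > block.duration_s * SAMPLE_HZ:
            warnings.warn("traversal window extends past block; dropped", stacklevel=2)
            continue
        feats = np.concatenate(
            [trace.az[start : start + win], trace.el[start : start + win]]
        )
        exemplars.append(EyeExemplar(feats, label, trace.run_id, segment))
    return exemplars


def _map_to_pair(labels: np.ndarray) -> tuple:
    pair = sorted(set(labels), key=str)
    if len(pair) != 2:
        raise ValueError(f"exactly two classes required, got {pair}")
    return tuple(pair)


def _svm_loro(features, labels, run_id, seed: int = 0) -> float:
    """Leave-one-run-out linear-SVM accuracy over exemplars."""
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    runs = np.unique(run_id)
    if runs.size < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    enc = {c: i for i, c in enumerate(_map_to_pair(labels))}
    y = np.array([enc[l] for l in labels])
    correct = total = 0
    for run in runs:
        test = run_id == run
        if len(set(y[test])) < 2:
            warnings.warn(f"run {run!r} missing one class; skipped", stacklevel=2)
            continue
        clf = make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=1.0, random_state=seed)
        )
        clf.fit(features[~test], y[~test])
        correct += int(np.sum(clf.predict(features[test]) == y[test]))
        total += int(test.sum())
    if total == 0:
        raise ValueError("no usable test folds")
    return correct / total


def eye_svm_decode(
    exemplars: list[EyeExemplar],
    n_perm: int = 1000,
    seed: int = 0,
) -> DecodingResult:
    """Linear-SVM decoding of eye-position exemplars with permutation null.

    Features are standardized on training folds; accuracy is computed by
    leave-one-run-out cross-validation, and the null by permuting exemplar
    labels within runs and repeating the full cross-validation.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable 95th percentile", stacklevel=2)
    features = np.stack([e.features for e in exemplars])
    labels = np.array([e.label for e in exemplars], dtype=object)
    run_id = np.array([e.run_id for e in exemplars])
    pair = _map_to_pair(labels)
    observed = _svm_loro(features, labels, run_id, seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = permute_labels_within_runs(labels, run_id, pair, rng)
        null[i] = _svm_loro(features, perm, run_id, seed)
    threshold = float(np.percentile(null, 95))
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return DecodingResult(
        accuracy=float(observed),
        null_accuracies=null,
        threshold_95=threshold,
        p_value=float(p),
        n_exemplars=len(exemplars),
    )
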