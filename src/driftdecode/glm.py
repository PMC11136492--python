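"""Two-stage GLM: FIR deconvolution of ROI responses, then per-voxel betas.

Stage 1 estimates each ROI's hemodynamic response to a 12 s block by
finite-impulse-response (FIR) deconvolution of the ROI-mean time series:
each condition group is modeled by 16 lagged indicator predictors spanning
the 24 s after block onset, and the system is solved by pseudoinverse.
Trials are grouped into two conditions (illusory drift vs control) and the
two deconvolved responses are averaged into a single per-ROI HRF.

Stage 2 builds a block design matrix in which each stimulus block is
modeled by that single HRF placed at the block onset (the deconvolved
response already characterises a full 12 s block, so no boxcar convolution
is applied), and estimates one amplitude (beta, percent signal) per voxel
per block by pseudoinverse.  Betas stacked across blocks and runs form the
m voxels x n blocks feature matrix for decoding, along with per-voxel R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import ConditionLabel, RunSchedule, ILLUSION_CONDITIONS
from .preprocess import VoxelTimeSeries, remove_drift

__all__ = [
    "HRF",
    "BetaMatrix",
    "canonical_block_hrf",
    "default_condition_groups",
    "deconvolve_fir",
    "estimate_roi_hrf",
    "block_design_matrix",
    "estimate_betas",
    "estimate_betas_session",
]

N_LAGS_DEFAULT = 16


@dataclass
class HRF:
    """Hemodynamic response to a 12 s block: amplitudes at TR spacing."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("HRF values must be a 1-D array")

    def __len__(self) -> int:
        return self.values.size


def canonical_block_hrf(tr: float = 1.5, n_points: int = N_LAGS_DEFAULT, peak: float = 1.0) -> HRF:
    """Canonical difference-of-gammas impulse response convolved with a
    12 s boxcar, sampled at TR spacing and scaled to a given peak (percent
    signal).  Used as simulation ground truth."""
    dt = 0.1
    t = np.arange(0, n_points * tr + 12.0, dt)
    from scipy.stats import gamma as gamma_dist

    impulse = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    boxcar = np.ones(int(round(12.0 / dt)))
    block = np.convolve(impulse, boxcar)[: t.size] * dt
    samples = block[(np.arange(n_points) * tr / dt).round().astype(int)]
    samples = samples / samples.max() * peak
    return HRF(samples, tr)


def default_condition_groups(schedule: RunSchedule) -> dict[str, frozenset]:
    """Group trials into illusory-drift vs control conditions for stage 1.

    Experiments 1/2 pair the illusion blocks against the no-illusion
    control; experiments 3/4 pair them against the local-motion controls.
    """
    present = {b.condition for b in schedule.stimulus_blocks()}
    illusion = frozenset(present & ILLUSION_CONDITIONS)
    control = frozenset(
        present - ILLUSION_CONDITIONS - {ConditionLabel.FIXATION}
    )
    groups = {}
    if illusion:
        groups["illusion"] = illusion
    if control:
        groups["control"] = control
    if not groups:
        raise ValueError("schedule contains no stimulus blocks to group")
    return groups


def _as_run_list(ts, schedule):
    if isinstance(ts, (list, tuple)):
        return list(zip(ts, schedule))
    return [(ts, schedule)]


def deconvolve_fir(
    roi_mean_ts,
    schedule,
    conditions: dict[str, frozenset] | None = None,
    n_lags: int = N_LAGS_DEFAULT,
    drift_cutoff_hz: float | None = 0.01,
) -> dict[str, HRF]:
    """FIR deconvolution of per-condition-group block responses.

    Parameters
    ----------
    roi_mean_ts:
        1-D ROI-mean percent-signal time course, or a list of them (one
        per run; runs are concatenated with one intercept column each).
    schedule:
        The matching RunSchedule or list of schedules.
    conditions:
        Mapping group name -> set of ConditionLabels.  Defaults to the
        illusion-vs-control grouping of the schedule's experiment.
    n_lags:
        Number of lagged indicator predictors per group (16 points at
        TR = 1.5 s span the 24 s after block onset).
    drift_cutoff_hz:
        The indicator columns have the same drift basis projected out as
        the high-pass preprocessing removes from the data, which keeps the
        deconvolution unbiased on filtered input; None disables this.

    Returns
    -------
    dict mapping group name to the deconvolved :class:`HRF`.
    """
    runs = _as_run_list(roi_mean_ts, schedule)
    tr = runs[0][1].tr
    if conditions is None:
        conditions = default_condition_groups(runs[0][1])
    names = list(conditions)

    rows = sum(sch.n_volumes for _, sch in runs)
    X = np.zeros((rows, n_lags * len(names) + len(runs)))
    y = np.zeros(rows)
    row0 = 0
    for run_i, (series, sch) in enumerate(runs):
        series = np.asarray(series, dtype=float).ravel()
        if series.size != sch.n_volumes:
            raise ValueError("time series length does not match schedule volumes")
        y[row0 : row0 + sch.n_volumes] = series
        for gi, name in enumerate(names):
            for block in sch.stimulus_blocks():
                if block.condition not in conditions[name]:
                    continue
                onset = sch.onset_volume(block)
                for lag in range(n_lags):
                    v = onset + lag
                    if v < sch.n_volumes:
                        X[row0 + v, gi * n_lags + lag] += 1.0
        X[row0 : row0 + sch.n_volumes, n_lags * len(names) + run_i] = 1.0
        row0 += sch.n_volumes

    if drift_cutoff_hz is not None:
        row0 = 0
        for _, sch in runs:
            seg = slice(row0, row0 + sch.n_volumes)
            X[seg, : n_lags * len(names)] = remove_drift(
                X[seg, : n_lags * len(names)], sch.tr, drift_cutoff_hz
            )
            row0 += sch.n_volumes

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which groups are involved in the collinearity
        bad = []
        for gi, name in enumerate(names):
            sub = np.delete(X, np.s_[gi * n_lags : (gi + 1) * n_lags], axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise np.linalg.LinAlgError(
            f"FIR predictor matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear condition groups: {bad or names}"
        )
    coef = np.linalg.pinv(X) @ y
    return {
        name: HRF(coef[gi * n_lags : (gi + 1) * n_lags], tr)
        for gi, name in enumerate(names)
    }


def estimate_roi_hrf(condition_hrfs) -> HRF:
    """Average the per-group deconvolved responses into one ROI HRF."""
    hrfs = list(condition_hrfs.values()) if isinstance(condition_hrfs, dict) else list(condition_hrfs)
    n = len(hrfs[0])
    if any(len(h) != n for h in hrfs):
        raise ValueError("HRFs must have equal length")
    return HRF(np.mean([h.values for h in hrfs], axis=0), hrfs[0].tr)


def block_design_matrix(schedule: RunSchedule, hrf: HRF) -> np.ndarray:
    """Design matrix with one column per stimulus block.

    Each column is the ROI HRF placed at the block's onset volume
    (truncated at the end of the run); fixation is the implicit baseline.
    """
    if abs(hrf.tr - schedule.tr) > 1e-9:
        raise ValueError("HRF sampling must match the schedule TR")
    blocks = schedule.stimulus_blocks()
    X = np.zeros((schedule.n_volumes, len(blocks)))
    for j, block in enumerate(blocks):
        onset = schedule.onset_volume(block)
        if abs(block.onset_s / schedule.tr - onset) > 1e-9:
            raise ValueError("block onset is not on the TR grid")
        n = min(len(hrf), schedule.n_volumes - onset)
        X[onset : onset + n, j] = hrf.values[:n]
    return X


@dataclass
class BetaMatrix:
    """Per-block response amplitudes: the decoding feature table.

    ``betas`` is m voxels x n blocks (percent signal); ``condition`` and
    ``run_id`` label the n block columns.  ``ss_res``/``ss_tot`` hold the
    per-voxel GLM residual and total sums of squares for each run, so that
    R² can be recomputed over any subset of runs (e.g. training folds
    only).  ``roi_labels`` carries the per-voxel ROI assignment.
    """

    betas: np.ndarray
    condition: np.ndarray
    run_id: np.ndarray
    ss_res: np.ndarray  # voxels x runs
    ss_tot: np.ndarray  # voxels x runs
    run_ids: np.ndarray  # unique run ids, column order of ss_*
    roi_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.run_id = np.asarray(self.run_id)
        if self.betas.shape[1] != self.condition.size:
            raise ValueError("one condition label per block column required")
        if any(c is ConditionLabel.FIXATION for c in self.condition):
            raise ValueError("BetaMatrix must not contain FIXATION columns")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.betas.shape[1]

    def r2(self, runs=None) -> np.ndarray:
        """Per-voxel R², over all runs or a subset (for fold-wise selection)."""
        if runs is None:
            cols = slice(None)
        else:
            cols = np.isin(self.run_ids, np.asarray(list(runs)))
        res = self.ss_res[:, cols].sum(axis=1)
        tot = self.ss_tot[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 1.0 - res / tot
        return np.where(tot > 0, out, 0.0)

    def subset_voxels(self, indices) -> "BetaMatrix":
        indices = np.asarray(indices)
        return BetaMatrix(
            self.betas[indices],
            self.condition,
            self.run_id,
            self.ss_res[indices],
            self.ss_tot[indices],
            self.run_ids,
            None if self.roi_labels is None else self.roi_labels[indices],
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("betas", data=self.betas)
            f.create_dataset(
                "condition",
                data=np.array(
                    [c.value if isinstance(c, ConditionLabel) else str(c) for c in self.condition],
                    dtype="S32",
                ),
            )
            f.create_dataset("run_id", data=np.asarray(self.run_id, dtype="S32"))
            f.create_dataset("ss_res", data=self.ss_res)
            f.create_dataset("ss_tot", data=self.ss_tot)
            f.create_dataset("run_ids", data=np.asarray(self.run_ids, dtype="S32"))
            if self.roi_labels is not None:
                f.create_dataset("roi_labels", data=np.asarray(self.roi_labels, dtype="S32"))

    @classmethod
    def from_hdf5(cls, path) -> "BetaMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            condition = np.array(
                [ConditionLabel(s.decode()) for s in f["condition"][()]], dtype=object
            )
            roi = None
            if "roi_labels" in f:
                roi = np.array([s.decode() for s in f["roi_labels"][()]])
            return cls(
                betas=f["betas"][()],
                condition=condition,
                run_id=np.array([s.decode() for s in f["run_id"][()]]),
                ss_res=f["ss_res"][()],
                ss_tot=f["ss_tot"][()],
                run_ids=np.array([s.decode() for s in f["run_ids"][()]]),
                roi_labels=roi,
            )

    def to_tsv(self, path) -> None:
        """Write the block table (run, condition) plus betas as TSV."""
        with open(path, "w") as fh:
            fh.write("run_id\tcondition\t")
            fh.write("\t".join(f"v{i}" for i in range(self.n_voxels)))
            fh.write("\n")
            for j in range(self.n_blocks):
                cond = self.condition[j]
                cond = cond.value if isinstance(cond, ConditionLabel) else cond
                vals = "\t".join(f"{x:.6g}" for x in self.betas[:, j])
                fh.write(f"{self.run_id[j]}\t{cond}\t{vals}\n")


def estimate_betas(
    ts: VoxelTimeSeries,
    design: np.ndarray,
    schedule: RunSchedule,
    drift_cutoff_hz: float | None = 0.01,
) -> BetaMatrix:
    """Per-voxel block amplitudes by pseudoinverse of the block design.

    The same drift basis removed from the data by the high-pass stage is
    projected out of the design columns (keeping amplitude estimates
    unbiased on filtered input), and a run intercept is included in the
    fit (and discarded).  R² is the fraction of (mean-removed) variance
    explained by the block regressors.
    """
    if ts.units != "percent":
        raise ValueError("estimate_betas expects percent-signal input")
    if design.shape[0] != ts.n_volumes:
        raise ValueError("design rows must match number of volumes")
    if drift_cutoff_hz is not None:
        design = remove_drift(design, ts.tr, drift_cutoff_hz)
    X = np.column_stack([design, np.ones(design.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("block design matrix is rank deficient")
    coefs = (np.linalg.pinv(X) @ ts.data.T).T  # voxels x (blocks + 1)
    betas = coefs[:, :-1]
    fitted = coefs @ X.T
    resid = ts.data - fitted
    ss_res = (resid**2).sum(axis=1)
    centered = ts.data - ts.data.mean(axis=1, keepdims=True)
    ss_tot = (centered**2).sum(axis=1)
    blocks = schedule.stimulus_blocks()
    return BetaMatrix(
        betas=betas,
        condition=np.array([b.condition for b in blocks], dtype=object),
        run_id=np.array([ts.run_id] * len(blocks)),
        ss_res=ss_res[:, None],
        ss_tot=ss_tot[:, None],
        run_ids=np.array([ts.run_id]),
        roi_labels=ts.roi_labels,
    )


def estimate_betas_session(
    runs: list[VoxelTimeSeries],
    schedules: list[RunSchedule],
    hrf: HRF,
) -> BetaMatrix:
    """Estimate betas run by run and stack blocks across runs."""
    parts = [
        estimate_betas(ts, block_design_matrix(sch, hrf), sch)
        for ts, sch in zip(runs, schedules)
    ]
    return BetaMatrix(
        betas=np.hstack([p.betas for p in parts]),
        condition=np.concatenate([p.condition for p in parts]),
        run_id=np.concatenate([p.run_id for p in parts]),
        ss_res=np.hstack([p.ss_res for p in parts]),
        ss_tot=np.hstack([p.ss_tot for p in parts]),
        run_ids=np.concatenate([p.run_ids for p in parts]),
        roi_labels=parts[0].roi_labels,
    )
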