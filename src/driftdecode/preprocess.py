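"""Voxel time-series container and minimal fMRI preprocessing.

The pipeline operates on percent-signal-change time series: each voxel is
divided by its temporal mean and expressed as percent modulation about
zero, then high-pass filtered at 0.01 Hz to remove scanner drift.  The
18 s and 24 s task periodicities sit well inside the passband.

The high-pass stage is realized as projection removal of a discrete-cosine
basis below the cutoff (plus the constant), rather than an IIR filter, to
avoid edge transients on short (288 s) runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "VoxelTimeSeries",
    "to_percent_signal",
    "highpass_filter",
    "drift_basis",
    "remove_drift",
    "average_localizer_runs",
]


@dataclass
class VoxelTimeSeries:
    """A voxels x volumes data matrix with acquisition metadata.

    ``units`` is "raw" (arbitrary scanner intensity) or "percent"
    (percent modulation about zero); every stage checks it.
    ``roi_labels`` assigns each voxel (row) to a named ROI.
    """

    data: np.ndarray
    tr: float
    run_id: int | str
    roi_labels: np.ndarray
    units: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be voxels x volumes")
        if self.roi_labels.shape[0] != self.data.shape[0]:
            raise ValueError("roi_labels length must match number of voxels")
        if self.units not in ("raw", "percent"):
            raise ValueError(f"unknown units {self.units!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def roi_indices(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.roi_labels == roi)

    def roi_mean(self, roi: str | None = None) -> np.ndarray:
        """Mean time course across voxels (optionally of one ROI)."""
        if roi is None:
            return self.data.mean(axis=0)
        idx = self.roi_indices(roi)
        if idx.size == 0:
            raise ValueError(f"no voxels labeled {roi!r}")
        return self.data[idx].mean(axis=0)

    # -- serialization -----------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset(
                "roi_labels", data=np.asarray(self.roi_labels, dtype="S32")
            )
            f.attrs["tr"] = self.tr
            f.attrs["run_id"] = str(self.run_id)
            f.attrs["units"] = self.units

    @classmethod
    def from_hdf5(cls, path) -> "VoxelTimeSeries":
        with h5py.File(path, "r") as f:
            labels = np.array([s.decode() for s in f["roi_labels"][()]])
            return cls(
                data=f["data"][()],
                tr=float(f.attrs["tr"]),
                run_id=f.attrs["run_id"],
                roi_labels=labels,
                units=str(f.attrs["units"]),
            )


def to_percent_signal(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Convert raw intensities to percent modulation about zero.

    Each voxel is divided by its temporal mean: out = (x/mean - 1) * 100.
    The output has exactly zero temporal mean per voxel.

    Raises
    ------
    ValueError
        If the input is already in percent units, or any voxel has a
        non-positive mean (naming the offending voxels).
    """
    if ts.units != "raw":
        raise ValueError("to_percent_signal expects raw units")
    means = ts.data.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(f"voxels with non-positive mean cannot be converted: {bad.tolist()}")
    out = (ts.data / means[:, None] - 1.0) * 100.0
    return replace(ts, data=out, units="percent")


def _dct_basis(n: int, k_max: int) -> np.ndarray:
    """Orthonormal DCT-II basis vectors 0..k_max (columns), length n."""
    t = np.arange(n)
    cols = [np.full(n, 1.0 / np.sqrt(n))]
    for k in range(1, k_max + 1):
        v = np.cos(np.pi * k * (2 * t + 1) / (2 * n))
        cols.append(v / np.linalg.norm(v))
    return np.column_stack(cols)


def drift_basis(n: int, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Orthonormal drift basis (constant + DCT components below cutoff)."""
    k_max = int(np.floor(cutoff_hz * 2 * n * tr))
    return _dct_basis(n, k_max)


def remove_drift(M: np.ndarray, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Project the drift basis out of each column of a volumes x k matrix.

    Applying the same projection to GLM regressors as to the data keeps
    amplitude estimates unbiased after high-pass filtering.
    """
    basis = drift_basis(M.shape[0], tr, cutoff_hz)
    return M - basis @ (basis.T @ M)


def highpass_filter(ts: VoxelTimeSeries, cutoff_hz: float = 0.01) -> VoxelTimeSeries:
    """Remove low-frequency drift below ``cutoff_hz``.

    Projects out discrete-cosine regressors with frequencies below the
    cutoff (and the constant term), per voxel.  This is linear, has no
    edge transients, and leaves the 1/18 Hz and 1/24 Hz task frequencies
    essentially untouched.
    """
    if ts.units != "percent":
        raise ValueError("highpass_filter expects percent units")
    nyquist = 0.5 / ts.tr
    if cutoff_hz >= nyquist:
        raise ValueError("cutoff must be below the Nyquist frequency")
    out = remove_drift(ts.data.T, ts.tr, cutoff_hz).T
    return replace(ts, data=out)


def average_localizer_runs(
    runs: list[VoxelTimeSeries], cycle_volumes: int = 12
) -> VoxelTimeSeries:
    """Average localizer runs voxelwise and discard the first cycle.

    The first ``cycle_volumes`` volumes of the averaged series are dropped
    to exclude the initial transient, leaving 13 cycles of a 14-cycle,
    252 s localizer.
    """
    if not runs:
        raise ValueError("need at least one run")
    shape = runs[0].data.shape
    for r in runs[1:]:
        if r.data.shape != shape:
            raise ValueError("localizer runs must have equal shapes")
    mean = np.mean([r.data for r in runs], axis=0)
    return replace(runs[0], data=mean[:, cycle_volumes:], run_id="localizer_avg")
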