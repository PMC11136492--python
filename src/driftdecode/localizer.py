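"""Phase-encoded localizer analysis: cosine fits and voxel selection.

Both localizers alternate 9 s on / 9 s off, so responsive voxels modulate
at an 18 s period (12 volumes at TR = 1.5 s).  Each voxel's time course is
fit with a cosine at that period; the voxel is assigned the correlation
coefficient (r) between its series and the best-fitting cosine, and the
cosine's phase.  Voxels with r > 0.2 count as active; a phase window can
additionally restrict the selection to voxels responding in phase with
stimulus (or pursuit) onset, allowing for hemodynamic delay.

The fit is a closed-form projection onto the sine/cosine pair at the task
frequency (the first Fourier coefficient of the cycle-locked series), not
an iterative fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import VoxelTimeSeries

__all__ = ["PhaseMap", "VoxelSelection", "cosine_fit", "select_voxels",
           "expected_onset_phase"]



@dataclass
class PhaseMap:
    """Per-voxel cosine-fit statistics for one localizer."""

    r: np.ndarray
    phase: np.ndarray  # radians in [0, 2pi)
    amplitude: np.ndarray
    period_s: float

    @property
    def phase_cycles(self) -> np.ndarray:
        """Phase expressed as a fraction of the cycle."""
        return self.phase / (2 * np.pi)

    def to_tsv(self, path, selected: np.ndarray | None = None) -> None:
        with open(path, "w") as fh:
            cols = "voxel_index\tr\tphase\tamplitude"
            if selected is not None:
                cols += "\tselected"
            fh.write(cols + "\n")
            for i in range(self.r.size):
                row = f"{i}\t{self.r[i]:.6g}\t{self.phase[i]:.6g}\t{self.amplitude[i]:.6g}"
                if selected is not None:
                    row += f"\t{int(i in set(np.atleast_1d(selected)))}"
                fh.write(row + "\n")


@dataclass
class VoxelSelection:
    """A set of voxel indices chosen by a localizer criterion."""

    indices: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=int))

    def __len__(self) -> int:
        return self.indices.size

    def intersect(self, other: "VoxelSelection") -> np.ndarray:
        return np.intersect1d(self.indices, other.indices)


def cosine_fit(ts: VoxelTimeSeries, period_s: float = 18.0) -> PhaseMap:
    """Fit each voxel's series with ``A * cos(2*pi*t/period + phi)``.

    Works on the averaged, first-cycle-discarded localizer series.  Returns
    per-voxel r (correlation between the series and the fitted cosine),
    phase phi in [0, 2pi), and amplitude A.
    """
    n = ts.n_volumes
    if n * ts.tr < period_s:
        raise ValueError("series shorter than one period")
    t = np.arange(n) * ts.tr
    w = 2 * np.pi / period_s
    c, s = np.cos(w * t), np.sin(w * t)
    # remove the mean so the projection is onto the zero-mean harmonics
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    a = 2.0 / n * (x @ c)
    b = 2.0 / n * (x @ s)
    amplitude = np.hypot(a, b)
    # x ~ a*cos + b*sin = A*cos(wt + phi) with a = A cos(phi), b = -A sin(phi)
    phase = np.mod(np.arctan2(-b, a), 2 * np.pi)
    fitted = a[:, None] * c + b[:, None] * s
    x_norm = np.linalg.norm(x, axis=1)
    f_norm = np.linalg.norm(fitted, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * fitted).sum(axis=1) / (x_norm * f_norm)
    r = np.where((x_norm > 0) & (f_norm > 0), r, 0.0)
    return PhaseMap(r=r, phase=phase, amplitude=amplitude, period_s=period_s)


def expected_onset_phase(period_s: float = 18.0, hrf=None) -> float:
    """Reference phase (radians) of a response locked to block onset.

    A voxel driven by the on half-cycle responds with a hemodynamically
    delayed block response repeating at the localizer period; the phase of
    that periodic signal's fundamental is the Fourier phase of the
    (canonical, unless given) block HRF at the task frequency.  Selections
    "in phase with onset" are windows around this value.
    """
    if hrf is None:
        from .glm import canonical_block_hrf

        hrf = canonical_block_hrf()
    n_cycle = int(round(period_s / hrf.tr))
    wrapped = np.zeros(n_cycle)
    for i, v in enumerate(hrf.values):
        wrapped[i % n_cycle] += v
    t = np.arange(n_cycle) * hrf.tr
    w = 2 * np.pi / period_s
    x = wrapped - wrapped.mean()
    a = x @ np.cos(w * t)
    b = x @ np.sin(w * t)
    return float(np.mod(np.arctan2(-b, a), 2 * np.pi))


def _circdist(a, b):
    return np.abs(np.angle(np.exp(1j * (a - b))))


def select_voxels(
    phase_map: PhaseMap,
    r_threshold: float = 0.2,
    phase_window: float | None = None,
    exclude: VoxelSelection | None = None,
    source: str = "stimulus_localizer",
) -> VoxelSelection:
    """Select voxels active in the localizer.

    Voxels with r strictly greater than ``r_threshold`` are selected.  If
    ``phase_window`` (radians) is given, the selection is restricted to
    voxels whose phase lies within that circular distance of the expected
    hemodynamically delayed onset phase.  ``exclude`` removes a previous
    selection (e.g. stimulus-localizer voxels when building the
    pursuit-only control selection).
    """
    if not -1.0 <= r_threshold <= 1.0:
        raise ValueError("r_threshold must be a correlation in [-1, 1]")
    keep = phase_map.r > r_threshold
    if phase_window is not None:
        target = expected_onset_phase(phase_map.period_s)
        keep &= _circdist(phase_map.phase, target) <= phase_window
    idx = np.flatnonzero(keep)
    if exclude is not None:
        idx = np.setdiff1d(idx, exclude.indices)
    if idx.size == 0:
        warnings.warn("localizer selection is empty", stacklevel=2)
    return VoxelSelection(indices=idx, source=source)
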