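"""Signal-to-concentration conversion for dynamic contrast-enhanced MRI.

Breast DCE-MRI acquired at high spatial but low (~1 min) temporal resolution
samples only the decay phase of the contrast bolus, where gadolinium
concentrations in both tumor and artery stay low (< 2 mM Gd-DOTA).  In that
regime signal enhancement is assumed proportional to concentration, so the
relative concentration is simply the baseline-subtracted signal intensity::

    C(t) = R * (IS(t) - IS(baseline))

with a single amplitude constant ``R`` shared by tissue and artery.  Because
the Tofts model only involves the ratio structure of tissue versus plasma
concentration, ``R`` cancels in the fitted parameters and is fixed to 1
throughout the package; concentrations are therefore in *relative* units of
``R * (signal units)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DceSeries",
    "Roi",
    "ConcentrationCurve",
    "roi_mean_signal",
    "signal_to_concentration",
    "SignalToConcentration",
]


@dataclass
class DceSeries:
    """A 4D dynamic contrast-enhanced series.

    Parameters
    ----------
    signal : ndarray, shape (nx, ny, nz, nt)
        Non-negative signal intensity in arbitrary scanner units.
    frame_times : array-like of float
        Acquisition time of each frame in minutes, strictly increasing.
        The first frame is pre-contrast.
    voxel_spacing : tuple of float
        Voxel size in mm (x, y, z).
    baseline_frames : int
        Number of pre-contrast frames (>= 1).
    """

    signal: np.ndarray
    frame_times: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    baseline_frames: int = 1

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D (x, y, z, t), got ndim={self.signal.ndim}")
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.signal.shape[3]:
            raise ValueError("frame_times length must match the number of frames")
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal intensities must be non-negative")
        if not 1 <= self.baseline_frames < len(self.frame_times):
            raise ValueError("baseline_frames must be >= 1 and leave post-contrast frames")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class Roi:
    """A voxel region of interest given as integer (x, y, z) indices."""

    voxel_indices: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        idx = np.atleast_2d(np.asarray(self.voxel_indices, dtype=int))
        if idx.size == 0:
            raise ValueError("ROI must contain at least one voxel")
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("voxel_indices must have shape (n, 3)")
        self.voxel_indices = idx

    def __len__(self) -> int:
        return len(self.voxel_indices)

    def validate_for(self, series: DceSeries) -> None:
        """Raise ValueError if any voxel falls outside the series grid."""
        shape = np.asarray(series.grid_shape)
        idx = self.voxel_indices
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValueError(f"ROI '{self.label}' has voxels outside the grid {tuple(shape)}")


@dataclass
class ConcentrationCurve:
    """Relative contrast-agent concentration over time (R = 1 units)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")


def roi_mean_signal(series: DceSeries, roi: Roi) -> np.ndarray:
    """Mean signal over the ROI voxels at each frame.

    Returns an array of length ``series.n_frames``.
    """
    roi.validate_for(series)
    x, y, z = roi.voxel_indices.T
    return series.signal[x, y, z, :].mean(axis=0)


def signal_to_concentration(
    signal_course: np.ndarray,
    baseline_frames: int = 1,
    times: np.ndarray | None = None,
) -> ConcentrationCurve:
    """Convert a signal-intensity time course to relative concentration.

    The concentration is the course minus the mean of the first
    ``baseline_frames`` values (unit amplitude constant).  Negative values
    after subtraction are retained: they are noise, and the model fit must
    tolerate them.

    Parameters
    ----------
    signal_course : array-like
        One signal value per frame.
    baseline_frames : int
        Number of pre-contrast frames averaged into the baseline (>= 1).
    times : array-like, optional
        Frame times in minutes; defaults to the frame indices.
    """
    course = np.asarray(signal_course, dtype=float)
    if course.ndim != 1:
        raise ValueError("signal_course must be 1D")
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    if len(course) <= baseline_frames:
        raise ValueError("need more frames than baseline_frames")
    baseline = course[:baseline_frames].mean()
    if times is None:
        times = np.arange(len(course), dtype=float)
    return ConcentrationCurve(times=times, values=course - baseline)


class SignalToConcentration(TransformerMixin, BaseEstimator):
    """Baseline-subtraction transformer for stacks of signal time courses.

    Operates row-wise on an ``(n_curves, n_frames)`` array: each row is
    reduced by the mean of its own first ``baseline_frames`` entries.  This
    is the linear low-concentration signal model with the amplitude constant
    fixed to 1.
    """

    def __init__(self, baseline_frames: int = 1):
        self.baseline_frames = baseline_frames

    def fit(self, X, y=None):
        X = self._check(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._check(X)
        baseline = X[:, : self.baseline_frames].mean(axis=1, keepdims=True)
        return X - baseline

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_curves, n_frames)")
        if self.baseline_frames < 1 or X.shape[1] <= self.baseline_frames:
            raise ValueError("need more frames than baseline_frames")
        return X
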