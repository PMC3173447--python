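"""Arterial input functions: population (Weinmann) model and ROI measurement.

The plasma concentration time course :math:`C_p(t)` drives the Tofts model.
Two routes are supported:

* **theoretical** — the Weinmann population biexponential decay

  .. math:: C_p(t) = D\\,(a_1 e^{-m_1 t} + a_2 e^{-m_2 t})

  with amplitudes ``a1 = 3.99``, ``a2 = 4.78`` kg/L, rates ``m1 = 0.144``,
  ``m2 = 0.0111`` min^-1 and injected dose ``D`` in mmol per kg body weight
  (default 0.1).  This describes the post-first-pass decay of plasma
  gadolinium; units are mmol/L.

* **measured** — mean signal of a 9-pixel in-plane square tracking the
  internal thoracic artery, converted to relative concentration by baseline
  subtraction.  Units are relative (amplitude constant R = 1); only relative
  parameter changes between two exams of the same patient are meaningful.

Injection happens immediately after the first (baseline) acquisition, so on
the frame clock the theoretical decay is conventionally started at the first
post-contrast frame time (the exact alignment is a configuration choice; see
``theoretical_aif_for_frames``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .concentration import DceSeries, signal_to_concentration

__all__ = [
    "WEINMANN_A1",
    "WEINMANN_A2",
    "WEINMANN_M1",
    "WEINMANN_M2",
    "DEFAULT_DOSE",
    "STANDARD_FRAME_TIMES",
    "Aif",
    "ArteryRoiTrack",
    "AifQualityWarning",
    "weinmann_aif",
    "theoretical_aif_for_frames",
    "measure_aif",
]

# Weinmann population constants for Gd chelates
WEINMANN_A1 = 3.99  # kg/L
WEINMANN_A2 = 4.78  # kg/L
WEINMANN_M1 = 0.144  # min^-1
WEINMANN_M2 = 0.0111  # min^-1
DEFAULT_DOSE = 0.1  # mmol per kg body weight

#: Acquisition times (min) of the 8-frame breast protocol this package targets.
STANDARD_FRAME_TIMES = np.array([0.0, 1.36, 2.47, 3.59, 5.10, 6.21, 7.32, 8.44])


class AifQualityWarning(UserWarning):
    """Measured artery curve shows no convincing enhancement."""


@dataclass
class Aif:
    """A plasma concentration curve with its provenance.

    ``kind`` is ``"theoretical"`` (Weinmann model, mmol/L, biexponential
    constants stored) or ``"measured"`` (relative units, baseline value 0).
    ``t0`` is the injection time on the frame clock: the analytic decay is
    evaluated at ``t - t0`` and is zero before it.
    """

    times: np.ndarray
    cp: np.ndarray
    kind: str
    dose: float | None = None
    a1: float | None = None
    a2: float | None = None
    m1: float | None = None
    m2: float | None = None
    t0: float = 0.0
    quality_warning: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape:
            raise ValueError("times and cp must have the same length")
        if self.kind not in ("measured", "theoretical"):
            raise ValueError("kind must be 'measured' or 'theoretical'")
        if self.kind == "theoretical":
            post = self.times > self.t0
            if np.any(self.cp[post] <= 0):
                raise ValueError("theoretical cp must be strictly positive after t0")
            if np.any(np.diff(self.cp[post]) >= 0):
                raise ValueError("theoretical cp must be strictly decreasing after t0")

    @property
    def is_analytic(self) -> bool:
        """True when biexponential constants are available for exact evaluation."""
        return None not in (self.dose, self.a1, self.a2, self.m1, self.m2)

    def cp_at(self, t: np.ndarray) -> np.ndarray:
        """Evaluate C_p at arbitrary times.

        Analytic for theoretical AIFs (zero before injection), linear
        interpolation of the samples otherwise.
        """
        t = np.asarray(t, dtype=float)
        if self.is_analytic:
            tau = t - self.t0
            out = self.dose * (
                self.a1 * np.exp(-self.m1 * np.maximum(tau, 0.0))
                + self.a2 * np.exp(-self.m2 * np.maximum(tau, 0.0))
            )
            return np.where(tau < 0, 0.0, out)
        if np.any(t > self.times[-1] + 1e-9) or np.any(t < self.times[0] - 1e-9):
            raise ValueError("requested times outside the measured AIF support")
        return np.interp(t, self.times, self.cp)


@dataclass
class ArteryRoiTrack:
    """Per-frame position of the 9-pixel artery square (in-plane)."""

    seed_center: tuple[int, int, int]
    centers: np.ndarray  # (n_frames, 3) int, (x, y, z) of the square center
    translations: np.ndarray  # (n_frames, 2) int in-plane shifts applied

    def square_indices(self, frame: int) -> np.ndarray:
        """The 9 (x, y, z) voxel indices of the square at a frame."""
        cx, cy, cz = self.centers[frame]
        dx, dy = np.meshgrid([-1, 0, 1], [-1, 0, 1], indexing="ij")
        return np.column_stack([(cx + dx).ravel(), (cy + dy).ravel(), np.full(9, cz)])


def weinmann_aif(
    dose: float = DEFAULT_DOSE,
    times: np.ndarray = STANDARD_FRAME_TIMES,
    a1: float = WEINMANN_A1,
    a2: float = WEINMANN_A2,
    m1: float = WEINMANN_M1,
    m2: float = WEINMANN_M2,
) -> Aif:
    """Weinmann biexponential population AIF evaluated at ``times``.

    ``times`` are minutes since injection (t = 0 at injection).  Returns
    plasma concentration in mmol/L.
    """
    times = np.asarray(times, dtype=float)
    if dose <= 0:
        raise ValueError("dose must be positive")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    cp = dose * (a1 * np.exp(-m1 * times) + a2 * np.exp(-m2 * times))
    return Aif(times=times, cp=cp, kind="theoretical", dose=dose, a1=a1, a2=a2, m1=m1, m2=m2, t0=0.0)


def theoretical_aif_for_frames(
    frame_times: np.ndarray,
    dose: float = DEFAULT_DOSE,
    offset: float | None = None,
) -> Aif:
    """Weinmann AIF aligned to an acquisition frame clock.

    The decay is started at ``offset`` minutes (default: the second frame
    time, i.e. the first post-contrast acquisition) and is zero before it,
    reflecting injection immediately after the baseline frame.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if offset is None:
        if len(frame_times) < 2:
            raise ValueError("need at least two frames to infer the injection offset")
        offset = float(frame_times[1])
    aif = weinmann_aif(dose=dose, times=np.maximum(frame_times - offset, 0.0))
    cp = np.where(frame_times < offset, 0.0, aif.cp)
    return Aif(
        times=frame_times, cp=cp, kind="theoretical",
        dose=dose, a1=aif.a1, a2=aif.a2, m1=aif.m1, m2=aif.m2, t0=offset,
    )


def measure_aif(
    series: DceSeries,
    seed_center: tuple[int, int, int],
    selection_frame: int = 1,
    translations: np.ndarray | None = None,
    enhancement_factor: float = 1.5,
) -> tuple[Aif, ArteryRoiTrack]:
    """Extract a measured AIF from a 9-pixel square in the artery.

    The square (seed pixel + its 8 in-plane neighbours, single slice) is
    defined at ``selection_frame`` and reproduced at every frame, optionally
    translated per frame by externally supplied integer in-plane shifts to
    compensate motion (mirroring the manual correction step).  The mean
    square signal per frame is converted to relative concentration by
    baseline subtraction.

    A quality warning is flagged (and emitted) when the post-contrast peak
    does not exceed ``enhancement_factor`` times the baseline standard
    deviation over the square — e.g. a mis-placed ROI on non-enhancing
    tissue.

    Returns
    -------
    (Aif, ArteryRoiTrack)
    """
    n_frames = series.n_frames
    seed = tuple(int(v) for v in seed_center)
    nx, ny, nz = series.grid_shape
    if not (1 <= seed[0] <= nx - 2 and 1 <= seed[1] <= ny - 2 and 0 <= seed[2] < nz):
        raise ValueError("seed_center must lie inside the grid with a 1-pixel in-plane margin")
    if not 0 <= selection_frame < n_frames:
        raise ValueError("selection_frame outside the series")

    if translations is None:
        translations = np.zeros((n_frames, 2), dtype=int)
    translations = np.asarray(translations, dtype=int)
    if translations.shape != (n_frames, 2):
        raise ValueError(f"translations must have shape ({n_frames}, 2)")

    centers = np.column_stack([
        seed[0] + translations[:, 0],
        seed[1] + translations[:, 1],
        np.full(n_frames, seed[2]),
    ])
    if (np.any(centers[:, 0] < 1) or np.any(centers[:, 0] > nx - 2)
            or np.any(centers[:, 1] < 1) or np.any(centers[:, 1] > ny - 2)):
        raise ValueError("artery square exits the grid after translation")

    track = ArteryRoiTrack(seed_center=seed, centers=centers, translations=translations)
    course = np.empty(n_frames)
    baseline_pixels = None
    for f in range(n_frames):
        idx = track.square_indices(f)
        pix = series.signal[idx[:, 0], idx[:, 1], idx[:, 2], f]
        course[f] = pix.mean()
        if f == 0:
            baseline_pixels = pix

    curve = signal_to_concentration(course, series.baseline_frames, times=series.frame_times)
    cp = curve.values.copy()
    cp[: series.baseline_frames] = 0.0  # baseline is exactly zero by construction

    baseline_sd = float(np.std(baseline_pixels))
    peak = float(cp[series.baseline_frames:].max(initial=-np.inf))
    flagged = peak <= enhancement_factor * baseline_sd
    if flagged:
        warnings.warn(
            "measured AIF shows no clear enhancement over baseline noise",
            AifQualityWarning,
            stacklevel=2,
        )
    aif = Aif(
        times=series.frame_times, cp=cp, kind="measured",
        t0=float(series.frame_times[series.baseline_frames]),  # decay-phase clock
        quality_warning=flagged,
    )
    return aif, track
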