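"""Synthetic DCE-MRI phantoms and patient cohorts with known ground truth.

Two generators make every pipeline stage testable without any acquisition:

``generate_phantom``
    A 4D digital phantom on the 8-frame, ~1.1-min breast protocol grid.
    Lesion voxels follow the Tofts model driven by the frame-aligned
    Weinmann input (known K^trans / V_e per sub-region); a thick artery
    (3x3 in-plane cross-section through all slices) carries the input
    function itself; everything sits on a constant baseline signal and is
    optionally corrupted by Rician (magnitude-MRI) or Gaussian noise whose
    sigma is expressed as a fraction of the peak artery signal.

``generate_cohort``
    Tabular patient records whose grade-conditional percent-change
    distributions mimic the structure seen clinically: complete responders
    (grade A) drop V_e by about -90%, partial responders (B) by about -75%,
    non-responders (C+D) are dispersed around -52% with occasional large
    increases.  Changes are drawn from shifted-scaled logistic distributions
    with a small heavy-tail mixture for outliers, truncated below at -100%.

Both are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aif import Aif, DEFAULT_DOSE, STANDARD_FRAME_TIMES, theoretical_aif_for_frames
from .concentration import DceSeries, Roi
from .response import PatientRecord
from .tofts import ParamMap, ToftsParams, tofts_forward_biexp

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "CohortConfig",
    "PhantomResult",
    "generate_phantom",
    "generate_cohort",
]


@dataclass
class LesionSpec:
    """A homogeneous spherical lesion sub-region with known kinetics."""

    center: tuple[int, int, int]
    radius: float
    ktrans: float
    ve: float


@dataclass
class PhantomConfig:
    """Geometry, kinetics and noise of the digital phantom."""

    grid_shape: tuple[int, int, int] = (24, 24, 6)
    frame_times: np.ndarray = field(default_factory=lambda: STANDARD_FRAME_TIMES.copy())
    lesions: list[LesionSpec] = field(
        default_factory=lambda: [LesionSpec(center=(14, 14, 3), radius=2.5, ktrans=0.2, ve=0.3)]
    )
    artery_center: tuple[int, int] = (3, 3)  # in-plane position of the vessel axis
    dose: float = DEFAULT_DOSE
    injection_offset: float | None = None  # default: first post-contrast frame time
    baseline: float = 100.0  # pre-contrast signal level (a.u.)
    signal_gain: float = 100.0  # signal units per mmol/L
    noise: str = "rician"  # "rician" | "gaussian"
    sigma: float = 0.0  # noise SD as a fraction of peak artery signal
    seed: int = 0

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.noise not in ("rician", "gaussian"):
            raise ValueError("noise must be 'rician' or 'gaussian'")


@dataclass
class PhantomResult:
    series: DceSeries
    truth: ParamMap
    aif: Aif
    rois: dict  # {"tumor": Roi, "artery": Roi}


def _lesion_voxels(shape, lesion: LesionSpec) -> np.ndarray:
    grid = np.indices(shape).reshape(3, -1).T
    d2 = ((grid - np.asarray(lesion.center)) ** 2).sum(axis=1)
    vox = grid[d2 <= lesion.radius**2]
    if len(vox) == 0:
        raise ValueError("lesion contains no voxels; enlarge the radius")
    return vox


def generate_phantom(config: PhantomConfig | None = None) -> PhantomResult:
    """Build a 4D series with known kinetic ground truth.

    Returns the series, the true parameter map over the lesion voxels, the
    generating (frame-aligned theoretical) AIF, and the tumor/artery ROIs.

    The returned AIF is expressed in the phantom's *signal* units (its
    amplitude absorbs ``signal_gain``, exploiting the model's linearity in
    dose).  Under the R = 1 convention this is exactly the input function a
    fit of the baseline-subtracted phantom signal should be driven by, so
    true parameters are recovered directly; it coincides with the measured
    AIF extracted from the noise-free artery at every frame.
    """
    cfg = config or PhantomConfig()
    shape = tuple(cfg.grid_shape)
    times = cfg.frame_times
    aif = theoretical_aif_for_frames(
        times, dose=cfg.dose * cfg.signal_gain, offset=cfg.injection_offset
    )

    signal = np.full(shape + (len(times),), cfg.baseline, dtype=float)
    nan = np.full(shape, np.nan)
    truth = ParamMap(
        ktrans=nan.copy(), ve=nan.copy(), rss=np.zeros(shape),
        converged=np.ones(shape, dtype=bool), mask=np.zeros(shape, dtype=bool),
    )

    # artery: 3x3 in-plane cross-section through every slice, carrying C_p
    ax, ay = cfg.artery_center
    nx, ny, nz = shape
    if not (1 <= ax <= nx - 2 and 1 <= ay <= ny - 2):
        raise ValueError("artery_center must leave a 1-pixel in-plane margin")
    adx, ady = np.meshgrid([-1, 0, 1], [-1, 0, 1], indexing="ij")
    artery_vox = np.array([
        (ax + i, ay + j, z) for i, j in zip(adx.ravel(), ady.ravel()) for z in range(nz)
    ])
    artery_set = {tuple(v) for v in artery_vox}
    signal[artery_vox[:, 0], artery_vox[:, 1], artery_vox[:, 2], :] += aif.cp

    tumor_vox = []
    for lesion in cfg.lesions:
        params = ToftsParams(lesion.ktrans, lesion.ve)
        ct = tofts_forward_biexp(
            params, dose=cfg.dose * cfg.signal_gain, eval_times=times, t0=aif.t0,
        ).values
        vox = _lesion_voxels(shape, lesion)
        for v in vox:
            if tuple(v) in artery_set:
                raise ValueError("lesion overlaps the artery; adjust the geometry")
            if truth.mask[tuple(v)]:
                raise ValueError("lesions overlap; adjust the geometry")
            truth.mask[tuple(v)] = True
            truth.ktrans[tuple(v)] = lesion.ktrans
            truth.ve[tuple(v)] = lesion.ve
        signal[vox[:, 0], vox[:, 1], vox[:, 2], :] += ct
        tumor_vox.append(vox)

    if cfg.sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        s = cfg.sigma * aif.cp.max()
        if cfg.noise == "gaussian":
            signal = signal + rng.normal(0.0, s, signal.shape)
            signal = np.clip(signal, 0.0, None)
        else:
            signal = np.sqrt(
                (signal + rng.normal(0.0, s, signal.shape)) ** 2
                + rng.normal(0.0, s, signal.shape) ** 2
            )

    series = DceSeries(signal=signal, frame_times=times)
    rois = {
        "tumor": Roi(np.vstack(tumor_vox), label="tumor"),
        "artery": Roi(artery_vox, label="artery"),
    }
    return PhantomResult(series=series, truth=truth, aif=aif, rois=rois)


@dataclass
class GroupChanges:
    """Location (median) and scale (standard deviation, percent) of a grade
    group's percent-change distributions; draws are logistic."""

    ve: float
    ktrans: float
    size: float
    scale_ve: float = 12.0
    scale_ktrans: float = 15.0
    scale_size: float = 20.0


@dataclass
class CohortConfig:
    """Sizes and grade-conditional change distributions of a synthetic cohort.

    Default group medians follow the clinically observed pattern for the
    measured-AIF changes (V_e about -90 / -75 / -52 for grades A / B / C+D);
    the theoretical-AIF changes are generated with weaker, partly inverted
    separation to mimic the poorer discrimination of a population input
    function.  A small mixture component (``heavy_tail_prob``) with an
    inflated scale produces occasional outliers such as large V_e increases
    in non-responders.
    """

    n_a: int = 6
    n_b: int = 7
    n_cd: int = 11
    measured: dict = field(default_factory=lambda: {
        "A": GroupChanges(ve=-90.0, ktrans=-94.0, size=-98.0),
        "B": GroupChanges(ve=-75.0, ktrans=-89.0, size=-73.0),
        "CD": GroupChanges(ve=-52.0, ktrans=-23.0, size=-72.0),
    })
    theoretical: dict = field(default_factory=lambda: {
        "A": GroupChanges(ve=-82.0, ktrans=-22.0, size=-98.0, scale_ve=18, scale_ktrans=40),
        "B": GroupChanges(ve=-68.0, ktrans=-94.0, size=-73.0, scale_ve=18, scale_ktrans=40),
        "CD": GroupChanges(ve=-50.0, ktrans=-85.0, size=-72.0, scale_ve=18, scale_ktrans=40),
    })
    heavy_tail_prob: float = 0.05
    heavy_tail_factor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_cd) < 1:
            raise ValueError("all group sizes must be >= 1")
        if not 0 <= self.heavy_tail_prob < 1:
            raise ValueError("heavy_tail_prob must be in [0, 1)")


_LOGISTIC_SD = np.pi / np.sqrt(3.0)  # SD of the unit-scale logistic


def _draw_change(rng, loc, scale, heavy_p, heavy_factor, floor=None):
    # scale is the group's standard deviation in percent; convert to the
    # logistic s-parameter
    s = scale / _LOGISTIC_SD * (heavy_factor if rng.random() < heavy_p else 1.0)
    v = rng.logistic(loc, s)
    if floor is not None:
        v = max(v, floor)
    return float(v)


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Draw a synthetic patient cohort, deterministic under the seed.

    Sataloff grades are assigned by group; clinical response is a crude
    size-based reading (CR below -95%, PR below -50%, else SD), mimicking
    the known imperfection of clinical assessment.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    records = []
    pid = 0
    groups = [("CD", cfg.n_cd), ("B", cfg.n_b), ("A", cfg.n_a)]
    for key, size in groups:
        meas = cfg.measured[key]
        theo = cfg.theoretical[key]
        for _ in range(size):
            pid += 1
            ve_m = _draw_change(rng, meas.ve, meas.scale_ve, cfg.heavy_tail_prob,
                                cfg.heavy_tail_factor, floor=-100.0)
            kt_m = _draw_change(rng, meas.ktrans, meas.scale_ktrans, cfg.heavy_tail_prob,
                                cfg.heavy_tail_factor, floor=-100.0)
            ve_t = _draw_change(rng, theo.ve, theo.scale_ve, cfg.heavy_tail_prob,
                                cfg.heavy_tail_factor, floor=-100.0)
            kt_t = _draw_change(rng, theo.ktrans, theo.scale_ktrans, cfg.heavy_tail_prob,
                                cfg.heavy_tail_factor, floor=-100.0)
            size_c = _draw_change(rng, meas.size, meas.scale_size, 0.0, 1.0, floor=-100.0)
            grade = key if key != "CD" else ("D" if rng.random() < 0.1 else "C")
            clinical = "CR" if size_c <= -95 else ("PR" if size_c <= -50 else "SD")
            records.append(PatientRecord(
                patient=pid,
                ktrans_change_measured=kt_m,
                ktrans_change_theoretical=kt_t,
                ve_change_measured=ve_m,
                ve_change_theoretical=ve_t,
                size_change=size_c,
                clinical=clinical,
                sataloff=grade,
            ))
    return records
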