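"""Reading and writing the standard on-disk formats.

4D series come in as NIfTI (.nii/.nii.gz) with frame times supplied in a
sidecar (JSON list/dict or two-column CSV of frame index -> minutes), since
NIfTI headers do not carry irregular DCE frame timing.  ROIs are 3D label
masks (NIfTI) or CSV voxel lists with 0-based (x, y, z) indices, x fastest.
Parameter maps are written back as one NIfTI volume per quantity plus a
per-voxel CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import Aif
from .concentration import DceSeries, Roi
from .tofts import ParamMap

__all__ = [
    "load_frame_times",
    "load_series",
    "load_roi_mask",
    "load_roi_csv",
    "save_param_map",
    "save_aif_csv",
    "load_aif_csv",
]


def load_frame_times(path: str | Path) -> np.ndarray:
    """Frame times in minutes from a JSON or CSV sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = [data[k] for k in sorted(data, key=lambda k: int(k))]
        return np.asarray(data, dtype=float)
    df = pd.read_csv(path)
    col = "time_min" if "time_min" in df.columns else df.columns[-1]
    return df[col].to_numpy(dtype=float)


def load_series(
    image_path: str | Path,
    times: str | Path | np.ndarray,
    baseline_frames: int = 1,
) -> DceSeries:
    """Load a 4D NIfTI series with its frame-time sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if isinstance(times, (str, Path)):
        times = load_frame_times(times)
    zooms = img.header.get_zooms()[:3]
    return DceSeries(
        signal=data,
        frame_times=np.asarray(times, dtype=float),
        voxel_spacing=tuple(float(z) for z in zooms),
        baseline_frames=baseline_frames,
    )


def load_roi_mask(path: str | Path, label: str = "tumor", value: int | None = None) -> Roi:
    """ROI from a 3D label-mask NIfTI (non-zero voxels, or a specific value)."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj)
    voxels = np.argwhere(mask == value) if value is not None else np.argwhere(mask != 0)
    return Roi(voxel_indices=voxels, label=label)


def load_roi_csv(path: str | Path, label: str = "tumor") -> Roi:
    """ROI from a CSV with columns x, y, z (0-based indices)."""
    df = pd.read_csv(path)
    return Roi(voxel_indices=df[["x", "y", "z"]].to_numpy(dtype=int), label=label)


def save_param_map(pm: ParamMap, out_dir: str | Path, affine: np.ndarray | None = None) -> None:
    """Write ktrans/ve/mask NIfTI volumes and a per-voxel CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    for name, arr in (("ktrans", pm.ktrans), ("ve", pm.ve), ("rss", pm.rss)):
        nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(out / f"{name}.nii.gz"))
    nib.save(nib.Nifti1Image(pm.mask.astype(np.uint8), affine), str(out / "mask.nii.gz"))
    vox = np.argwhere(pm.mask)
    pd.DataFrame({
        "x": vox[:, 0], "y": vox[:, 1], "z": vox[:, 2],
        "ktrans": pm.ktrans[pm.mask],
        "ve": pm.ve[pm.mask],
        "rss": pm.rss[pm.mask],
        "converged": pm.converged[pm.mask].astype(int),
    }).to_csv(out / "voxels.csv", index=False)


def save_aif_csv(aif: Aif, path: str | Path) -> None:
    """Write an AIF as two-column CSV (time_min, cp)."""
    pd.DataFrame({"time_min": aif.times, "cp": aif.cp}).to_csv(path, index=False)


def load_aif_csv(path: str | Path, kind: str = "measured") -> Aif:
    """Read a two-column AIF CSV back into an :class:`Aif`.

    The model clock ``t0`` is inferred as the time of the first non-zero
    sample (the first post-contrast frame); biexponential constants are not
    recoverable from samples, so the curve is used by interpolation.
    """
    df = pd.read_csv(path)
    times = df["time_min"].to_numpy(dtype=float)
    cp = df["cp"].to_numpy(dtype=float)
    nz = np.nonzero(cp)[0]
    t0 = float(times[nz[0]]) if len(nz) else 0.0
    return Aif(times=times, cp=cp, kind=kind, t0=t0)
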