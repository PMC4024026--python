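"""NIfTI volume I/O and curve export.

Volumes travel as NIfTI-1 with a diagonal affine built from the voxel size;
for 4D dynamic series the frame interval is stored in the header timing
slot (pixdim[4], time units seconds). All analysis runs on 0-based voxel
indices; world coordinates exist only through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .kinetics import EnhancementCurve

__all__ = ["VolumeMeta", "read_volume", "write_volume", "export_curves", "read_curves"]


@dataclass(frozen=True)
class VolumeMeta:
    voxel_size_mm: tuple[float, ...]
    frame_interval_s: float | None
    ndim: int


def write_volume(
    path,
    data: np.ndarray,
    voxel_size_mm=(1.0, 1.0, 1.0),
    frame_interval_s: float | None = None,
) -> None:
    """Write a 3D or 4D array as NIfTI-1, preserving dtype and grid."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise FormatError(f"only 3D/4D volumes are supported, got {data.ndim}D")
    affine = np.diag([*voxel_size_mm[:3], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(data.dtype)
    zooms = list(voxel_size_mm[:3])
    if data.ndim == 4:
        zooms.append(frame_interval_s if frame_interval_s is not None else 0.0)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume(path, expect_ndim: int | None = None) -> tuple[np.ndarray, VolumeMeta]:
    """Read a NIfTI volume; optionally enforce 3D vs 4D."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected a 3D/4D volume, got ndim={data.ndim}")
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise FormatError(f"{path}: expected ndim={expect_ndim}, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    frame_interval = float(zooms[3]) if data.ndim == 4 else None
    return data, VolumeMeta(tuple(float(z) for z in zooms[:3]), frame_interval, data.ndim)


def export_curves(curves: list[EnhancementCurve], path) -> None:
    """Write enhancement curves to CSV: one row per frame, one column per ROI."""
    if not curves:
        pd.DataFrame(columns=["time_s"]).to_csv(path, index=False)
        return
    times = curves[0].times_s
    for c in curves[1:]:
        if len(c.times_s) != len(times) or not np.array_equal(c.times_s, times):
            raise InputError("all curves must share one time axis")
    cols = {"time_s": times}
    for c in curves:
        cols[c.roi_name or f"roi{len(cols)}"] = c.si_rel_percent
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_curves(path) -> list[EnhancementCurve]:
    """Re-import curves written by :func:`export_curves`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    times = df["time_s"].to_numpy()
    return [
        EnhancementCurve(times, df[col].to_numpy(), col)
        for col in df.columns
        if col != "time_s"
    ]
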