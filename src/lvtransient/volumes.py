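"""Cavity-volume reconstruction from short-axis segmentation stacks.

Binary per-frame mask stacks are reduced to a left-ventricular (LV)
volume transient: per frame, slice cross-sectional areas are integrated
along the long axis with the trapezoidal rule; the resulting volume-time
samples are interpolated with a periodic cubic spline for all
slope-sensitive downstream computations.

Internal length unit is mm (areas mm^2, volumes mm^3); volumes are
reported in mL (1 mL = 1000 mm^3). Times are in ms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

MM3_PER_ML = 1000.0


class InputError(ValueError):
    """Raised on malformed inputs (non-binary masks, bad grids...)."""


@dataclass
class VolumeTransient:
    """LV cavity volume over one cardiac cycle.

    Parameters
    ----------
    trigger_times : array of float
        Frame trigger times in ms, strictly increasing, starting at 0.
    volumes : array of float
        Cavity volume per frame, in mL.
    rr_ms : float
        Cycle length (RR-interval) in ms; at least the last trigger time.
    patient_id : str
    """

    trigger_times: np.ndarray
    volumes: np.ndarray
    rr_ms: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.trigger_times.shape != self.volumes.shape:
            raise InputError("trigger_times and volumes must have equal length")
        if self.trigger_times.size < 10:
            raise InputError("a transient needs at least 10 frames")
        if self.trigger_times[0] != 0.0:
            raise InputError("trigger times must start at 0")
        if np.any(np.diff(self.trigger_times) <= 0):
            raise InputError("trigger times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise InputError("volumes must be non-negative")
        if self.rr_ms < self.trigger_times[-1]:
            raise InputError("rr_ms must cover the last trigger time")

    @property
    def n_frames(self) -> int:
        return int(self.trigger_times.size)


@dataclass
class SegmentationStack:
    """Per-frame binary LV-cavity masks on a regular short-axis grid.

    masks has shape (frames, slices, rows, cols); pixel_spacing is the
    in-plane (row, col) size in mm and slice_spacing the inter-slice
    distance in mm. Ground-truth per-frame volumes (mL), when known for
    a phantom, ride along in ``true_volumes_ml``.
    """

    masks: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_spacing: float
    trigger_times: np.ndarray
    rr_ms: float
    patient_id: str = ""
    true_volumes_ml: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 4:
            raise InputError("masks must be (frames, slices, rows, cols)")
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, (0, 1))):
            raise InputError("masks must be binary")
        if min(self.pixel_spacing) <= 0 or self.slice_spacing <= 0:
            raise InputError("spacings must be positive")
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.trigger_times.size != self.masks.shape[0]:
            raise InputError("one trigger time per frame required")


def frame_volumes_ml(stack: SegmentationStack) -> np.ndarray:
    """Per-frame cavity volume (mL) by trapezoidal slice integration.

    Per frame, each slice contributes its cavity cross-sectional area
    (pixel count x pixel area); volumes are the trapezoidal rule over
    slice positions: spacing * (A_1/2 + A_2 + ... + A_{n-1} + A_n/2).
    """
    px_area = stack.pixel_spacing[0] * stack.pixel_spacing[1]
    areas = stack.masks.sum(axis=(2, 3)) * px_area  # (frames, slices) mm^2
    vols_mm3 = np.trapezoid(areas, dx=stack.slice_spacing, axis=1)
    if np.any(areas.sum(axis=1) == 0):
        warnings.warn("frame(s) with empty masks: volume set to 0", stacklevel=2)
    return vols_mm3 / MM3_PER_ML


def integrate_cavity_volume(stack: SegmentationStack) -> VolumeTransient:
    """Turn a segmentation stack into a volume transient (one sample per
    frame at its trigger time); see :func:`frame_volumes_ml`."""
    return VolumeTransient(
        trigger_times=stack.trigger_times,
        volumes=frame_volumes_ml(stack),
        rr_ms=stack.rr_ms,
        patient_id=stack.patient_id,
    )


def periodic_spline(t: VolumeTransient) -> CubicSpline:
    """Periodic cubic spline through the transient samples over [0, RR].

    The cycle is closed by repeating the first sample at t = RR (the
    transient covers exactly one period). Raises InputError for fewer
    than 4 samples.
    """
    if t.n_frames < 4:
        raise InputError("periodic spline needs at least 4 samples")
    times = np.append(t.trigger_times, t.rr_ms)
    vols = np.append(t.volumes, t.volumes[0])
    return CubicSpline(times, vols, bc_type="periodic")


def resample_transient(t: VolumeTransient, upsample_factor: int = 10) -> VolumeTransient:
    """Resample onto a uniform dense grid of factor * n_frames points.

    Periodic cubic-spline interpolation over [0, rr_ms); knot values are
    reproduced exactly at the original trigger times.
    """
    if upsample_factor < 1:
        raise InputError("upsample_factor must be >= 1")
    spline = periodic_spline(t)
    n_out = upsample_factor * t.n_frames
    grid = np.arange(n_out) * (t.rr_ms / n_out)
    return VolumeTransient(
        trigger_times=grid,
        volumes=np.maximum(spline(grid), 0.0),
        rr_ms=t.rr_ms,
        patient_id=t.patient_id,
    )


def dense_grid_step_ms(t: VolumeTransient, upsample_factor: int = 10) -> float:
    """Spacing of the dense resampling grid, in ms."""
    return t.rr_ms / (upsample_factor * t.n_frames)


# ---------------------------------------------------------------- file I/O

def write_mask_stack(stack: SegmentationStack, nifti_path, sidecar_path=None) -> None:
    """Write masks as 4D NIfTI (x, y, z, t) plus a JSON timing sidecar."""
    import nibabel as nib

    arr = np.transpose(stack.masks, (3, 2, 1, 0)).astype(np.uint8)
    affine = np.diag([stack.pixel_spacing[1], stack.pixel_spacing[0],
                      stack.slice_spacing, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(nifti_path))
    if sidecar_path is not None:
        meta = {
            "patient_id": stack.patient_id,
            "trigger_times_ms": stack.trigger_times.tolist(),
            "rr_ms": stack.rr_ms,
            "pixel_spacing_mm": list(stack.pixel_spacing),
            "slice_spacing_mm": stack.slice_spacing,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_mask_stack(nifti_path, sidecar_path) -> SegmentationStack:
    """Read a 4D NIfTI mask volume with its JSON timing sidecar."""
    import nibabel as nib

    img = nib.load(str(nifti_path))
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    masks = np.transpose(np.asarray(img.dataobj), (3, 2, 1, 0))
    return SegmentationStack(
        masks=masks,
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        slice_spacing=meta["slice_spacing_mm"],
        trigger_times=np.asarray(meta["trigger_times_ms"], dtype=float),
        rr_ms=meta["rr_ms"],
        patient_id=meta.get("patient_id", ""),
    )


def write_transients_csv(transients: list[VolumeTransient], path) -> None:
    """Long-format CSV: patient_id, trigger_time_ms, volume_ml, rr_ms."""
    import pandas as pd

    rows = []
    for t in transients:
        rows.append(pd.DataFrame({
            "patient_id": t.patient_id,
            "trigger_time_ms": t.trigger_times,
            "volume_ml": t.volumes,
            "rr_ms": t.rr_ms,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_transients_csv(path) -> list[VolumeTransient]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("trigger_time_ms")
        out.append(VolumeTransient(
            trigger_times=grp["trigger_time_ms"].to_numpy(),
            volumes=grp["volume_ml"].to_numpy(),
            rr_ms=float(grp["rr_ms"].iloc[0]),
            patient_id=str(pid),
        ))
    return out
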