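"""4D perfusion-series containers, NIfTI IO, temporal smoothing and the
mirrored normal-tissue ROI construction.

A DSC-PWI acquisition is handled as a ``(t, s, r, c)`` intensity array: a
contrast bolus transiently darkens perfused tissue, so each voxel carries a
time-intensity curve I(t).  The lesion mask (LT) is an input (perfusion
deficit, segmented upstream); the contralateral normal-tissue mask (NT) is
obtained by reflecting LT across the left-right image midline.
Registration/motion correction is assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "PerfusionSeries", "RoiPair", "smooth_series", "mirror_roi",
    "read_series", "write_series", "read_mask", "write_mask",
]


@dataclass
class PerfusionSeries:
    """A 4D perfusion series: ``data[t, s, r, c]`` with voxel spacing in mm
    ordered (slice, row, col)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"series must be 4D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("series contains non-finite intensities")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class RoiPair:
    """Lesion-tissue and mirrored normal-tissue binary masks."""

    lt_mask: np.ndarray
    nt_mask: np.ndarray
    mirror_axis: int = 2          # column axis of the (s, r, c) volume

    def __post_init__(self):
        self.lt_mask = _as_binary(self.lt_mask)
        self.nt_mask = _as_binary(self.nt_mask)
        if self.lt_mask.shape != self.nt_mask.shape:
            raise ValueError("LT and NT masks differ in shape")
        if (self.lt_mask & self.nt_mask).any():
            raise ValueError("LT and NT masks overlap")
        if self.lt_mask.sum() != self.nt_mask.sum():
            raise ValueError("LT and NT voxel counts differ (not a mirror pair)")


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {m.shape}")
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask is not strictly binary: values {vals}")
    return m.astype(np.uint8)


def smooth_series(series: PerfusionSeries, passes: int = 3) -> PerfusionSeries:
    """Triple moving-average smoothing of every voxel's time curve.

    Three successive passes of a length-3 uniform (1x3) kernel along the
    time axis, equivalent to one pass of the 7-tap kernel
    (1,3,6,7,6,3,1)/27 in the interior.  Edges are replicate-padded so the
    curve length is preserved.
    """
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to smooth")
    out = series.data
    for _ in range(passes):
        out = ndimage.uniform_filter1d(out, size=3, axis=0, mode="nearest")
    return PerfusionSeries(data=out, spacing=series.spacing)


def mirror_roi(lt_mask: np.ndarray, axis: int = 2) -> np.ndarray:
    """Reflect the lesion mask across the image midline of ``axis``:
    voxel (s, r, c) maps to (s, r, W-1-c).  Raises if the reflected mask
    intersects the lesion (a midline-crossing lesion has no disjoint
    contralateral mirror)."""
    lt = _as_binary(lt_mask)
    if not lt.any():
        raise ValueError("lesion mask is empty")
    nt = np.flip(lt, axis=axis)
    if (nt & lt).any():
        raise ValueError("mirrored mask intersects the lesion "
                         "(lesion crosses the midline)")
    return nt


# ---------------------------------------------------------------------------
# NIfTI IO.  On disk the series is stored spatial-first, time-last
# ((s, r, c, t), the conventional NIfTI layout); in memory it is time-first.

def write_series(series: PerfusionSeries, path) -> None:
    affine = np.diag(list(series.spacing) + [1.0])
    img = nib.Nifti1Image(np.moveaxis(series.data, 0, -1), affine)
    nib.save(img, str(path))


def read_series(path) -> PerfusionSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return PerfusionSeries(data=np.moveaxis(data, -1, 0), spacing=spacing)


def write_mask(mask: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    m = _as_binary(mask)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(m.astype(np.uint8), affine), str(path))


def read_mask(path, expected_shape: tuple | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    m = _as_binary(data)
    if expected_shape is not None and m.shape != tuple(expected_shape):
        raise ValueError(f"{path}: mask shape {m.shape} does not match the "
                         f"series spatial shape {tuple(expected_shape)}")
    return m
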