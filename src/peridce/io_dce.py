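"""Reading, writing and cropping of 4D dynamic contrast-enhanced MRI data.

A dynamic series is held as a :class:`DceSeries`: a ``(t, z, y, x)`` intensity
array with voxel spacing in mm and the dynamic frame duration in seconds.
NIfTI volumes (single 4D file or one 3D file per time point) and read-only
DICOM series directories are supported.  Binary region masks travel as
:class:`VolumeMask` and round-trip through NIfTI with 0/1 voxel values.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import StructuralError, ValidationError

#: Dynamic frame duration of the acquisition protocol, seconds per frame.
DEFAULT_FRAME_DURATION = 58.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DceSeries:
    """A 4D DCE-MRI record: one pre-contrast plus >=1 post-contrast volumes.

    Parameters
    ----------
    data
        Intensity array indexed ``(t, z, y, x)`` in arbitrary scanner units.
    voxel_spacing
        ``(dz, dy, dx)`` in millimetres.
    frame_duration
        Seconds per dynamic frame.
    pre_contrast_index
        Index of the unenhanced frame (default 0).
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_duration: float = DEFAULT_FRAME_DURATION
    pre_contrast_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"series data must be 4D (t,z,y,x), got {self.data.ndim}D")
        if self.data.shape[0] < 2:
            raise ValidationError("a dynamic series needs at least 2 time points")
        if not np.all(np.isfinite(self.data.astype(float, copy=False))):
            raise ValidationError("series intensities must be finite")
        if np.min(self.data) < 0:
            raise ValidationError("series intensities must be non-negative")
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(v <= 0 for v in self.voxel_spacing):
            raise ValidationError("voxel_spacing must be three positive lengths (dz,dy,dx)")
        if self.frame_duration <= 0:
            raise ValidationError("frame_duration must be positive")
        if not 0 <= self.pre_contrast_index < self.data.shape[0]:
            raise ValidationError("pre_contrast_index out of range")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def times_minutes(self) -> np.ndarray:
        """Frame start times in minutes from the pre-contrast frame."""
        return np.arange(self.n_timepoints) * self.frame_duration / 60.0


@dataclass(frozen=True)
class RoiBox:
    """Rectangular ROI: half-open ``[lo, hi)`` index ranges on y and x.

    ``z_range=None`` replicates the rectangle across all slices, matching the
    workflow of drawing the box on the slice with the largest tumour area and
    stretching it through the stack.
    """

    y_range: tuple[int, int]
    x_range: tuple[int, int]
    z_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("y_range", "x_range", "z_range"):
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = rng
            if hi <= lo:
                raise ValidationError(f"{name} [{lo},{hi}) is empty")
            if lo < 0:
                raise ValidationError(f"{name} starts below 0")

    def slices(self, spatial_shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        nz, ny, nx = spatial_shape
        z = self.z_range or (0, nz)
        for (lo, hi), n, name in ((z, nz, "z"), (self.y_range, ny, "y"), (self.x_range, nx, "x")):
            if hi > n:
                raise ValidationError(f"{name}_range [{lo},{hi}) exceeds grid extent {n}")
        return slice(*z), slice(*self.y_range), slice(*self.x_range)


def compose_boxes(outer: RoiBox, inner: RoiBox, spatial_shape: tuple[int, int, int]) -> RoiBox:
    """Absolute box equivalent to cropping by *outer* then by *inner*."""
    oz, oy, ox = outer.slices(spatial_shape)

    def shift(rng, off):
        return (rng[0] + off, rng[1] + off)

    z = None
    if inner.z_range is not None or outer.z_range is not None:
        iz = inner.z_range or (0, oz.stop - oz.start)
        z = shift(iz, oz.start)
    return RoiBox(
        y_range=shift(inner.y_range, oy.start),
        x_range=shift(inner.x_range, ox.start),
        z_range=z,
    )


@dataclass
class VolumeMask:
    """Boolean 3D region aligned to a series grid."""

    grid: np.ndarray
    label: str = "mask"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValidationError("mask grid must be 3D (z,y,x)")
        if self.grid.dtype != bool:
            self.grid = self.grid.astype(bool)
        self.spacing = tuple(float(v) for v in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _natural_key(path: Path):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", path.name)]


def _nifti_to_tzyx(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    arr = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return arr, spacing


def _sidecar_frame_duration(path: Path) -> float | None:
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "frame_duration_seconds" in meta:
            return float(meta["frame_duration_seconds"])
    return None


def read_series(
    path,
    format: str | None = None,
    frame_duration: float | None = None,
    pre_contrast_index: int = 0,
) -> DceSeries:
    """Read a dynamic series from NIfTI (4D or per-frame files) or a DICOM dir.

    ``format`` is one of ``nifti4d``, ``nifti_list``, ``dicom_dir``; when
    omitted it is inferred from the path.  ``frame_duration`` overrides any
    value found in metadata; with neither present the protocol default of
    58.5 s is used.
    """
    if isinstance(path, (list, tuple)):
        paths = [Path(p) for p in path]
        return _read_nifti_list(paths, frame_duration, pre_contrast_index)
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such path: {path}")
    if format is None:
        if path.is_dir():
            format = "dicom_dir" if list(path.glob("*.dcm")) else "nifti_list"
        else:
            format = "nifti4d"
    if format == "nifti4d":
        img = nib.load(str(path))
        arr, spacing = _nifti_to_tzyx(img)
        if arr.ndim != 4:
            raise StructuralError(f"{path} is not a 4D NIfTI")
        data = arr.transpose(3, 2, 1, 0)
        fd = frame_duration or _sidecar_frame_duration(path)
        if fd is None:
            zooms = img.header.get_zooms()
            fd = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else DEFAULT_FRAME_DURATION
        return DceSeries(data, spacing, fd, pre_contrast_index)
    if format == "nifti_list":
        paths = sorted(path.glob("*.nii*"), key=_natural_key) if path.is_dir() else [path]
        return _read_nifti_list(paths, frame_duration, pre_contrast_index)
    if format == "dicom_dir":
        return _read_dicom_dir(path, frame_duration, pre_contrast_index)
    raise ValidationError(f"unknown format {format!r}")


def _read_nifti_list(paths: Sequence[Path], frame_duration, pre_contrast_index) -> DceSeries:
    if len(paths) < 2:
        raise ValidationError("a dynamic series needs at least 2 time points")
    frames = []
    spacing = None
    for p in paths:
        arr, sp = _nifti_to_tzyx(nib.load(str(p)))
        if arr.ndim != 3:
            raise StructuralError(f"{p} is not a 3D volume")
        if frames and arr.shape != frames[0].shape:
            raise StructuralError(
                f"frame shape mismatch: {p} has {arr.shape}, expected {frames[0].shape}"
            )
        frames.append(arr)
        spacing = spacing or sp
    data = np.stack([f.transpose(2, 1, 0) for f in frames])
    fd = frame_duration or _sidecar_frame_duration(paths[0]) or DEFAULT_FRAME_DURATION
    return DceSeries(data, spacing, fd, pre_contrast_index)


def _read_dicom_dir(path: Path, frame_duration, pre_contrast_index) -> DceSeries:
    import pydicom

    files = sorted(path.glob("*.dcm"))
    if not files:
        raise ValidationError(f"no DICOM files in {path}")
    by_time: dict[int, list] = {}
    for f in files:
        ds = pydicom.dcmread(str(f))
        t = int(getattr(ds, "TemporalPositionIdentifier", getattr(ds, "AcquisitionNumber", 1)))
        by_time.setdefault(t, []).append(ds)
    if len(by_time) < 2:
        raise ValidationError("a dynamic series needs at least 2 time points")
    frames = []
    spacing = None
    for t in sorted(by_time):
        slices = sorted(by_time[t], key=lambda d: int(d.InstanceNumber))
        vol = np.stack([d.pixel_array for d in slices])  # (z, y, x)
        if frames and vol.shape != frames[0].shape:
            raise StructuralError("frame shape mismatch between DICOM time points")
        frames.append(vol)
        if spacing is None:
            ds0 = slices[0]
            dy, dx = (float(v) for v in ds0.PixelSpacing)
            dz = float(getattr(ds0, "SliceThickness", 1.0))
            spacing = (dz, dy, dx)
    fd = frame_duration or DEFAULT_FRAME_DURATION
    return DceSeries(np.stack(frames), spacing, fd, pre_contrast_index)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def write_series(series: DceSeries, path) -> None:
    """Write a series as a single 4D NIfTI; frame duration goes in the 4th zoom."""
    arr = series.data.transpose(3, 2, 1, 0)  # (x, y, z, t)
    img = nib.Nifti1Image(arr, _affine(series.voxel_spacing))
    img.header.set_data_dtype(series.data.dtype)
    dz, dy, dx = series.voxel_spacing
    img.header.set_zooms((dx, dy, dz, series.frame_duration))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_mask(mask: VolumeMask, path) -> None:
    """Write a mask as a 0/1 uint8 NIfTI with spacing in the header."""
    arr = mask.grid.astype(np.uint8).transpose(2, 1, 0)
    img = nib.Nifti1Image(arr, _affine(mask.spacing))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def read_mask(path, reference: DceSeries | VolumeMask | None = None, label: str = "mask") -> VolumeMask:
    """Read a 0/1 NIfTI mask, optionally validating shape/spacing vs a reference."""
    arr, spacing = _nifti_to_tzyx(nib.load(str(path)))
    if arr.ndim != 3:
        raise StructuralError(f"{path} is not a 3D mask")
    mask = VolumeMask(arr.transpose(2, 1, 0) > 0, label=label, spacing=spacing,
                      provenance={"op": "read_mask", "path": str(path)})
    if reference is not None:
        ref_shape = reference.spatial_shape if isinstance(reference, DceSeries) else reference.grid.shape
        ref_spacing = reference.voxel_spacing if isinstance(reference, DceSeries) else reference.spacing
        if mask.grid.shape != tuple(ref_shape):
            raise ValidationError(
                f"mask shape {mask.grid.shape} does not match reference {tuple(ref_shape)}"
            )
        if not np.allclose(mask.spacing, ref_spacing, rtol=1e-4):
            raise ValidationError("mask spacing does not match reference spacing")
    return mask


# ---------------------------------------------------------------------------
# restructuring
# ---------------------------------------------------------------------------

def deinterleave(series: DceSeries) -> list[np.ndarray]:
    """Split the 4D record into one 3D volume per time point, order preserved."""
    return [series.data[t] for t in range(series.n_timepoints)]


def crop(series: DceSeries, box: RoiBox) -> DceSeries:
    """Crop every frame to the ROI box; the time axis is untouched."""
    sz, sy, sx = box.slices(series.spatial_shape)
    return DceSeries(
        series.data[:, sz, sy, sx],
        voxel_spacing=series.voxel_spacing,
        frame_duration=series.frame_duration,
        pre_contrast_index=series.pre_contrast_index,
    )
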