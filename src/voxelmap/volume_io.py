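"""Reading and writing CT volumes and label maps.

Volumes are held in ``(i, j, k) == (x, y, z)`` index order with ``z`` the
slice axis, 0-based indices, world coordinates in millimetres, and
axis-aligned spacing only.  Hounsfield units are kept as signed integers on
read; any clamping (e.g. the epicardial-fat rule) happens explicitly in
downstream stages, never at I/O time.

Supported formats: NIfTI (.nii / .nii.gz) read+write, DICOM series read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InputError

__all__ = ["CTVolume", "LabelGrid", "read_volume", "write_volume"]


@dataclass
class _Grid3D:
    """Shared geometry for value and label grids."""

    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be three positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise InputError(f"origin must have three components, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._array().shape

    def _array(self) -> np.ndarray:
        raise NotImplementedError

    def index_to_world(self, index) -> np.ndarray:
        """World mm coordinate of voxel index (i, j, k); accepts (N, 3) arrays."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Continuous voxel index of a world mm coordinate (inverse of index_to_world)."""
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class CTVolume(_Grid3D):
    """A 3D grid of CT attenuation values (HU) with mm spacing and origin."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int16))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InputError(f"volume must be 3D, got shape {self.values.shape}")

    def _array(self) -> np.ndarray:
        return self.values


@dataclass
class LabelGrid(_Grid3D):
    """A 3D grid of integer labels sharing geometry with a companion CTVolume."""

    labels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int16))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InputError(f"label grid must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer) and self.labels.dtype != bool:
            raise InputError(f"labels must be integer or boolean, got {self.labels.dtype}")

    def _array(self) -> np.ndarray:
        return self.labels


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path:
        A ``.nii``/``.nii.gz`` file or a directory of DICOM slices.
    format:
        ``"nifti"`` or ``"dicom_dir"``; inferred from *path* when omitted.

    Returns
    -------
    CTVolume
        HU values with spacing/origin taken from the file headers.  DICOM
        rescale slope/intercept is applied; integer HU are preserved.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")
    if format is None:
        format = "dicom_dir" if p.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(p)
    if format == "dicom_dir":
        return _read_dicom_dir(p)
    raise InputError(f"unknown format {format!r}; expected 'nifti' or 'dicom_dir'")


def _read_nifti(p: Path) -> CTVolume:
    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises several unrelated types
        raise InputError(f"could not read NIfTI file {p}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{p}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(spacing=tuple(float(z) for z in zooms), origin=origin, values=data)


def _read_dicom_dir(p: Path) -> CTVolume:
    import pydicom

    files = sorted(f for f in p.iterdir() if f.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, reports)
        if hasattr(ds, "PixelData"):
            slices.append((f, ds))
    if not slices:
        raise InputError(f"no DICOM image slices found in {p}")
    slices.sort(key=lambda fd: float(fd[1].ImagePositionPatient[2]))
    z = np.array([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    if len(z) > 1:
        steps = np.diff(z)
        if np.any(steps <= 0):
            dup = [str(slices[i + 1][0].name) for i in np.nonzero(steps <= 0)[0]]
            raise FormatError(f"{p}: duplicate or non-increasing slice positions at {dup}")
        if np.max(np.abs(steps - steps[0])) > 1e-3 * abs(steps[0]):
            bad = [str(slices[i + 1][0].name) for i in np.nonzero(np.abs(steps - steps[0]) > 1e-3 * abs(steps[0]))[0]]
            raise FormatError(f"{p}: inconsistent slice spacing; offending slices: {bad}")
        dz = float(steps[0])
    else:
        dz = float(getattr(slices[0][1], "SliceThickness", 1.0))
    first = slices[0][1]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (dy, dx) per DICOM
    planes = []
    for _, ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = arr * slope + intercept
        planes.append(np.round(hu).astype(np.int32).T)  # (rows, cols) -> (x, y)
    values = np.stack(planes, axis=-1)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return CTVolume(spacing=(col_sp, row_sp, dz), origin=origin, values=values)


def write_volume(vol: CTVolume | LabelGrid, path: str | os.PathLike, format: str = "nifti") -> None:
    """Write a volume or label grid to NIfTI, losslessly for integer grids."""
    if format != "nifti":
        raise InputError(f"unsupported output format {format!r}; only 'nifti' is supported")
    p = Path(path)
    if not p.parent.exists():
        raise InputError(f"output directory does not exist: {p.parent}")
    data = vol.values if isinstance(vol, CTVolume) else vol.labels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(p))
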