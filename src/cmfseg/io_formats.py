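"""Volume and mask I/O.

All stages of the pipeline operate on :class:`VolumeImage`, a 3-D scalar grid
in ``(z, y, x)`` axis order (slice = axial ``(y, x)`` plane) with voxel
spacing in millimetres.  Masks are :class:`BinaryMask` with values in
``{0, 1}`` exactly; any nonzero value in a file is binarized to 1 on read, so
``{0, 255}`` exports round-trip cleanly.

Supported formats: NIfTI (``.nii``/``.nii.gz``) through nibabel, read-only
DICOM series directories through pydicom, multi-page or per-slice TIFF stacks
through tifffile, and PNG slice export for figures.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VolumeImage:
    """3-D scalar image, axis order (z, y, x), spacing in mm per axis."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.spacing, self.intensity_range)


@dataclass
class BinaryMask:
    """3-D mask over {0, 1}, same grid as its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly {0, 1}; binarize first")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> "BinaryMask":
        """Binarize with the rule value > 0 -> 1 (idempotent)."""
        return cls((np.asarray(arr) > 0).astype(np.uint8), spacing)


_FORMATS = ("nifti", "dicom_series", "tiff_stack")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if path.is_dir():
        # directory of per-slice TIFFs or a DICOM series
        entries = sorted(os.listdir(path))
        if any(e.lower().endswith((".tif", ".tiff")) for e in entries):
            return "tiff_stack"
        return "dicom_series"
    raise ValueError(f"cannot infer format of {path}")


def read_volume(path, format: str | None = None, *, as_mask: bool = False):
    """Read a 3-D volume (or mask) from ``path``.

    Parameters
    ----------
    path : path-like
        File (NIfTI, multi-page TIFF) or directory (DICOM series, TIFF
        slices).
    format : {"nifti", "dicom_series", "tiff_stack"}, optional
        Inferred from the path when omitted.
    as_mask : bool
        Binarize (value > 0 -> 1) and return a :class:`BinaryMask`.

    Returns
    -------
    VolumeImage or BinaryMask
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")

    if fmt == "nifti":
        data, spacing = _read_nifti(path)
    elif fmt == "dicom_series":
        data, spacing = _read_dicom_series(path)
    else:
        data, spacing = _read_tiff(path)

    if data.ndim != 3:
        raise ValueError(f"{path} does not hold 3-D content (shape {data.shape})")
    if as_mask:
        return BinaryMask.from_array(data, spacing)
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing)


def _read_nifti(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    # nibabel array order is (x, y, z); internal order is (z, y, x)
    data = np.transpose(arr, (2, 1, 0)).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if any(s <= 0 for s in spacing):
        spacing = (1.0, 1.0, 1.0)
    return data, spacing


def _read_dicom_series(path: Path):
    import pydicom

    files = [path / f for f in sorted(os.listdir(path))
             if not f.startswith(".")]
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {path}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    shapes = {ds.pixel_array.shape for ds in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent DICOM series geometry: shapes {shapes}")
    data = np.stack([ds.pixel_array.astype(np.float64) for ds in slices])
    ds0 = slices[0]
    ps = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    spacing = (dz, float(ps[0]), float(ps[1]))
    return data, spacing


def _read_tiff(path: Path):
    import tifffile

    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"no TIFF slices in {path}")
        data = np.stack([tifffile.imread(str(f)) for f in files])
    else:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
    return data.astype(np.float64), (1.0, 1.0, 1.0)


def write_volume(vol, path, format: str | None = None) -> None:
    """Write a volume or mask; round-trips through :func:`read_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    data = vol.data
    spacing = getattr(vol, "spacing", (1.0, 1.0, 1.0))
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValueError(f"cannot write non-3-D content of shape {data.shape}")

    fmt = format
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith((".tif", ".tiff")):
            fmt = "tiff_stack"
        else:
            fmt = "tiff_stack" if path.suffix == "" else None
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
        nib.save(img, str(path))
    elif fmt == "tiff_stack":
        import tifffile

        if path.suffix == "":
            # per-slice stack with zero-padded indices
            path.mkdir(exist_ok=True)
            width = max(4, len(str(data.shape[0] - 1)))
            for i, sl in enumerate(data):
                tifffile.imwrite(str(path / f"slice_{i:0{width}d}.tif"),
                                 sl.astype(np.float32))
        else:
            tifffile.imwrite(str(path), data.astype(np.float32),
                             photometric="minisblack")
    else:
        raise ValueError(f"unsupported write format {fmt!r}")


def export_png_slice(vol, z: int, path) -> None:
    """Export one axial slice rescaled to 8 bit for figures."""
    import imageio.v3 as iio

    sl = np.asarray(vol.data[z], dtype=np.float64)
    lo, hi = float(sl.min()), float(sl.max())
    scaled = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo) * 255.0
    iio.imwrite(str(path), scaled.astype(np.uint8))
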