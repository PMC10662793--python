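"""Image input/output and intensity normalization.

All arrays in this package are indexed ``(row, col)`` for 2D images and
``(z, y, x)`` for volumes, 0-based. Point coordinates everywhere follow the
same convention. Intensities are normalized to ``[0, 1]`` by a linear
min--max map before any processing.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ImageFormatError(RuntimeError):
    """Raised when a file cannot be interpreted as a supported image."""


@dataclass
class IntensityImage:
    """A 2D image or 3D volume of real-valued intensities.

    Parameters
    ----------
    data:
        Rank-2 or rank-3 float array. After :func:`normalize_intensity`
        all values lie in ``[0, 1]``.
    spacing:
        Per-axis physical size of a pixel/voxel, in the array's axis order
        (``(z, y, x)`` for volumes). Defaults to 1 per axis.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D array, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing must have one entry per axis")

    @property
    def dims(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def as_image(obj) -> IntensityImage:
    """Coerce an array or IntensityImage into an IntensityImage."""
    if isinstance(obj, IntensityImage):
        return obj
    return IntensityImage(np.asarray(obj, dtype=float))


def normalize_intensity(img) -> IntensityImage:
    """Linearly map intensities onto ``[0, 1]``.

    A constant image maps to all zeros (it carries no structure, and this
    avoids a divide by zero). Non-finite values are rejected.
    """
    image = as_image(obj=img)
    data = image.data
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains NaN or Inf values")
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return IntensityImage(out, image.spacing)


def _read_dicom_file(path: Path):
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pragma: no cover - message path
        raise ImageFormatError(f"unreadable DICOM file: {path}") from exc
    return ds

def _dicom_pixel_array(ds) -> np.ndarray:
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _load_dicom_series(directory: Path) -> IntensityImage:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ImageFormatError(f"no files in DICOM directory: {directory}")
    datasets = [_read_dicom_file(p) for p in files]
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    slices = [_dicom_pixel_array(ds) for ds in datasets]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ImageFormatError(
            f"mixed slice shapes in DICOM series {directory}: {sorted(shapes)}"
        )
    volume = np.stack(slices, axis=0)
    ds0 = datasets[0]
    pixel_spacing = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    spacing = (dz, float(pixel_spacing[0]), float(pixel_spacing[1]))
    return IntensityImage(volume, spacing)


def _load_nifti(path: Path) -> IntensityImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    data = np.squeeze(data)
    if data.ndim == 3:
        # nibabel is (x, y, z); this package is (z, y, x)
        data = data.transpose(2, 1, 0)
        spacing = zooms[::-1]
    elif data.ndim == 2:
        spacing = zooms[::-1]
    else:
        raise ImageFormatError(f"unsupported NIfTI rank {data.ndim}: {path}")
    return IntensityImage(data, spacing)


def _load_flat(path: Path) -> IntensityImage:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path))).astype(float)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ImageFormatError(f"expected a 2D image in {path}, got shape {arr.shape}")
    return IntensityImage(arr)


_FLAT_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def load_image(path, format_hint: str | None = None) -> IntensityImage:
    """Read DICOM (file or series directory), NIfTI, or PNG/TIFF.

    Raw intensities are preserved (DICOM rescale slope/intercept applied);
    spacing is taken from metadata when present, else 1 per axis.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    hint = (format_hint or "").lower()
    if path.is_dir() or hint == "dicom-series":
        return _load_dicom_series(path)
    name = path.name.lower()
    if hint == "nifti" or name.endswith(".nii") or name.endswith(".nii.gz"):
        return _load_nifti(path)
    if hint == "dicom" or path.suffix.lower() in {".dcm", ".ima"}:
        ds = _read_dicom_file(path)
        return IntensityImage(_dicom_pixel_array(ds))
    if hint in {"png", "tiff", "tif"} or path.suffix.lower() in _FLAT_SUFFIXES:
        return _load_flat(path)
    raise ImageFormatError(f"unrecognized image format: {path}")


def save_mask(mask: np.ndarray, path, spacing=None) -> None:
    """Write a binary mask: PNG (2D, 0/255) or NIfTI (0/1)."""
    mask = np.asarray(mask).astype(bool)
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        arr = mask.astype(np.uint8)
        if arr.ndim == 3:
            arr = arr.transpose(2, 1, 0)
            zooms = (spacing or (1.0,) * 3)[::-1]
        else:
            zooms = (spacing or (1.0,) * 2)[::-1]
        affine = np.diag(list(zooms) + [1.0] * (4 - len(zooms)))
        nib.save(nib.Nifti1Image(arr, affine), str(path))
        return
    if path.suffix.lower() in _FLAT_SUFFIXES:
        if mask.ndim != 2:
            raise ValueError("PNG/TIFF masks must be 2D; use NIfTI for volumes")
        import imageio.v3 as iio

        iio.imwrite(str(path), (mask.astype(np.uint8) * 255))
        return
    raise ImageFormatError(f"unrecognized mask format: {path}")


def load_mask(path) -> np.ndarray:
    """Read a mask written by :func:`save_mask` back as a boolean array."""
    img = load_image(path)
    data = img.data
    if data.max() > 1:
        return data > (data.max() / 2.0)
    return data > 0.5


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=2)
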