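"""Readers and writers for images and masks (grayscale PNG and NIfTI-1).

Masks are encoded 0/255 in PNG and 0/1 uint8 in NIfTI; both round-trip
bit-exactly.  NIfTI pixel spacing is read into ``ImageSlice.spacing_mm``.
Arrays are row-major with the origin at the top-left, 0-based.
"""
from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import BsunetError
from .image import ImageSlice

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "extract_mid_slice"]

_PNG_EXTS = {".png"}


class IOFormatError(BsunetError):
    pass


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _load_nifti(path: Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = float(img.header.get_zooms()[0])
    if data.ndim == 3:
        import warnings
        warnings.warn(f"{path.name}: 3-D volume, taking first slice along "
                      "the last axis; use extract_mid_slice for explicit "
                      "selection")
        data = data[..., 0]
    if data.ndim != 2:
        raise IOFormatError(f"{path}: expected a 2-D (or 3-D) NIfTI image")
    return np.asarray(data, np.float64), spacing


def read_image(path, spacing_mm: float | None = None) -> ImageSlice:
    """Load a grayscale PNG (8/16-bit) or NIfTI image as float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data, sp = _load_nifti(path)
        lo, hi = data.min(), data.max()
        if hi > 1.0 or lo < 0.0:  # stored in raw units
            data = (data - lo) / (hi - lo) if hi > lo else data * 0.0
        return ImageSlice(data.astype(np.float32),
                          spacing_mm if spacing_mm is not None else sp)
    if path.suffix.lower() in _PNG_EXTS:
        img = Image.open(path)
        if img.mode not in ("L", "I", "I;16"):
            raise IOFormatError(
                f"{path}: only grayscale PNG supported, got mode {img.mode}")
        arr = np.asarray(img, np.float64)
        denom = 65535.0 if arr.max() > 255 else 255.0
        return ImageSlice((arr / denom).astype(np.float32),
                          spacing_mm if spacing_mm is not None else 1.5)
    raise IOFormatError(f"unsupported image format: {path.suffix!r}")


def write_image(image: ImageSlice, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag([image.spacing_mm, image.spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))
    elif path.suffix.lower() in _PNG_EXTS:
        arr = np.clip(np.round(image.data * 255.0), 0, 255).astype(np.uint8)
        _atomic_png(arr, path)
    else:
        raise IOFormatError(f"unsupported image format: {path.suffix!r}")


def read_mask(path) -> np.ndarray:
    """Load a binary mask (PNG 0/255 or NIfTI 0/1) as uint8 {0, 1}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data, _ = _load_nifti(path)
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise IOFormatError(f"{path}: mask values must be 0/1, got {vals}")
        return data.astype(np.uint8)
    if path.suffix.lower() in _PNG_EXTS:
        img = Image.open(path)
        if img.mode != "L":
            raise IOFormatError(
                f"{path}: only 8-bit grayscale mask PNG supported, got {img.mode}")
        arr = np.asarray(img)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 255))):
            raise IOFormatError(f"{path}: mask PNG values must be 0/255, got {vals}")
        return (arr > 0).astype(np.uint8)
    raise IOFormatError(f"unsupported mask format: {path.suffix!r}")


def write_mask(mask: np.ndarray, path, spacing_mm: float = 1.5) -> None:
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask, affine), str(path))
    elif path.suffix.lower() in _PNG_EXTS:
        _atomic_png(mask * 255, path)
    else:
        raise IOFormatError(f"unsupported mask format: {path.suffix!r}")


def _atomic_png(arr: np.ndarray, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(tmp, format="PNG")
    os.replace(tmp, path)


def extract_mid_slice(path, index: int) -> ImageSlice:
    """Explicitly select one sagittal slice of a 3-D NIfTI volume."""
    path = Path(path)
    if not _is_nifti(path):
        raise IOFormatError("mid-slice extraction requires a NIfTI volume")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOFormatError(f"{path}: expected a 3-D volume")
    if not (0 <= index < data.shape[-1]):
        raise IOFormatError(f"slice index {index} out of range {data.shape[-1]}")
    sl = np.asarray(data[..., index], np.float64)
    lo, hi = sl.min(), sl.max()
    if hi > lo:
        sl = (sl - lo) / (hi - lo)
    return ImageSlice(sl.astype(np.float32), float(img.header.get_zooms()[0]))
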