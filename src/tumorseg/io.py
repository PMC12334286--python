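"""Image and metadata IO: PNG/TIFF, DICOM pixel data + PixelSpacing, CSV sidecars."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .sample import MRISample, PixelSpacing


def write_png(path, array):
    """Write a [0,1] float image or a {0,1} mask as 8-bit PNG."""
    arr = np.asarray(array)
    if arr.dtype == np.uint8 and arr.max(initial=0) <= 1:
        arr = arr * 255
    elif arr.dtype != np.uint8:
        arr = np.clip(np.asarray(arr, dtype=float), 0.0, 1.0)
        arr = np.round(arr * 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF into a float [0,1] H x W x 3 array."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr, dtype=float)
    if arr.max(initial=0) > 1:
        arr = arr / 255.0
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] > 3:
        arr = arr[:, :, :3]
    return np.clip(arr, 0.0, 1.0)


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG; any value >= 128 counts as foreground."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr >= 128).astype(np.uint8) if arr.max(initial=0) > 1 else arr.astype(np.uint8)


def read_dicom_sample(path, sample_id=None) -> MRISample:
    """Read pixel data and the PixelSpacing tag (0028,0030) from a DICOM file."""
    import pydicom

    ds = pydicom.dcmread(Path(path))
    arr = ds.pixel_array.astype(float)
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    spacing = read_dicom_spacing(path, dataset=ds)
    mask = np.zeros(arr.shape[:2], dtype=np.uint8)
    return MRISample(arr, mask, spacing, sample_id or Path(path).stem)


def read_dicom_spacing(path, dataset=None) -> PixelSpacing:
    """Pixel spacing from DICOM metadata; DICOM orders it (row, column) =
    (y, x) spacing."""
    import pydicom

    ds = dataset if dataset is not None else pydicom.dcmread(Path(path), stop_before_pixels=True)
    if "PixelSpacing" not in ds:
        raise ValueError(f"DICOM file {path} has no PixelSpacing tag (0028,0030)")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    return PixelSpacing(sx=col_mm, sy=row_mm)


def read_spacing_csv(path) -> dict[str, PixelSpacing]:
    """Sidecar CSV with columns id, pixel_spacing_x_mm, pixel_spacing_y_mm."""
    import pandas as pd

    df = pd.read_csv(Path(path))
    return {
        str(r["id"]): PixelSpacing(float(r["pixel_spacing_x_mm"]), float(r["pixel_spacing_y_mm"]))
        for _, r in df.iterrows()
    }
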