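"""Tumor area quantification from a binary mask and pixel spacing.

The physical area of a segmented lesion is obtained in three steps:
the tumor pixel count N_P (sum of the binary mask), the physical area of one
pixel P_A = S_x * S_y in mm^2, and the lesion area = P_A * N_P.  Anisotropic
spacing (S_x != S_y) is fully supported.  By default every 1-pixel counts; a
minimum-blob-size filter is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sample import PixelSpacing


@dataclass(frozen=True)
class AreaResult:
    pixel_count: int
    pixel_area: float  # mm^2
    tumor_area: float  # mm^2
    sample_id: str


def count_tumor_pixels(mask) -> int:
    """N_P: the exact number of 1-valued pixels in a strictly binary mask."""
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary")
    return int(m.sum())


def pixel_area(spacing: PixelSpacing) -> float:
    """P_A = S_x * S_y, the physical footprint of one pixel in mm^2."""
    return spacing.sx * spacing.sy


def filter_small_blobs(mask, min_size: int) -> np.ndarray:
    """Remove connected components smaller than ``min_size`` pixels."""
    from scipy import ndimage

    labels, n = ndimage.label(np.asarray(mask) > 0)
    if n == 0:
        return np.zeros_like(mask, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labels, keep).astype(np.uint8)


def tumor_area(mask, spacing: PixelSpacing, sample_id: str = "",
               min_blob_size: int = 0) -> AreaResult:
    """Area = P_A * N_P in mm^2, with all intermediate quantities reported."""
    if min_blob_size > 0:
        mask = filter_small_blobs(mask, min_blob_size)
    n_p = count_tumor_pixels(mask)
    p_a = pixel_area(spacing)
    return AreaResult(pixel_count=n_p, pixel_area=p_a,
                      tumor_area=p_a * n_p, sample_id=sample_id)


def area_report(samples, min_blob_size: int = 0) -> pd.DataFrame:
    """One row per (mask, spacing, id) sample, ordered by id for longitudinal
    reading; columns: id, pixel_count, pixel_area_mm2, area_mm2."""
    samples = list(samples)
    if not samples:
        raise ValueError("area_report needs at least one sample")
    rows = []
    for mask, spacing, sample_id in samples:
        r = tumor_area(mask, spacing, sample_id, min_blob_size=min_blob_size)
        rows.append({
            "id": r.sample_id,
            "pixel_count": r.pixel_count,
            "pixel_area_mm2": r.pixel_area,
            "area_mm2": r.tumor_area,
        })
    return pd.DataFrame(rows).sort_values("id", kind="stable").reset_index(drop=True)
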