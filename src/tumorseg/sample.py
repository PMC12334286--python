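"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PixelSpacing:
    """Physical size of one pixel, in millimetres per pixel along x and y."""

    sx: float
    sy: float

    def __post_init__(self):
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("pixel spacing must be positive in both axes")


@dataclass
class MRISample:
    """One 2-D slice: 3-channel intensity grid in [0,1], binary mask,
    physical pixel spacing, and an identifier."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray   # (H, W) in {0, 1}
    spacing: PixelSpacing
    id: str

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("image and mask must share spatial dimensions")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
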