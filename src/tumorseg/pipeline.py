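"""Preprocessing: intensity normalization, resizing, splitting, augmentation.

Normalization is the per-image min-max rescale I_N = (I - min I)/(max I - min I).
Resizing uses nearest-neighbor interpolation and rescales the pixel spacing so
the physical extent of the slice is preserved.  Two augmentation schemes are
provided: a fixed scheme (rotations of 45/90/135 degrees plus axis flips) and
a random scheme (rotation factor 0.2, shift 0.05, zoom 0.05 with
nearest-neighbor fill), the latter being the default for training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .sample import MRISample, PixelSpacing

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    seed: int = 0

    def validate(self):
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f < 0 for f in fracs):
            raise ValueError("split fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        return self


@dataclass(frozen=True)
class AugmentSpec:
    """Augmentation parameters.

    ``random_rotation_factor`` follows the dimensionless convention of common
    augmentation layers: a factor f draws a rotation uniformly from
    [-f*180, +f*180] degrees.  Shift and zoom are fractions of the image size.
    """

    fixed_rotations: tuple[float, ...] = (45.0, 90.0, 135.0)
    allow_flips: bool = True
    random_rotation_factor: float = 0.2
    shift_fraction: float = 0.05
    zoom_fraction: float = 0.05
    fill_mode: str = "nearest"
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.shift_fraction < 1.0:
            raise ValueError("shift_fraction must lie in [0, 1)")
        if not 0.0 <= self.zoom_fraction < 1.0:
            raise ValueError("zoom_fraction must lie in [0, 1)")
        for r in self.fixed_rotations:
            if not 0.0 < r < 360.0:
                raise ValueError("fixed rotations must lie in (0, 360)")
        if self.fill_mode != "nearest":
            raise ValueError("only nearest fill mode is supported")
        return self


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_intensity(raw_image) -> np.ndarray:
    """Min-max rescale an image to [0, 1].

    A constant image is degenerate (max == min); it maps to all zeros and a
    warning is logged.
    """
    raw = np.asarray(raw_image, dtype=float)
    if raw.size == 0:
        raise ValueError("image is empty")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("constant image: min == max == %s; normalizing to zeros", lo)
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def resize_sample(sample: MRISample, target_h: int, target_w: int) -> MRISample:
    """Nearest-neighbor resize of image and mask together.

    Pixel spacing is rescaled by (original/target) per axis so the slice
    keeps its physical extent; the mask stays strictly binary.
    """
    if target_h <= 0 or target_w <= 0:
        raise ValueError("target dimensions must be positive")
    h, w = sample.mask.shape
    if (h, w) == (target_h, target_w):
        return MRISample(sample.image.copy(), sample.mask.copy(), sample.spacing, sample.id)
    image = _sk_resize(sample.image, (target_h, target_w), order=0,
                       preserve_range=True, anti_aliasing=False)
    mask = _sk_resize(sample.mask.astype(float), (target_h, target_w), order=0,
                      preserve_range=True, anti_aliasing=False)
    spacing = PixelSpacing(sample.spacing.sx * w / target_w,
                           sample.spacing.sy * h / target_h)
    return MRISample(image, (mask >= 0.5).astype(np.uint8), spacing, sample.id)


def split_dataset(samples, spec: SplitSpec):
    """Seed-deterministic shuffle, then a floor-rule partition.

    Train and validation get floor(n * fraction) samples each; the remainder
    goes to test.  The three lists are disjoint and cover the input.
    """
    spec.validate()
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(n * spec.train_fraction))
    n_val = int(np.floor(n * spec.val_fraction))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


def _transform_pair(image, mask, fn):
    """Apply the same geometric transform to image (per channel) and mask,
    re-binarizing the mask at 0.5 after any interpolation."""
    out_img = np.stack([fn(image[:, :, c], 1) for c in range(image.shape[2])], axis=2)
    out_mask = fn(mask.astype(float), 1)
    return np.clip(out_img, 0.0, 1.0), (out_mask >= 0.5).astype(np.uint8)


def rotate_sample(sample: MRISample, degrees: float) -> MRISample:
    """Counter-clockwise rotation about the image center.

    Exact 90-degree multiples are pure pixel permutations (no interpolation);
    other angles interpolate bilinearly with nearest fill, and the mask is
    re-binarized.
    """
    deg = degrees % 360.0
    if deg % 90.0 == 0.0:
        k = int(deg // 90) % 4
        image = np.rot90(sample.image, k, axes=(0, 1)).copy()
        mask = np.rot90(sample.mask, k, axes=(0, 1)).copy()
        return MRISample(image, mask, sample.spacing, sample.id)

    def fn(arr, order):
        return ndimage.rotate(arr, deg, reshape=False, order=order, mode="nearest")

    image, mask = _transform_pair(sample.image, sample.mask, fn)
    return MRISample(image, mask, sample.spacing, sample.id)


def flip_sample(sample: MRISample, axis: int) -> MRISample:
    """Mirror along axis 0 (vertical) or 1 (horizontal)."""
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    return MRISample(np.flip(sample.image, axis).copy(),
                     np.flip(sample.mask, axis).copy(),
                     sample.spacing, sample.id)


def augment(sample: MRISample, spec: AugmentSpec, draw_seed: int) -> MRISample:
    """Random-scheme augmentation: rotation, shift, zoom, optional flips.

    The draw is fully determined by ``(spec.seed, draw_seed)``; image and
    mask receive the identical transform.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(draw_seed,)))
    h, w = sample.mask.shape

    angle = rng.uniform(-1.0, 1.0) * spec.random_rotation_factor * 180.0
    shift_y = rng.uniform(-1.0, 1.0) * spec.shift_fraction * h
    shift_x = rng.uniform(-1.0, 1.0) * spec.shift_fraction * w
    zoom = 1.0 + rng.uniform(-1.0, 1.0) * spec.zoom_fraction
    flip_axes = []
    if spec.allow_flips:
        if rng.random() < 0.5:
            flip_axes.append(0)
        if rng.random() < 0.5:
            flip_axes.append(1)

    def fn(arr, order):
        out = ndimage.rotate(arr, angle, reshape=False, order=order, mode="nearest")
        out = ndimage.shift(out, (shift_y, shift_x), order=order, mode="nearest")
        # zoom about the center, keeping the frame size fixed
        mat = np.array([[1.0 / zoom, 0.0], [0.0, 1.0 / zoom]])
        center = (np.array([h, w]) - 1) / 2.0
        offset = center - mat @ center
        out = ndimage.affine_transform(out, mat, offset=offset, order=order, mode="nearest")
        for ax in flip_axes:
            out = np.flip(out, ax)
        return out

    image, mask = _transform_pair(sample.image, sample.mask, fn)
    return MRISample(image, mask, sample.spacing, sample.id)


def fixed_augmentations(sample: MRISample, spec: AugmentSpec) -> list[MRISample]:
    """The fixed enrichment scheme: each listed rotation, plus both flips."""
    spec.validate()
    out = [rotate_sample(sample, deg) for deg in spec.fixed_rotations]
    if spec.allow_flips:
        out.append(flip_sample(sample, 0))
        out.append(flip_sample(sample, 1))
    return out
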