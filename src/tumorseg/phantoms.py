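"""Synthetic MRI phantom generator.

Produces 2-D FLAIR-like slices: a darker elliptical "brain" region on a black
background, textured with smoothed Gaussian noise, optionally containing one
rotated hyperintense elliptical lesion.  The ground-truth mask is analytic —
exactly the set of pixels whose centers fall inside the lesion ellipse — so
every downstream stage (segmentation, metrics, area quantification) can be
validated against exact integer pixel counts without any external dataset.

What the phantoms do NOT emulate: MRI physics (bias fields, partial volume,
Rician noise), 3-D anatomy, multi-focal or non-elliptical lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sample import MRISample, PixelSpacing


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom family.

    Defaults describe the desk-scale study conditions: 128x128 slices at
    1.0 mm isotropic spacing, 70% lesion prevalence, lesion semi-axes of
    6-20 px, a 0.35 intensity step between lesion and brain tissue, mild
    smoothed background texture and additive noise.
    """

    image_height: int = 128
    image_width: int = 128
    tumor_probability: float = 0.7
    tumor_semi_axes_range: tuple[float, float] = (6.0, 20.0)
    tumor_contrast: float = 0.35
    background_texture_sigma: float = 0.06
    noise_sigma: float = 0.02
    pixel_spacing_x: float = 1.0
    pixel_spacing_y: float = 1.0
    seed: int = 0

    def validate(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image_height/image_width must be positive")
        lo, hi = self.tumor_semi_axes_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_semi_axes_range must satisfy 0 < min <= max")
        if hi >= min(self.image_height, self.image_width) / 2:
            raise ValueError("tumor_semi_axes_range max must be < min(image dims)/2")
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ValueError("tumor_probability must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.background_texture_sigma < 0:
            raise ValueError("background_texture_sigma must be >= 0")
        if self.pixel_spacing_x <= 0 or self.pixel_spacing_y <= 0:
            raise ValueError("pixel spacing must be positive")
        return self


def _ellipse_membership(h, w, cy, cx, a, b, theta):
    """Boolean grid: pixel centers inside the rotated ellipse.

    Semi-axis ``a`` lies along the (rotated) x direction, ``b`` along y.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, index: int) -> MRISample:
    """Generate one deterministic phantom slice.

    The same ``(spec, index)`` always yields bit-identical output; the random
    stream is derived from ``(spec.seed, index)`` so a dataset can be
    regenerated sample by sample.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))
    h, w = spec.image_height, spec.image_width

    # brain: a large ellipse of moderate intensity on black background
    brain_a = 0.44 * w
    brain_b = 0.46 * h
    brain = _ellipse_membership(h, w, h / 2, w / 2, brain_a, brain_b, 0.0)
    img = np.where(brain, 0.25, 0.02)

    texture = rng.standard_normal((h, w))
    texture = ndimage.gaussian_filter(texture, sigma=3.0)
    texture /= max(texture.std(), 1e-12)
    img = img + spec.background_texture_sigma * texture * brain

    mask = np.zeros((h, w), dtype=np.uint8)
    has_tumor = rng.random() < spec.tumor_probability
    if has_tumor:
        lo, hi = spec.tumor_semi_axes_range
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 2.0
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        inside = _ellipse_membership(h, w, cy, cx, a, b, theta)
        mask[inside] = 1
        # smooth hyperintense profile with a floor at half the contrast so
        # the lesion remains separable from tissue out to its boundary
        yy, xx = np.mgrid[0:h, 0:w]
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r2 = (u / a) ** 2 + (v / b) ** 2
        bump = spec.tumor_contrast * (0.5 + 0.5 * np.exp(-3.0 * r2))
        img = img + bump * inside

    img = img + spec.noise_sigma * rng.standard_normal((h, w))
    img = np.clip(img, 0.0, 1.0)
    image = np.repeat(img[:, :, None], 3, axis=2)

    return MRISample(
        image=image,
        mask=mask,
        spacing=PixelSpacing(spec.pixel_spacing_x, spec.pixel_spacing_y),
        id=f"phantom_{index:04d}",
    )


def generate_dataset(spec: PhantomSpec, n: int) -> list[MRISample]:
    """Generate ``n`` phantoms with indices ``0..n-1``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(spec, i) for i in range(n)]


def write_dataset(samples, out_dir, metadata_name="phantoms.csv"):
    """Write paired PNGs (image_XXXX.png / mask_XXXX.png) plus a CSV sidecar.

    The sidecar records id, has_tumor, pixel spacing, and the exact
    ground-truth pixel count of each mask.
    """
    import pandas as pd

    from .io import write_png

    out_dir = _ensure_dir(out_dir)
    rows = []
    for i, s in enumerate(samples):
        write_png(out_dir / f"image_{i:04d}.png", s.image)
        write_png(out_dir / f"mask_{i:04d}.png", s.mask)
        rows.append({
            "id": s.id,
            "has_tumor": int(s.mask.any()),
            "pixel_spacing_x_mm": s.spacing.sx,
            "pixel_spacing_y_mm": s.spacing.sy,
            "true_pixel_count": int(s.mask.sum()),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / metadata_name, index=False)
    return table


def _ensure_dir(path):
    from pathlib import Path

    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
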