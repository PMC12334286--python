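"""Classical intensity-threshold segmentation baselines.

Three operations: the hard thresholding rule g(x,y) = [f(x,y) >= T], the
isodata iterative threshold (T updated to the midpoint of the foreground and
background means until it stops moving), and Otsu's method (the histogram
level maximizing between-class variance, equivalently minimizing weighted
within-class variance).  Pixels equal to T always belong to the foreground
class, matching the >= branch of the thresholding rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    iterations: int
    converged: bool


def apply_threshold(image, T: float) -> np.ndarray:
    """Binary mask: 1 where the pixel value is >= T, else 0."""
    return (np.asarray(image) >= T).astype(np.uint8)


def isodata_threshold(image, initial_T: float | None = None, tolerance: float = 0.5,
                      max_iterations: int = 256) -> ThresholdResult:
    """Iterate T <- (mean of pixels >= T + mean of pixels < T) / 2.

    Starts from the global mean unless ``initial_T`` is given and stops when
    the threshold moves by at most ``tolerance``.  The default tolerance of
    0.5 is below the quantization resolution of 8-bit images.
    """
    x = np.asarray(image, dtype=float).ravel()
    if np.unique(x).size < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct values")
    t = float(x.mean()) if initial_T is None else float(initial_T)
    for it in range(1, max_iterations + 1):
        fg = x[x >= t]
        bg = x[x < t]
        if fg.size == 0 or bg.size == 0:
            # threshold fell outside the data range; re-center and continue
            t_new = float(x.mean())
        else:
            t_new = (fg.mean() + bg.mean()) / 2.0
        if abs(t_new - t) <= tolerance:
            return ThresholdResult(threshold=t_new, iterations=it, converged=True)
        t = t_new
    return ThresholdResult(threshold=t, iterations=max_iterations, converged=False)


def _class_stats(x, t):
    """Weights, means, variances of the background (< t) and foreground (>= t)."""
    fg = x[x >= t]
    bg = x[x < t]
    n = x.size
    w0, w1 = bg.size / n, fg.size / n
    mu0 = bg.mean() if bg.size else 0.0
    mu1 = fg.mean() if fg.size else 0.0
    v0 = bg.var() if bg.size else 0.0
    v1 = fg.var() if fg.size else 0.0
    return w0, w1, mu0, mu1, v0, v1


def between_class_variance(image, t: float) -> float:
    x = np.asarray(image, dtype=float).ravel()
    w0, w1, mu0, mu1, _, _ = _class_stats(x, t)
    return w0 * w1 * (mu1 - mu0) ** 2


def within_class_variance(image, t: float) -> float:
    x = np.asarray(image, dtype=float).ravel()
    w0, w1, _, _, v0, v1 = _class_stats(x, t)
    return w0 * v0 + w1 * v1


def otsu_threshold(image) -> ThresholdResult:
    """Otsu's method over the distinct observed levels.

    Candidates are every distinct level above the minimum (so both classes
    are non-empty); the argmax of between-class variance is returned, ties
    broken toward the lowest level.
    """
    x = np.asarray(image, dtype=float).ravel()
    levels = np.unique(x)
    if levels.size < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct values")
    candidates = levels[1:]  # threshold == min would give an empty background
    best_t, best_v = None, None
    for t in candidates:
        v = between_class_variance(x, t)
        if best_t is None or v > best_v + 1e-12 * max(1.0, abs(best_v)):
            best_t, best_v = float(t), v
    return ThresholdResult(threshold=best_t, iterations=int(candidates.size), converged=True)
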