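"""Segmentation quality metrics and trial statistics.

Pixel accuracy, Dice similarity coefficient DSC = 2|P∩O|/(|P|+|O|), and
intersection-over-union IoU = |P∩O|/|P∪O| on binary masks, with the
0/0 case (both masks empty) scored 1.0 — a correct all-negative prediction
is not penalized.  Trials are summarized as mean ± sample (n-1) SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_binary(arr, name):
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary")
    return a.astype(bool)


def _check_pair(pred, truth):
    p = _as_binary(pred, "pred")
    o = _as_binary(truth, "truth")
    if p.shape != o.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {o.shape}")
    return p, o


def pixel_accuracy(pred, truth) -> float:
    """Fraction of pixels on which the two masks agree."""
    p, o = _check_pair(pred, truth)
    return float((p == o).mean())


def dice_coefficient(pred, truth) -> float:
    """2|P∩O| / (|P|+|O|); 1.0 when both masks are empty."""
    p, o = _check_pair(pred, truth)
    denom = p.sum() + o.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, o).sum() / denom)


def iou(pred, truth) -> float:
    """|P∩O| / |P∪O|; 1.0 when both masks are empty."""
    p, o = _check_pair(pred, truth)
    union = np.logical_or(p, o).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, o).sum() / union)


@dataclass
class TrialSummary:
    mean: float
    sd: float

    def __str__(self):
        return f"{self.mean:.4f} ± {self.sd:.4f}"


def summarize_trials(values) -> TrialSummary:
    """Arithmetic mean and sample (n-1 denominator) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 trials to summarize")
    sd = 0.0 if (v == v[0]).all() else float(v.std(ddof=1))
    return TrialSummary(mean=float(v.mean()), sd=sd)


@dataclass
class MetricReport:
    """Per-sample metric table plus aggregates, optionally across trials."""

    per_sample: pd.DataFrame
    aggregate: dict[str, float]
    trials: list[dict[str, float]] = field(default_factory=list)
    summary: dict[str, TrialSummary] = field(default_factory=dict)


def evaluate_pairs(pairs, mode="per_slice") -> MetricReport:
    """Score (id, pred, truth) triples.

    ``per_slice`` averages each metric over slices (the reporting
    convention used throughout); ``pooled`` accumulates pixel counts over
    the whole set before forming each metric.
    """
    rows = []
    tp = fp = fn = correct = total = 0
    for sample_id, pred, truth in pairs:
        rows.append({
            "id": sample_id,
            "accuracy": pixel_accuracy(pred, truth),
            "dice": dice_coefficient(pred, truth),
            "iou": iou(pred, truth),
        })
        p, o = _check_pair(pred, truth)
        tp += np.logical_and(p, o).sum()
        fp += np.logical_and(p, ~o).sum()
        fn += np.logical_and(~p, o).sum()
        correct += (p == o).sum()
        total += p.size
    table = pd.DataFrame(rows)
    if mode == "per_slice":
        aggregate = {m: float(table[m].mean()) for m in ("accuracy", "dice", "iou")}
    elif mode == "pooled":
        denom = 2 * tp + fp + fn
        union = tp + fp + fn
        aggregate = {
            "accuracy": correct / total,
            "dice": 1.0 if denom == 0 else 2 * tp / denom,
            "iou": 1.0 if union == 0 else tp / union,
        }
    else:
        raise ValueError("mode must be 'per_slice' or 'pooled'")
    return MetricReport(per_sample=table, aggregate=aggregate)


def summarize_trial_reports(trial_aggregates) -> dict[str, TrialSummary]:
    """mean ± SD per metric over a list of aggregate dicts (one per trial)."""
    out = {}
    for m in ("accuracy", "dice", "iou"):
        out[m] = summarize_trials([t[m] for t in trial_aggregates])
    return out
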