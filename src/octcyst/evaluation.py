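"""Per-image sensitivity/specificity evaluation and parameter sweeps.

The unit of evaluation is the B-scan: a scan is *positive* when labeled
cystic.  Sensitivity ``SE = TP / (TP + FN)`` and specificity
``SP = TN / (TN + FP)`` are reported per parameter setting; a ratio
with zero denominator is returned as NaN with a warning rather than
silently imputed, so degenerate batches cannot corrupt a sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .maps import GrayImage
from .pipeline import PipelineParams, classify_scan

__all__ = ["ConfusionCounts", "confusion", "se_sp", "sweep"]

POSITIVE = "cystic"
NEGATIVE = "non-cystic"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _check_label(label: str) -> str:
    if label not in (POSITIVE, NEGATIVE):
        raise ValueError(f"labels must be {POSITIVE!r} or {NEGATIVE!r}, got {label!r}")
    return label


def confusion(pred: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Standard 2x2 counts over per-image labels (cystic = positive)."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        p, t = _check_label(p), _check_label(t)
        if t == POSITIVE:
            tp, fn = tp + (p == POSITIVE), fn + (p == NEGATIVE)
        else:
            tn, fp = tn + (p == NEGATIVE), fp + (p == POSITIVE)
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def se_sp(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity; NaN (with a warning) when undefined."""
    if counts.TP + counts.FN > 0:
        se = counts.TP / (counts.TP + counts.FN)
    else:
        warnings.warn("no positive images in batch: SE undefined", stacklevel=2)
        se = float("nan")
    if counts.TN + counts.FP > 0:
        sp = counts.TN / (counts.TN + counts.FP)
    else:
        warnings.warn("no negative images in batch: SP undefined", stacklevel=2)
        sp = float("nan")
    return se, sp


def evaluate(
    images: Sequence[GrayImage],
    truth: Sequence[str],
    params: PipelineParams | None = None,
) -> tuple[ConfusionCounts, float, float]:
    """Classify every image and score against the truth labels."""
    pred = [classify_scan(img, params).label for img in images]
    counts = confusion(pred, truth)
    se, sp = se_sp(counts)
    return counts, se, sp


def sweep(
    images: Sequence[GrayImage],
    truth: Sequence[str],
    grid: Iterable[PipelineParams],
) -> pd.DataFrame:
    """Evaluate a batch under every parameter setting in ``grid``.

    Returns one row per grid point with the key detection/shadow
    parameters alongside SE and SP, mirroring the usual operating-point
    summary table.
    """
    rows = []
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    if not images:
        raise ValueError("image batch is empty")
    for params in grid:
        counts, se, sp = evaluate(images, truth, params)
        rows.append(
            {
                "alpha": params.shadow.alpha,
                "s": params.detection.s,
                "t": params.detection.t,
                "num": params.detection.num,
                "thv": params.detection.thv,
                "thv_rel": params.detection.thv_rel,
                "shadow_removal": params.shadow_removal,
                "TP": counts.TP,
                "FP": counts.FP,
                "TN": counts.TN,
                "FN": counts.FN,
                "SE": se,
                "SP": sp,
            }
        )
    return pd.DataFrame(rows)
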