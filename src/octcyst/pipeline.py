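"""End-to-end cystic / non-cystic classification of a B-scan.

Three phases: median-filter denoising, boundary-pixel determination
(patch voting), and shadow-based false-positive suppression.  The scan
is labeled *cystic* when at least ``min_candidates`` accepted patches
survive the shadow filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .boundary import CystCandidate, DetectionParams, detect_candidates
from .maps import GrayImage, compute_diff_maps
from .shadows import ShadowParams, ShadowProfile, detect_shadow_columns

__all__ = [
    "PipelineParams",
    "ScanResult",
    "denoise",
    "remove_near_shadow",
    "classify_scan",
]


@dataclass(frozen=True)
class PipelineParams:
    """Full-pipeline parameters.

    ``median_kernel`` is the odd denoising window (1 disables it).
    ``shadow_margin`` is the column distance within which a candidate
    seed is discarded around a flagged shadow column; ``None`` ties it
    to the patch width ``t`` (a candidate whose patch could overlap a
    shadow column is suspect).  ``shadow_removal=False`` skips phase 3
    entirely, which is useful for quantifying its effect.
    """

    detection: DetectionParams = field(default_factory=DetectionParams)
    shadow: ShadowParams = field(default_factory=ShadowParams)
    median_kernel: int = 3
    shadow_margin: int | None = None
    min_candidates: int = 1
    shadow_removal: bool = True

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.shadow_margin is not None and self.shadow_margin < 0:
            raise ValueError("shadow_margin must be >= 0")
        if self.min_candidates < 1:
            raise ValueError("min_candidates must be >= 1")

    def resolve_margin(self) -> int:
        return self.detection.t if self.shadow_margin is None else self.shadow_margin


@dataclass(frozen=True)
class ScanResult:
    """Outcome of classifying one B-scan."""

    label: str  # "cystic" | "non-cystic"
    candidates_raw: tuple[CystCandidate, ...]
    candidates_kept: tuple[CystCandidate, ...]
    shadow: ShadowProfile
    params_used: PipelineParams

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_raw": len(self.candidates_raw),
            "n_kept": len(self.candidates_kept),
            "n_shadow_columns": int(self.shadow.shadow_columns.size),
            "candidates": [c.to_dict() for c in self.candidates_kept],
            "shadow": self.shadow.to_dict(),
        }


def denoise(img: GrayImage | np.ndarray, median_kernel: int = 3) -> GrayImage:
    """Median-filter speckle suppression (reflected edges)."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if median_kernel % 2 == 0 or median_kernel < 1:
        raise ValueError("median_kernel must be odd and >= 1")
    if median_kernel > min(px.shape):
        raise ValueError("median_kernel exceeds the image extent")
    if median_kernel == 1:
        return GrayImage(px.copy())
    return GrayImage(median_filter(px, size=median_kernel, mode="reflect"))


def remove_near_shadow(
    candidates: list[CystCandidate] | tuple[CystCandidate, ...],
    shadow: ShadowProfile | np.ndarray,
    shadow_margin: int,
) -> list[CystCandidate]:
    """Drop candidates whose seed column lies within ``shadow_margin``
    columns of any flagged shadow column; survivor order preserved."""
    cols = shadow.shadow_columns if isinstance(shadow, ShadowProfile) else np.asarray(shadow)
    if cols.size == 0:
        return list(candidates)
    cols = np.sort(cols)
    kept = []
    for cand in candidates:
        j = cand.seed[1]
        idx = np.searchsorted(cols, j)
        near = False
        if idx < cols.size and cols[idx] - j <= shadow_margin:
            near = True
        if idx > 0 and j - cols[idx - 1] <= shadow_margin:
            near = True
        if not near:
            kept.append(cand)
    return kept


def classify_scan(
    img: GrayImage | np.ndarray, params: PipelineParams | None = None
) -> ScanResult:
    """Run denoise -> patch voting -> shadow detection -> filtering.

    Deterministic for a fixed image and parameter set.
    """
    params = params or PipelineParams()
    if not isinstance(img, GrayImage):
        img = GrayImage.from_array(np.asarray(img))
    clean = denoise(img, params.median_kernel)
    diff = compute_diff_maps(clean, params.detection.a, params.detection.b)
    raw = detect_candidates(clean, params.detection, diff=diff)
    if params.detection.a == params.shadow.a and params.detection.b == params.shadow.b:
        shadow = detect_shadow_columns(clean, params.shadow, diff=diff)
    else:
        shadow = detect_shadow_columns(clean, params.shadow)
    if params.shadow_removal:
        kept = remove_near_shadow(raw, shadow, params.resolve_margin())
    else:
        kept = list(raw)
    label = "cystic" if len(kept) >= params.min_candidates else "non-cystic"
    return ScanResult(
        label=label,
        candidates_raw=tuple(raw),
        candidates_kept=tuple(kept),
        shadow=shadow,
        params_used=params,
    )
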