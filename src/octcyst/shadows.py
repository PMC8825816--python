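"""Vessel-shadow column detection by per-column transition tracking.

A retinal blood vessel attenuates the OCT beam and casts a dark
vertical stripe over everything beneath it, most visibly over the
bright retinal pigment epithelium (RPE) band near the bottom of the
scan.  Dark shadow boundaries are a major source of false cyst
detections, so shadowed columns must be found and candidates near them
discarded.

Per column the detector finds ``Q_j``: the bottom-most pixel at which

* ``|df|`` has a strict local maximum along the column,
* ``df < 0`` (scanning upward, a dark-to-light transition), and
* the region just above is genuinely bright — the mean map two rows up
  is at least ``m_th``, the smallest of the column's top ``floor(alpha*m)``
  mean values.

In an unshadowed column ``Q_j`` sits at the lower edge of the bright
RPE band.  Under a shadow that band is too dark to qualify, so ``Q_j``
jumps to a much higher structure or disappears entirely.  Columns are
therefore flagged as shadow wherever the ``Q_j`` track jumps by more
than ``jump_thr`` rows between consecutive columns (or flips between
present and absent): each jump opens or closes a shadow run, and the
whole run of displaced/absent columns between an entry jump and its
return jump is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .maps import DiffMaps, GrayImage, compute_diff_maps, local_max_mask

__all__ = [
    "ShadowParams",
    "ShadowProfile",
    "column_transition",
    "detect_shadow_columns",
]


@dataclass(frozen=True)
class ShadowParams:
    """Parameters of the shadow-column detector.

    ``alpha`` sets the brightness bar for the region above the tracked
    transition: the top ``floor(alpha*m)`` mean values of the column
    define the cutoff ``m_th``.  Smaller ``alpha`` demands a brighter
    region, making transitions harder to certify and flagging more
    columns as shadow.  ``jump_thr`` (pixels) is the minimum change of
    the transition row between consecutive columns that signals a
    shadow boundary; the default ``max(10, ceil(0.05*m))`` adapts to
    image height and is resolved at run time.
    """

    alpha: float = 0.08
    jump_thr: int | None = None
    a: int = 1
    b: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.jump_thr is not None and self.jump_thr < 1:
            raise ValueError("jump_thr must be >= 1")
        if self.a < 1 or self.b < 1:
            raise ValueError("window half-widths a, b must be >= 1")

    def resolve_jump_thr(self, m: int) -> int:
        if self.jump_thr is not None:
            return int(self.jump_thr)
        return max(10, math.ceil(0.05 * m))


@dataclass(frozen=True)
class ShadowProfile:
    """Per-column transition track and the flagged shadow columns.

    ``Q`` holds the 0-based transition row per column (NaN where no
    pixel qualifies, including the undefined border columns); ``m_th``
    the per-column brightness cutoff (NaN likewise).  ``shadow_columns``
    is a sorted array of 0-based flagged column indices, always within
    the defined interior.
    """

    Q: np.ndarray
    m_th: np.ndarray
    shadow_columns: np.ndarray
    jump_thr: int

    def to_dict(self) -> dict:
        q = [None if not np.isfinite(v) else int(v) + 1 for v in self.Q]
        mth = [None if not np.isfinite(v) else float(v) for v in self.m_th]
        return {
            "Q": q,
            "m_th": mth,
            "jump_thr": self.jump_thr,
            "shadow_columns": [int(c) + 1 for c in self.shadow_columns],
        }


def _alpha_count(alpha: float, m: int) -> int:
    k = math.floor(alpha * m)
    if k < 1:
        raise ValueError(f"alpha={alpha} gives floor(alpha*m)={k} < 1 for m={m} rows")
    return k


def column_transition(
    diff: DiffMaps, col: int, alpha: float
) -> tuple[int | None, float | None]:
    """Locate ``Q`` and ``m_th`` for one column (0-based index).

    Returns ``(None, None)`` when the column has no defined mean values
    and ``(None, m_th)`` when none of its pixels satisfies all three
    transition conditions.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    m = diff.A.shape[0]
    a_col = diff.A[:, col]
    defined = np.isfinite(a_col)
    if not defined.any():
        return None, None
    k = min(_alpha_count(alpha, m), int(defined.sum()))
    vals = np.sort(a_col[defined])[::-1]
    m_th = float(vals[k - 1])

    df_col = diff.df[:, col]
    absdf = np.abs(df_col)
    peak = local_max_mask(absdf[:, None], "vertical")[:, 0]
    above = np.full(m, np.nan)
    above[2:] = a_col[:-2]  # A two rows above each position
    ok = peak & (df_col < 0) & (above >= m_th)
    rows = np.nonzero(ok)[0]
    if rows.size == 0:
        return None, m_th
    return int(rows[-1]), m_th


def _runs(cols: np.ndarray, boundary_after: np.ndarray) -> list[np.ndarray]:
    """Split the interior column index array at jump boundaries."""
    segments, start = [], 0
    for idx in range(cols.size - 1):
        if boundary_after[idx]:
            segments.append(cols[start : idx + 1])
            start = idx + 1
    segments.append(cols[start:])
    return [s for s in segments if s.size]


def detect_shadow_columns(
    img: GrayImage | np.ndarray,
    params: ShadowParams | None = None,
    diff: DiffMaps | None = None,
) -> ShadowProfile:
    """Track ``Q`` across all interior columns and flag shadow runs.

    The track is segmented at every jump (``|dQ| > jump_thr`` or a
    present/absent flip between consecutive columns).  The unshadowed
    baseline row is the median of all recorded ``Q``; a segment is
    flagged when its pixels have no transition at all or its median
    ``Q`` is displaced from the baseline by more than ``jump_thr``.
    """
    params = params or ShadowParams()
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if diff is None:
        diff = compute_diff_maps(px, params.a, params.b)
    m, n = px.shape
    jump_thr = params.resolve_jump_thr(m)

    Q = np.full(n, np.nan)
    m_th = np.full(n, np.nan)
    interior = np.array(
        [j for j in range(n) if np.isfinite(diff.A[:, j]).any()], dtype=np.int64
    )
    for j in interior:
        q, cut = column_transition(diff, int(j), params.alpha)
        if cut is not None:
            m_th[j] = cut
        if q is not None:
            Q[j] = q

    flagged: list[int] = []
    if interior.size:
        qi = Q[interior]
        present = np.isfinite(qi)
        jump = np.zeros(interior.size - 1, dtype=bool)
        for idx in range(interior.size - 1):
            if present[idx] != present[idx + 1]:
                jump[idx] = True
            elif present[idx] and abs(qi[idx + 1] - qi[idx]) > jump_thr:
                jump[idx] = True
        if jump.any() and present.any():
            baseline = float(np.median(qi[present]))
            for seg in _runs(interior, jump):
                seg_q = Q[seg]
                if not np.isfinite(seg_q).any():
                    flagged.extend(int(c) for c in seg)
                elif abs(float(np.median(seg_q)) - baseline) > jump_thr:
                    flagged.extend(int(c) for c in seg)

    return ShadowProfile(
        Q=Q,
        m_th=m_th,
        shadow_columns=np.array(sorted(flagged), dtype=np.int64),
        jump_thr=jump_thr,
    )
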