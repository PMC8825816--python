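"""Independent brute-force reference implementations used by the tests.

Everything here is a deliberately naive loop over pixels, kept free of
the vectorized code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_mean_map(px: np.ndarray, a: int, b: int) -> np.ndarray:
    m, n = px.shape
    out = np.full((m, n), np.nan)
    for i in range(a, m - a):
        for j in range(b, n - b):
            acc = 0.0
            for p in range(i - a, i + a + 1):
                for q in range(j - b, j + b + 1):
                    acc += px[p, q]
            out[i, j] = acc / ((2 * a + 1) * (2 * b + 1))
    return out


def _get(arr: np.ndarray, i: int, j: int) -> float:
    m, n = arr.shape
    if 0 <= i < m and 0 <= j < n:
        return arr[i, j]
    return math.nan


def naive_diff_maps(px: np.ndarray, a: int, b: int) -> dict[str, np.ndarray]:
    A = naive_mean_map(px, a, b)
    m, n = px.shape
    maps = {k: np.full((m, n), np.nan) for k in ("dv", "dl", "dr", "df")}
    for i in range(m):
        for j in range(n):
            maps["dv"][i, j] = _get(A, i - 1, j) - _get(A, i + 1, j)
            maps["dl"][i, j] = _get(A, i - 1, j - 1) - _get(A, i + 1, j + 1)
            maps["dr"][i, j] = _get(A, i - 1, j + 1) - _get(A, i + 1, j - 1)
            maps["df"][i, j] = _get(A, i + 2, j) - _get(A, i - 2, j)
    maps["A"] = A
    return maps


_OFFS = {"vertical": (1, 0), "diag-down-right": (1, 1), "diag-down-left": (1, -1)}


def naive_local_max(arr: np.ndarray, direction: str) -> np.ndarray:
    di, dj = _OFFS[direction]
    m, n = arr.shape
    out = np.zeros((m, n), dtype=bool)
    for i in range(m):
        for j in range(n):
            v = arr[i, j]
            before = _get(arr, i - di, j - dj)
            after = _get(arr, i + di, j + dj)
            out[i, j] = v > before and v > after  # NaN comparisons are False
    return out


def naive_sets(px: np.ndarray, a: int, b: int, thv: float):
    maps = naive_diff_maps(px, a, b)
    V = naive_local_max(maps["dv"], "vertical") & (maps["dv"] > thv) & (maps["dv"] > 0)
    L = (
        naive_local_max(maps["dl"], "diag-down-right")
        & (maps["dl"] > thv)
        & (maps["dl"] > 0)
    )
    R = (
        naive_local_max(maps["dr"], "diag-down-left")
        & (maps["dr"] > thv)
        & (maps["dr"] > 0)
    )
    return V, L, R


def naive_candidates(
    px: np.ndarray, a: int, b: int, s: int, t: int, num: int, thv: float
) -> list[tuple]:
    """Straight-line patch voting: returns (seed, side, rows, cols, count)."""
    m, n = px.shape
    V, L, R = naive_sets(px, a, b, thv)
    out = []
    for i in range(m):
        for j in range(n):
            if not V[i, j]:
                continue
            r1, r2 = i + 1, min(i + s, m - 1)
            if r1 > r2:
                continue
            for side, mask, c1, c2 in (
                ("left", L, j - t, j - 1),
                ("right", R, j + 1, j + t),
            ):
                c1c, c2c = max(c1, 0), min(c2, n - 1)
                if c1c > c2c:
                    continue
                count = 0
                for p in range(r1, r2 + 1):
                    for q in range(c1c, c2c + 1):
                        count += bool(mask[p, q])
                if count > num:
                    out.append(((i, j), side, (r1, r2), (c1c, c2c), count))
    return out


def naive_column_transition(A: np.ndarray, df: np.ndarray, col: int, alpha: float):
    """Bottom-up scan of the three transition conditions in one column."""
    m = A.shape[0]
    vals = sorted((A[i, col] for i in range(m) if np.isfinite(A[i, col])), reverse=True)
    if not vals:
        return None, None
    k = min(max(int(math.floor(alpha * m)), 1), len(vals))
    m_th = vals[k - 1]
    for i in range(m - 1, -1, -1):
        v = df[i, col]
        if not np.isfinite(v) or not (v < 0):
            continue
        up = abs(_get(df, i - 1, col))
        down = abs(_get(df, i + 1, col))
        if not (abs(v) > up if np.isfinite(up) else False):
            continue
        if not (abs(v) > down if np.isfinite(down) else False):
            continue
        above = _get(A, i - 2, col)
        if np.isfinite(above) and above >= m_th:
            return i, m_th
    return None, m_th
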