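"""Neighborhood-mean and directional difference maps for OCT B-scans.

The detector reasons about an image entirely through the local mean map
``A`` and four directional difference maps derived from it:

* ``dv[i, j] = A[i-1, j] - A[i+1, j]``   (vertical change; > 0 where a
  bright region sits above a dark one, i.e. a light-to-dark transition
  going down the column),
* ``dl[i, j] = A[i-1, j-1] - A[i+1, j+1]``  (change along the down-right
  diagonal, sensed at the left shoulder of a pixel),
* ``dr[i, j] = A[i-1, j+1] - A[i+1, j-1]``  (change along the down-left
  diagonal, right shoulder),
* ``df[i, j] = A[i+2, j] - A[i-2, j]``   (wider-offset vertical change
  used by the shadow detector; < 0 where the region above is brighter).

``A`` itself is the arithmetic mean over a ``(2a+1) x (2b+1)`` window.
Positions where the full window (or any difference operand) does not fit
inside the image are *undefined* and stored as NaN; no padding is ever
applied, since padded values would fabricate intensity transitions at
the image borders.

Indexing is 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "DiffMaps",
    "compute_mean_map",
    "compute_diff_maps",
    "local_max_mask",
    "DimensionError",
]

#: minimum image side so that every offset-2 difference has an interior
MIN_SIDE = 7


class DimensionError(ValueError):
    """Raised when an image is too small for the requested window."""


@dataclass(frozen=True)
class GrayImage:
    """A single-channel B-scan with intensities normalized to [0, 255].

    Parameters
    ----------
    pixels:
        ``m x n`` float64 array; every value finite and in [0, 255].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale array, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise DimensionError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape[0]}x{px.shape[1]}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 255.0:
            raise ValueError("intensities must lie in [0, 255]; use GrayImage.from_array")
        object.__setattr__(self, "pixels", px)

    @property
    def m(self) -> int:
        """Row count (depth axis, increasing downward)."""
        return self.pixels.shape[0]

    @property
    def n(self) -> int:
        """Column count (lateral axis)."""
        return self.pixels.shape[1]

    @property
    def intensity_range(self) -> float:
        return float(self.pixels.max() - self.pixels.min())

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GrayImage":
        """Build a GrayImage from an arbitrary-depth raster.

        Integer inputs are rescaled linearly by their dtype range so a
        16-bit scan lands on the same [0, 255] scale as an 8-bit one
        (thresholds then carry one fixed meaning).  Float inputs are
        accepted as-is when already within [0, 255], or rescaled from
        [0, 1].  Multi-channel inputs are collapsed by luminance average
        with a warning.
        """
        a = np.asarray(arr)
        if a.ndim == 3:
            warnings.warn(
                "multi-channel image collapsed to grayscale by channel average",
                stacklevel=2,
            )
            a = a.astype(np.float64).mean(axis=2)
        if a.ndim != 2:
            raise ValueError(f"cannot interpret array of shape {a.shape} as a B-scan")
        if np.issubdtype(a.dtype, np.integer):
            info = np.iinfo(a.dtype)
            a = a.astype(np.float64) * (255.0 / info.max)
        else:
            a = a.astype(np.float64)
            if a.size and np.nanmax(a) <= 1.0 and np.nanmin(a) >= 0.0:
                a = a * 255.0
            a = np.clip(a, 0.0, 255.0)
        return cls(a)

    @classmethod
    def load(cls, path: str | Path) -> "GrayImage":
        """Read a PNG or TIFF grayscale image from disk."""
        path = Path(path)
        if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
            raise ValueError(f"unsupported image format: {path.suffix!r} (PNG/TIFF only)")
        return cls.from_array(iio.imread(path))


@dataclass(frozen=True)
class DiffMaps:
    """Mean map and the four directional difference maps of one image.

    All maps share the image shape; undefined positions are NaN.
    """

    A: np.ndarray
    dv: np.ndarray
    dl: np.ndarray
    dr: np.ndarray
    df: np.ndarray
    a: int
    b: int


def _check_window(a: int, b: int) -> tuple[int, int]:
    a, b = int(a), int(b)
    if a < 1 or b < 1:
        raise ValueError(f"window half-widths must be >= 1, got a={a}, b={b}")
    return a, b


def compute_mean_map(img: GrayImage | np.ndarray, a: int = 1, b: int = 1) -> np.ndarray:
    """Mean intensity over the ``(2a+1) x (2b+1)`` window at each pixel.

    Border positions where the window does not fit are NaN.  The sum is
    accumulated by explicit shifted adds, which reproduces a naive
    double-loop evaluation to float rounding.
    """
    a, b = _check_window(a, b)
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    m, n = px.shape
    if m <= 2 * a or n <= 2 * b:
        raise DimensionError(
            f"image {m}x{n} too small for window half-widths a={a}, b={b}; "
            f"need at least {2 * a + 1}x{2 * b + 1}"
        )
    hi, wi = m - 2 * a, n - 2 * b
    acc = np.zeros((hi, wi), dtype=np.float64)
    for di in range(2 * a + 1):
        for dj in range(2 * b + 1):
            acc += px[di : di + hi, dj : dj + wi]
    out = np.full((m, n), np.nan)
    out[a : m - a, b : n - b] = acc / ((2 * a + 1) * (2 * b + 1))
    return out


def _shift(arr: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Return S with S[i, j] = arr[i+di, j+dj], NaN where out of range."""
    m, n = arr.shape
    out = np.full_like(arr, np.nan)
    src_r = slice(max(di, 0), m + min(di, 0))
    src_c = slice(max(dj, 0), n + min(dj, 0))
    dst_r = slice(max(-di, 0), m + min(-di, 0))
    dst_c = slice(max(-dj, 0), n + min(-dj, 0))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def compute_diff_maps(img: GrayImage | np.ndarray, a: int = 1, b: int = 1) -> DiffMaps:
    """Compute the mean map and all four directional difference maps."""
    A = compute_mean_map(img, a, b)
    dv = _shift(A, -1, 0) - _shift(A, 1, 0)
    dl = _shift(A, -1, -1) - _shift(A, 1, 1)
    dr = _shift(A, -1, 1) - _shift(A, 1, -1)
    df = _shift(A, 2, 0) - _shift(A, -2, 0)
    return DiffMaps(A=A, dv=dv, dl=dl, dr=dr, df=df, a=a, b=b)


#: comparison-neighbor offset per direction (applied with both signs)
_DIRECTION_OFFSETS = {
    "vertical": (1, 0),
    "diag-down-right": (1, 1),
    "diag-down-left": (1, -1),
}


def local_max_mask(diff_map: np.ndarray, direction: str) -> np.ndarray:
    """Strict directional local maxima of a difference map.

    True where the value strictly exceeds both neighbors along the given
    direction; False on plateaus and wherever the value or a neighbor is
    undefined.  ``direction`` is one of ``vertical``, ``diag-down-right``
    (neighbors at (i-1, j-1)/(i+1, j+1)) or ``diag-down-left``
    (neighbors at (i-1, j+1)/(i+1, j-1)).
    """
    try:
        di, dj = _DIRECTION_OFFSETS[direction]
    except KeyError:
        raise ValueError(
            f"unknown direction {direction!r}; expected one of {sorted(_DIRECTION_OFFSETS)}"
        ) from None
    arr = np.asarray(diff_map, dtype=np.float64)
    before = _shift(arr, -di, -dj)
    after = _shift(arr, di, dj)
    # NaN comparisons are False, so undefined neighbors never certify a maximum
    return (arr > before) & (arr > after)
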