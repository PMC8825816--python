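"""Synthetic OCT-like B-scan phantoms with known ground truth.

A phantom is rendered as a stack of horizontal intensity bands (the
layered retina: dark vitreous, a bright inner band, mid-reflectivity
tissue, the bright RPE band, dark background), optionally carrying

* dark elliptical fluid pockets (cysts) inside the tissue,
* vertical shadow stripes that attenuate everything below a stated row
  (a vessel blocking the beam), and
* multiplicative speckle-like noise, ``pixel * (1 + sigma * z)`` with
  standard-normal ``z``.

Before noise the clean scene is smoothed with a small isotropic
Gaussian (default 0.8 px) standing in for the system point-spread
function; real band interfaces are never single-pixel steps.  The
ground truth (cyst mask, shadow columns, cystic/non-cystic label) is
recorded from the geometry, not from the rendered image.

The generator emulates the second-order intensity structure the
detector consumes — local means and directional differences — not the
physics of OCT speckle (which is non-Gaussian) nor foveal curvature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .maps import GrayImage

__all__ = [
    "Layer",
    "Cyst",
    "Shadow",
    "PhantomSpec",
    "PhantomScan",
    "dme_like",
    "generate_phantom",
    "generate_batch",
    "save_phantom",
]


@dataclass(frozen=True)
class Layer:
    """Horizontal band: rows ``top..bottom`` inclusive at one intensity.

    ``ramp_rows`` spreads the transition from the band above over the
    first rows of this band as a linear ramp (0 keeps a sharp interface
    with a single intermediate row).  Gradual tapers model reflectivity
    fading smoothly between layer complexes.
    """

    top: int
    bottom: int
    intensity: float
    ramp_rows: int = 0


@dataclass(frozen=True)
class Cyst:
    """Dark ellipse: center (row, col), semi-axes in rows/cols, interior intensity."""

    center_row: float
    center_col: float
    semi_rows: float
    semi_cols: float
    intensity: float = 35.0


@dataclass(frozen=True)
class Shadow:
    """Column range ``start..end`` inclusive, attenuated by ``factor`` below ``from_row``."""

    start: int
    end: int
    factor: float = 0.35
    from_row: int = 30


@dataclass(frozen=True)
class PhantomSpec:
    m: int = 100
    n: int = 256
    layers: tuple[Layer, ...] = ()
    cysts: tuple[Cyst, ...] = ()
    shadows: tuple[Shadow, ...] = ()
    noise_sigma: float = 0.05
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 7 or self.n < 7:
            raise ValueError("phantom must be at least 7x7")
        if not (0.0 <= self.noise_sigma < 1.0):
            raise ValueError("noise_sigma must lie in [0, 1)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        rows = 0
        for lay in self.layers:
            if lay.top != rows or lay.bottom < lay.top:
                raise ValueError(
                    "layers must be ordered top to bottom, non-overlapping and cover the image"
                )
            rows = lay.bottom + 1
        if self.layers and rows != self.m:
            raise ValueError(f"layers cover rows 0..{rows - 1}, expected 0..{self.m - 1}")
        for sh in self.shadows:
            if not (0.0 < sh.factor < 1.0):
                raise ValueError("shadow attenuation factor must lie in (0, 1)")
            if not (0 <= sh.start <= sh.end < self.n):
                raise ValueError("shadow column range outside the image")


@dataclass(frozen=True)
class PhantomScan:
    """Rendered phantom plus its ground truth."""

    image: GrayImage
    truth_label: str  # "cystic" | "non-cystic"
    cyst_mask: np.ndarray = field(repr=False)
    true_shadow_columns: frozenset[int]
    spec: PhantomSpec


def dme_like(
    *,
    cystic: bool = True,
    shadows: tuple[Shadow, ...] = (),
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> PhantomSpec:
    """The default 100 x 256 macular-edema-like preset.

    Dark vitreous above, a bright inner band rows 20-28 at 165, mid
    tissue rows 29-73 at 120, a thin bright RPE band rows 74-78 at 220,
    dark surround at 30; one wide flat cyst (semi-axes 10 rows x 24
    cols, interior 35) centered at (50, 128) when ``cystic``.

    The RPE band is deliberately thinner than ``floor(alpha*m)`` rows
    for the default shadow quantile ``alpha = 0.08`` (8 rows at
    ``m = 100``): the brightness cutoff ``m_th`` then falls below the
    RPE values, onto the next-brightest structure, which is the regime
    in which the per-column transition tracker certifies the RPE lower
    edge.  Real scans satisfy this naturally (hundreds of rows against
    a 15-20 px RPE band).
    """
    layers = (
        Layer(0, 19, 30.0),
        Layer(20, 28, 165.0),
        Layer(29, 73, 120.0, ramp_rows=8),
        Layer(74, 78, 220.0),
        Layer(79, 99, 30.0),
    )
    cysts = (Cyst(50.0, 128.0, 10.0, 24.0, 35.0),) if cystic else ()
    return PhantomSpec(
        m=100,
        n=256,
        layers=layers,
        cysts=cysts,
        shadows=shadows,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _ellipse_mask(m: int, n: int, cyst: Cyst) -> np.ndarray:
    rr, cc = np.ogrid[:m, :n]
    return ((rr - cyst.center_row) / cyst.semi_rows) ** 2 + (
        (cc - cyst.center_col) / cyst.semi_cols
    ) ** 2 < 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomScan:
    """Render one phantom: bands, cysts, shadows, PSF blur, speckle."""
    img = np.zeros((spec.m, spec.n), dtype=np.float64)
    for lay in spec.layers:
        img[lay.top : lay.bottom + 1, :] = lay.intensity
    # band interfaces: either a linear ramp over the first rows of the
    # lower band, or a one-row intermediate value.  Real interfaces are
    # never single-pixel steps, and an exact two-level step would put a
    # spurious symmetry (tied difference values) into every boundary.
    for upper, lower in zip(spec.layers, spec.layers[1:]):
        k = min(lower.ramp_rows, lower.bottom - lower.top)
        if k > 0:
            frac = np.arange(1, k + 1) / (k + 1)
            ramp = upper.intensity + frac * (lower.intensity - upper.intensity)
            img[lower.top : lower.top + k, :] = ramp[:, None]
        else:
            img[lower.top, :] = 0.5 * (upper.intensity + lower.intensity)

    cyst_mask = np.zeros((spec.m, spec.n), dtype=bool)
    for cyst in spec.cysts:
        mask = _ellipse_mask(spec.m, spec.n, cyst)
        img[mask] = cyst.intensity
        cyst_mask |= mask

    true_shadow: set[int] = set()
    for sh in spec.shadows:
        img[sh.from_row :, sh.start : sh.end + 1] *= sh.factor
        true_shadow.update(range(sh.start, sh.end + 1))

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma, mode="nearest")

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img * (1.0 + spec.noise_sigma * rng.standard_normal(img.shape))

    img = np.clip(img, 0.0, 255.0)
    return PhantomScan(
        image=GrayImage(img),
        truth_label="cystic" if cyst_mask.any() else "non-cystic",
        cyst_mask=cyst_mask,
        true_shadow_columns=frozenset(true_shadow),
        spec=spec,
    )


def generate_batch(
    n_cystic: int,
    n_clean: int,
    n_shadow_only: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomScan]:
    """Generate a labeled batch with randomized cyst and shadow geometry.

    Cystic scans carry one cyst with center row U[42, 58], center col
    U[50, n-50], semi-axes U[7, 13] rows x U[16, 28] cols; shadow-only
    scans carry one stripe with start col U[30, n-45], width U[9, 15]
    and attenuation U[0.2, 0.5].  Reproducible for a fixed seed.
    """
    if min(n_cystic, n_clean, n_shadow_only) < 0:
        raise ValueError("scan counts must be >= 0")
    base = base_spec or dme_like(cystic=False)
    base = replace(base, cysts=(), shadows=())
    rng = np.random.default_rng(seed)
    scans: list[PhantomScan] = []

    def draw_cyst() -> Cyst:
        return Cyst(
            center_row=rng.uniform(42, 58),
            center_col=rng.uniform(50, base.n - 50),
            semi_rows=rng.uniform(7, 13),
            semi_cols=rng.uniform(16, 28),
            intensity=35.0,
        )

    def draw_shadow() -> Shadow:
        start = int(rng.integers(30, base.n - 45))
        width = int(rng.integers(9, 16))
        return Shadow(start=start, end=start + width - 1, factor=float(rng.uniform(0.2, 0.5)))

    for _ in range(n_cystic):
        spec = replace(base, cysts=(draw_cyst(),), seed=int(rng.integers(0, 2**31 - 1)))
        scans.append(generate_phantom(spec))
    for _ in range(n_clean):
        spec = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        scans.append(generate_phantom(spec))
    for _ in range(n_shadow_only):
        spec = replace(base, shadows=(draw_shadow(),), seed=int(rng.integers(0, 2**31 - 1)))
        scans.append(generate_phantom(spec))
    return scans


def save_phantom(scan: PhantomScan, out_dir: str | Path, stem: str = "phantom") -> dict:
    """Write image, cyst mask (8-bit PNGs) and truth sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.png"
    iio.imwrite(img_path, np.round(scan.image.pixels).astype(np.uint8))
    mask_path = out / f"{stem}_mask.png"
    iio.imwrite(mask_path, (scan.cyst_mask * 255).astype(np.uint8))
    truth = {
        "label": scan.truth_label,
        "shadow_columns": sorted(int(c) + 1 for c in scan.true_shadow_columns),
    }
    truth_path = out / f"{stem}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"image": str(img_path), "mask": str(mask_path), "truth": str(truth_path)}
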