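"""Cyst-boundary pixel determination by directional patch voting.

A cyst appears as a dark fluid pocket inside brighter retinal tissue.
Its top boundary produces, going down each column, a significant
light-to-dark transition; its flanking walls descend from that entrance
point on both sides and produce significant diagonal light-to-dark
transitions.  The detector therefore:

1. collects *seed* pixels ``V`` — strict vertical local maxima of ``dv``
   exceeding the significance threshold ``thv`` with ``dv > 0``;
2. collects diagonal-change sets ``L`` (via ``dl``) and ``R`` (via
   ``dr``) under the analogous three conditions;
3. for every seed, forms an ``s x t`` rectangular patch immediately to
   its left and another to its right and counts the members of ``L``
   (resp. ``R``) inside; a patch holding strictly more than ``num``
   members is accepted as a cyst-boundary region.

Patches are anchored just *below* the seed row (rows ``i+1 .. i+s``):
the fluid pocket and its descending walls lie below the entrance point,
whereas a straight horizontal layer boundary concentrates all of its
diagonal-change pixels on the seed row itself.  Anchoring below the
seed therefore keeps ordinary layer interfaces — which every B-scan
contains — from voting themselves into cyst candidates, while the
curved cyst walls, which drop below the entrance row, still fill the
patch.  A ``centered`` alignment is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .maps import DiffMaps, GrayImage, compute_diff_maps, local_max_mask

__all__ = [
    "DetectionParams",
    "CandidateSets",
    "CystCandidate",
    "find_vertical_seeds",
    "find_diagonal_sets",
    "detect_candidates",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the boundary-pixel determination stage.

    ``thv`` is the absolute significance threshold on the difference
    maps (intensity units on the [0, 255] scale).  When left ``None``
    it is resolved per image as ``thv_rel`` times the intensity range
    of the (denoised) image, which keeps behavior stable across
    acquisition brightness.
    """

    a: int = 1
    b: int = 1
    s: int = 11
    t: int = 11
    num: int = 10
    thv: float | None = None
    thv_rel: float = 0.08
    patch_align: Literal["below", "centered"] = "below"

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise ValueError("window half-widths a, b must be >= 1")
        if self.s < 1 or self.t < 1:
            raise ValueError("patch dimensions s, t must be >= 1")
        if self.num < 0:
            raise ValueError("acceptance threshold num must be >= 0")
        if self.num >= self.s * self.t:
            raise ValueError("num must be smaller than the patch area s*t")
        if self.thv is not None and self.thv <= 0:
            raise ValueError("thv must be positive")
        if not (0 < self.thv_rel < 1):
            raise ValueError("thv_rel must lie in (0, 1)")
        if self.patch_align not in ("below", "centered"):
            raise ValueError("patch_align must be 'below' or 'centered'")

    def resolve_thv(self, img: GrayImage | np.ndarray) -> float:
        """Absolute threshold for this image (fixed or range-relative)."""
        if self.thv is not None:
            return float(self.thv)
        px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
        return self.thv_rel * float(px.max() - px.min())


@dataclass(frozen=True)
class CandidateSets:
    """Boolean membership masks for the seed and diagonal-change sets."""

    V: np.ndarray
    L: np.ndarray
    R: np.ndarray


@dataclass(frozen=True)
class CystCandidate:
    """An accepted seed pixel with its voting patch.

    Coordinates are 0-based (row, col); ``to_dict`` reports 1-based.
    ``row_range``/``col_range`` are inclusive patch bounds after
    clipping to the image.  ``members`` lists the diagonal-change
    pixels counted inside the patch.
    """

    seed: tuple[int, int]
    side: Literal["left", "right"]
    row_range: tuple[int, int]
    col_range: tuple[int, int]
    members: tuple[tuple[int, int], ...] = field(repr=False)
    member_count: int

    def to_dict(self) -> dict:
        return {
            "seed_row": self.seed[0] + 1,
            "seed_col": self.seed[1] + 1,
            "side": self.side,
            "patch_rows": [self.row_range[0] + 1, self.row_range[1] + 1],
            "patch_cols": [self.col_range[0] + 1, self.col_range[1] + 1],
            "member_count": self.member_count,
            "members": [[i + 1, j + 1] for i, j in self.members],
        }


def find_vertical_seeds(diff: DiffMaps, thv: float) -> np.ndarray:
    """Mask of seed pixels: strict vertical local maxima of ``dv`` that
    are positive (light above, dark below) and exceed ``thv``."""
    if thv <= 0:
        raise ValueError("thv must be positive")
    return local_max_mask(diff.dv, "vertical") & (diff.dv > thv) & (diff.dv > 0)


def find_diagonal_sets(diff: DiffMaps, thv: float) -> tuple[np.ndarray, np.ndarray]:
    """Masks of the left- and right-diagonal significant-change sets."""
    if thv <= 0:
        raise ValueError("thv must be positive")
    L = local_max_mask(diff.dl, "diag-down-right") & (diff.dl > thv) & (diff.dl > 0)
    R = local_max_mask(diff.dr, "diag-down-left") & (diff.dr > thv) & (diff.dr > 0)
    return L, R


def candidate_sets(diff: DiffMaps, thv: float) -> CandidateSets:
    L, R = find_diagonal_sets(diff, thv)
    return CandidateSets(V=find_vertical_seeds(diff, thv), L=L, R=R)


def _integral(mask: np.ndarray) -> np.ndarray:
    s = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    s[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    return s


def _box_count(integral: np.ndarray, r1: int, r2: int, c1: int, c2: int) -> int:
    return int(
        integral[r2 + 1, c2 + 1]
        - integral[r1, c2 + 1]
        - integral[r2 + 1, c1]
        + integral[r1, c1]
    )


def _patch_rows(i: int, s: int, m: int, align: str) -> tuple[int, int] | None:
    if align == "below":
        r1, r2 = i + 1, i + s
    else:  # centered, extra row below for even s
        r1 = i - s // 2
        r2 = r1 + s - 1
    r1, r2 = max(r1, 0), min(r2, m - 1)
    return (r1, r2) if r1 <= r2 else None


def detect_candidates(
    img: GrayImage | np.ndarray,
    params: DetectionParams | None = None,
    diff: DiffMaps | None = None,
) -> list[CystCandidate]:
    """Run the full boundary-pixel determination stage on one image.

    Returns one candidate per accepted patch; a seed passing on both
    sides yields two candidates.  Patches reaching past the image are
    clipped; the acceptance count ``num`` is not rescaled for clipped
    patches.
    """
    params = params or DetectionParams()
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if diff is None:
        diff = compute_diff_maps(px, params.a, params.b)
    thv = params.resolve_thv(px)
    sets = candidate_sets(diff, thv)
    m, n = px.shape
    int_L, int_R = _integral(sets.L), _integral(sets.R)

    candidates: list[CystCandidate] = []
    for i, j in np.argwhere(sets.V):
        rows = _patch_rows(int(i), params.s, m, params.patch_align)
        if rows is None:
            continue
        r1, r2 = rows
        for side, mask, integ, c1, c2 in (
            ("left", sets.L, int_L, j - params.t, j - 1),
            ("right", sets.R, int_R, j + 1, j + params.t),
        ):
            c1c, c2c = max(int(c1), 0), min(int(c2), n - 1)
            if c1c > c2c:
                continue
            count = _box_count(integ, r1, r2, c1c, c2c)
            if count > params.num:
                members = tuple(
                    (int(r) + r1, int(c) + c1c)
                    for r, c in np.argwhere(mask[r1 : r2 + 1, c1c : c2c + 1])
                )
                candidates.append(
                    CystCandidate(
                        seed=(int(i), int(j)),
                        side=side,
                        row_range=(r1, r2),
                        col_range=(c1c, c2c),
                        members=members,
                        member_count=count,
                    )
                )
    return candidates
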