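"""Result serialization and overlay rendering.

Candidates and shadow profiles go out as JSON (full payload, 1-based
coordinates) or CSV (one row per candidate); overlays draw each
accepted patch as a blue rectangle with a red circle on its seed pixel
and mark shadow columns with orange ticks along the top edge.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .boundary import CystCandidate
from .maps import GrayImage
from .pipeline import ScanResult

__all__ = [
    "result_to_json",
    "candidates_to_csv",
    "batch_to_csv",
    "render_overlay",
]


def result_to_json(result: ScanResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=1))


def candidates_to_csv(
    candidates: Sequence[CystCandidate], path: str | Path
) -> pd.DataFrame:
    """One row per candidate (1-based coordinates); also written to ``path``."""
    rows = []
    for c in candidates:
        d = c.to_dict()
        rows.append(
            {
                "seed_row": d["seed_row"],
                "seed_col": d["seed_col"],
                "side": d["side"],
                "patch_row_start": d["patch_rows"][0],
                "patch_row_end": d["patch_rows"][1],
                "patch_col_start": d["patch_cols"][0],
                "patch_col_end": d["patch_cols"][1],
                "member_count": d["member_count"],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "seed_row",
            "seed_col",
            "side",
            "patch_row_start",
            "patch_row_end",
            "patch_col_start",
            "patch_col_end",
            "member_count",
        ],
    )
    df.to_csv(path, index=False)
    return df


def batch_to_csv(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
    return df


def render_overlay(
    img: GrayImage,
    candidates: Sequence[CystCandidate] = (),
    shadow_columns: np.ndarray | Sequence[int] = (),
    path: str | Path | None = None,
) -> Image.Image:
    """Render detection results over the B-scan as an RGB image."""
    base = np.round(img.pixels).astype(np.uint8)
    rgb = Image.fromarray(np.stack([base] * 3, axis=-1))
    draw = ImageDraw.Draw(rgb)
    for col in shadow_columns:
        draw.line([(int(col), 0), (int(col), 4)], fill=(255, 165, 0), width=1)
    for c in candidates:
        (r1, r2), (c1, c2) = c.row_range, c.col_range
        draw.rectangle([c1, r1, c2, r2], outline=(60, 100, 255), width=1)
        i, j = c.seed
        draw.ellipse([j - 2, i - 2, j + 2, i + 2], outline=(255, 40, 40), width=1)
    if path is not None:
        rgb.save(Path(path))
    return rgb
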