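"""Pseudo-color class maps and single-band contrast images.

The classified raster is rendered with one saturated color per
histologic class, black for unclassified tissue and white for
non-tissue background — a stain-free analog of an H&E overview.
Single-band images (e.g. absorbance at 1236 cm^-1, the collagen-heavy
amide III band) use a robust 1st-99th percentile contrast stretch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import BaselineAnchors, DEFAULT_ANCHORS, PixelMask, baseline_correct
from .spectral_io import CLASS_NAMES, SpectralCube

__all__ = [
    "Palette",
    "DEFAULT_PALETTE",
    "band_image",
    "class_image",
    "codes_from_image",
    "save_png",
]


@dataclass(frozen=True)
class Palette:
    """Class-code -> RGB mapping; colors must be pairwise distinct."""

    colors: dict[int, tuple[int, int, int]]
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        seen = list(self.colors.values()) + [self.background]
        if len(set(seen)) != len(seen):
            raise ValueError("palette colors must be unique")

    def legend(self) -> dict[str, tuple[int, int, int]]:
        return {CLASS_NAMES.get(code, str(code)): rgb
                for code, rgb in sorted(self.colors.items())}

    def write_legend(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {name: list(rgb) for name, rgb in self.legend().items()}, indent=1))


DEFAULT_PALETTE = Palette({
    0: (0, 0, 0),          # unclassified: black
    1: (178, 34, 34),      # myocardium: firebrick
    2: (255, 200, 70),     # endocardium: gold
    3: (65, 105, 225),     # fibrosis-endocardium: royal blue
    4: (148, 0, 211),      # fibrosis-myocardium: violet
    5: (0, 190, 80),       # lymphocytes: green
})


def band_image(cube: SpectralCube, band: float, mask: PixelMask | None = None,
               anchors: BaselineAnchors = DEFAULT_ANCHORS,
               stretch: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Grayscale image of baseline-corrected absorbance at the band
    nearest ``band`` (cm^-1).

    Values are linearly mapped to [0, 255] over the ``stretch`` percentile
    range of kept pixels (masked pixels render as 0).  A constant image
    maps to mid-gray.
    """
    idx = cube.axis.index_of(band)
    corrected = baseline_correct(cube.data, cube.axis, anchors)[:, :, idx].astype(np.float64)
    keep = np.ones(corrected.shape, dtype=bool) if mask is None else mask.keep
    if not keep.any():
        raise ValueError("no kept pixels to stretch over")
    lo, hi = np.percentile(corrected[keep], stretch)
    if hi <= lo:
        out = np.full(corrected.shape, 127, dtype=np.uint8)
    else:
        scaled = np.clip((corrected - lo) / (hi - lo), 0.0, 1.0) * 255.0
        out = np.rint(scaled).astype(np.uint8)
    out[~keep] = 0
    return out


def class_image(pred: np.ndarray, palette: Palette = DEFAULT_PALETTE,
                mask: PixelMask | None = None) -> np.ndarray:
    """RGB rendering of a class map: per-pixel palette lookup; with a
    mask, non-tissue pixels render in the background color."""
    pred = np.asarray(pred)
    codes = np.unique(pred)
    unknown = [int(c) for c in codes if int(c) not in palette.colors]
    if unknown:
        raise ValueError(f"palette lacks colors for class codes {unknown}")
    lut = np.zeros((max(palette.colors) + 1, 3), dtype=np.uint8)
    for code, rgb in palette.colors.items():
        lut[code] = rgb
    rgb = lut[pred]
    if mask is not None:
        rgb[~mask.keep] = palette.background
    return rgb


def codes_from_image(rgb: np.ndarray, palette: Palette = DEFAULT_PALETTE) -> np.ndarray:
    """Exact inverse of :func:`class_image` (background maps to 0)."""
    rgb = np.asarray(rgb)
    out = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for code, color in palette.colors.items():
        out[np.all(rgb == np.asarray(color, dtype=np.uint8), axis=-1)] = code
    out[np.all(rgb == np.asarray(palette.background, dtype=np.uint8), axis=-1)] = 0
    if np.any(out < 0):
        raise ValueError("image contains colors outside the palette")
    return out


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Write a uint8 grayscale or RGB array as PNG."""
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(Path(path))
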