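"""Pixel masking, two-point baseline correction, amide-I normalization
and a residual-paraffin QC score.

All spectral functions are vectorized: a "spectrum" argument may be a
single 1-D array or any ``(..., n_bands)`` stack, with the wavenumber
axis passed alongside.

Order matters in this pipeline: the tissue mask is computed on *raw*
absorbance (the amide-I threshold reads sample thickness, which
normalization would erase), then baseline correction, then amide-I
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_io import SpectralCube, WavenumberAxis

__all__ = [
    "AMIDE_I",
    "AMIDE_II",
    "PARAFFIN_BAND",
    "DEFAULT_AMIDE_THRESHOLD",
    "DEFAULT_HALF_WINDOW",
    "PixelMask",
    "BaselineAnchors",
    "DEFAULT_ANCHORS",
    "amide_mask",
    "baseline_correct",
    "normalize_amide1",
    "preprocess_cube",
    "paraffin_residual_score",
]

#: Protein amide I band (C=O stretch), the normalization anchor, cm^-1.
AMIDE_I = 1652.0
#: Protein amide II band, cm^-1.
AMIDE_II = 1543.0
#: Paraffin CH-bending band, cm^-1.
PARAFFIN_BAND = 1464.0
#: Minimum raw amide-I absorbance for a pixel to count as tissue (AU).
DEFAULT_AMIDE_THRESHOLD = 0.30
#: Half-width of the window used for named peak-height lookups (cm^-1).
DEFAULT_HALF_WINDOW = 6.0


@dataclass
class PixelMask:
    """Boolean keep-raster paired with a cube's spatial dimensions."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass(frozen=True)
class BaselineAnchors:
    """Fixed anchor wavenumber pairs for two-point linear correction.

    The same anchors are applied to every spectrum.  Pairs must not
    overlap: each band belongs to at most one correction interval.
    """

    pairs: tuple[tuple[float, float], ...]

    def __init__(self, pairs) -> None:
        pairs = tuple((float(l), float(r)) for l, r in pairs)
        for l, r in pairs:
            if not l < r:
                raise ValueError(f"anchor pair ({l:g}, {r:g}) must satisfy left < right")
        ordered = sorted(pairs)
        for (_, r1), (l2, _) in zip(ordered, ordered[1:]):
            if l2 < r1:
                raise ValueError("baseline anchor pairs overlap")
        object.__setattr__(self, "pairs", pairs)


#: Default anchors: one pair spanning the fingerprint/amide region, one the
#: amide-A region.  Chosen to sit in signal-free spectral windows.
DEFAULT_ANCHORS = BaselineAnchors(((900.0, 1800.0), (2800.0, 3600.0)))


def _window_max(spectra: np.ndarray, axis_values: WavenumberAxis, center: float,
                half_window: float = DEFAULT_HALF_WINDOW) -> np.ndarray:
    i0, i1 = axis_values.slice_indices(center - half_window, center + half_window)
    return np.max(spectra[..., i0:i1 + 1], axis=-1)


def amide_mask(cube: SpectralCube, threshold: float = DEFAULT_AMIDE_THRESHOLD) -> PixelMask:
    """Keep pixels whose *raw* absorbance at the band nearest amide I
    (1652 cm^-1) is >= ``threshold`` (inclusive).

    Pixels below threshold lack protein-characteristic absorbance and are
    treated as non-tissue (bare substrate, gaps between stitched tiles).
    """
    idx = cube.axis.index_of(AMIDE_I)  # raises if the axis misses the region
    return PixelMask(cube.data[:, :, idx] >= threshold)


def baseline_correct(spectra: np.ndarray, axis: WavenumberAxis,
                     anchors: BaselineAnchors = DEFAULT_ANCHORS) -> np.ndarray:
    """Two-point linear baseline correction with fixed anchors.

    For each anchor pair the straight line through the spectrum's values at
    the two anchor bands is subtracted over the closed interval between
    them; the corrected value at both anchors is exactly zero.  Bands
    outside every pair are left unchanged.  Idempotent per pair.
    """
    spectra = np.asarray(spectra)
    out = spectra.copy()
    v = axis.values
    for left, right in anchors.pairs:
        i0 = axis.index_of(left)
        i1 = axis.index_of(right)
        if i1 <= i0:
            raise ValueError(f"anchor pair ({left:g}, {right:g}) collapses on this axis")
        y0 = spectra[..., i0]
        y1 = spectra[..., i1]
        frac = (v[i0:i1 + 1] - v[i0]) / (v[i1] - v[i0])
        line = y0[..., None] + (y1 - y0)[..., None] * frac
        out[..., i0:i1 + 1] = spectra[..., i0:i1 + 1] - line
    return out


def normalize_amide1(spectra: np.ndarray, axis: WavenumberAxis,
                     half_window: float = DEFAULT_HALF_WINDOW):
    """Divide each (baseline-corrected) spectrum by its amide-I peak height.

    The height is the windowed maximum around 1652 cm^-1 (see
    :func:`irhisto.metrics.peak_height`).  Returns ``(normalized, ok)``
    where ``ok`` flags spectra with positive height; spectra with
    non-positive height are returned unscaled and must be routed to the
    unclassified category downstream (they are kept in the raster so
    rendered images stay aligned).
    """
    spectra = np.asarray(spectra)
    height = _window_max(spectra, axis, AMIDE_I, half_window)
    ok = height > 0
    safe = np.where(ok, height, 1.0)
    normalized = spectra / safe[..., None]
    if spectra.ndim == 1:
        return normalized, bool(ok)
    return normalized, ok


def preprocess_cube(cube: SpectralCube,
                    threshold: float = DEFAULT_AMIDE_THRESHOLD,
                    anchors: BaselineAnchors = DEFAULT_ANCHORS,
                    half_window: float = DEFAULT_HALF_WINDOW):
    """Full preprocessing: amide mask -> baseline correction -> amide-I
    normalization.

    Returns ``(processed_cube, mask, stats)``.  ``mask.keep`` is True for
    pixels that both pass the raw amide threshold and normalize cleanly;
    ``stats`` reports the two exclusion counts separately.
    """
    mask = amide_mask(cube, threshold)
    corrected = baseline_correct(cube.data, cube.axis, anchors)
    normalized, ok = normalize_amide1(corrected, cube.axis, half_window)
    stats = {
        "n_pixels": cube.n_pixels,
        "n_below_amide_threshold": int((~mask.keep).sum()),
        "n_failed_normalization": int((mask.keep & ~ok).sum()),
    }
    keep = mask.keep & ok
    processed = SpectralCube(
        normalized.astype(np.float32), cube.axis, cube.pixel_pitch,
        cube.provenance + "; baseline-corrected, amide-I normalized",
    )
    return processed, PixelMask(keep), stats


# ---------------------------------------------------------------------------
# Residual paraffin QC
# ---------------------------------------------------------------------------

#: Fit window and component bands for the paraffin estimator (cm^-1).
_PARAFFIN_WINDOW = (1424.0, 1504.0)
_CH2_BEND = 1452.0
_PARAFFIN_FWHM = 25.0


def _gaussian(v: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-4.0 * np.log(2.0) * ((v - center) / fwhm) ** 2)


def paraffin_residual_score(cube: SpectralCube, mask: PixelMask,
                            anchors: BaselineAnchors = DEFAULT_ANCHORS,
                            half_window: float = DEFAULT_HALF_WINDOW) -> float:
    """Residual-paraffin QC score: mean amide-normalized amplitude of the
    1464 cm^-1 CH-bending band over kept pixels.

    The tissue CH2-bending band at 1452 cm^-1 overlaps 1464 cm^-1 heavily,
    so a plain band-height readout is biased by ~0.1 AU even on fully
    de-paraffinized tissue.  The amplitude is therefore estimated per pixel
    by linear least squares over 1424-1504 cm^-1 with four components:
    constant, linear slope, a unit Gaussian at 1452 and a unit Gaussian at
    1464 (both FWHM 25 cm^-1).  The 1464 coefficient, divided by the
    baseline-corrected amide-I height, is averaged over kept pixels.

    This is a QC number, not a gate: ~0 on clean tissue, and approximately
    the contaminating peak height (in amide-normalized AU) otherwise.
    """
    if mask.keep.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if mask.n_kept == 0:
        raise ValueError("paraffin score undefined: no kept pixels")
    cube.axis.index_of(PARAFFIN_BAND)  # raises if the region is absent

    corrected = baseline_correct(cube.data[mask.keep], cube.axis, anchors).astype(np.float64)
    amide = _window_max(corrected, cube.axis, AMIDE_I, half_window)
    if np.any(amide <= 0):
        raise ValueError("paraffin score undefined: non-positive amide-I height in mask")

    i0, i1 = cube.axis.slice_indices(*_PARAFFIN_WINDOW)
    v = cube.axis.values[i0:i1 + 1]
    design = np.column_stack([
        np.ones_like(v),
        v - PARAFFIN_BAND,
        _gaussian(v, _CH2_BEND, _PARAFFIN_FWHM),
        _gaussian(v, PARAFFIN_BAND, _PARAFFIN_FWHM),
    ])
    coeffs, *_ = np.linalg.lstsq(design, corrected[:, i0:i1 + 1].T, rcond=None)
    return float(np.mean(coeffs[3] / amide))
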