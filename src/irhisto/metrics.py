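"""Spectral metric extraction.

Four metric families reduce each pixel's spectrum to scalar features:

- ``peak_height_ratio``   — ratio of two windowed peak heights;
- ``area_to_height_ratio``— band area (above a local two-point baseline)
  divided by a peak height;
- ``area_to_area_ratio``  — ratio of two band areas;
- ``center_of_gravity``   — absorbance-weighted mean wavenumber over a band.

Ratios of heights and areas are exactly invariant under multiplicative
scaling of the spectrum, which makes them robust to residual thickness
and instrument-response variation.  All functions accept a single 1-D
spectrum or any ``(..., n_bands)`` stack.

Undefined values (vanishing denominators, non-positive weights) come back
as NaN; the classifier treats NaN as "metric missing for this pixel".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import DEFAULT_HALF_WINDOW, PixelMask
from .spectral_io import SpectralCube, WavenumberAxis

__all__ = [
    "EPS_DENOM",
    "MetricDefinition",
    "FeatureImage",
    "peak_height",
    "peak_height_ratio",
    "band_area",
    "area_to_height_ratio",
    "area_to_area_ratio",
    "center_of_gravity",
    "evaluate_metric",
    "default_metric_library",
    "annotated_bands",
    "save_metric_library",
    "load_metric_library",
    "compute_features",
]

#: Denominators with magnitude at or below this are treated as undefined.
EPS_DENOM = 1e-6

_KIND_NPARAMS = {
    "peak_height_ratio": 2,
    "area_to_height_ratio": 3,
    "area_to_area_ratio": 4,
    "center_of_gravity": 4,
}


@dataclass(frozen=True)
class MetricDefinition:
    """One spectral-feature recipe.

    ``params`` are wavenumbers in cm^-1, by kind:

    - peak_height_ratio:    (peak1, peak2)
    - area_to_height_ratio: (area_left, area_right, peak)
    - area_to_area_ratio:   (left1, right1, left2, right2)
    - center_of_gravity:    (left, right, cg1, cg2) — local baseline anchored
      at (left, right); the weighted mean is taken over [cg1, cg2]
    """

    name: str
    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KIND_NPARAMS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _KIND_NPARAMS[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_KIND_NPARAMS[self.kind]} wavenumbers, got {len(params)}"
            )
        if self.kind == "area_to_height_ratio" and not params[0] < params[1]:
            raise ValueError("area bounds must satisfy left < right")
        if self.kind == "area_to_area_ratio":
            if not (params[0] < params[1] and params[2] < params[3]):
                raise ValueError("area bounds must satisfy left < right")
        if self.kind == "center_of_gravity":
            if not (params[0] < params[1] and params[2] < params[3]):
                raise ValueError("bounds must satisfy left < right")


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------

def peak_height(spectra, axis: WavenumberAxis, center: float,
                half_window: float = DEFAULT_HALF_WINDOW):
    """Peak height at a named band: the maximum absorbance within
    ``center +- half_window``.

    The windowed maximum (rather than a fixed-band lookup) tolerates small
    calibration jitter of the band position; the spectrum is expected to be
    baseline-corrected already.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    i0, i1 = axis.slice_indices(center - half_window, center + half_window)
    out = np.max(spectra[..., i0:i1 + 1], axis=-1)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def peak_height_ratio(spectra, axis: WavenumberAxis, p1: float, p2: float,
                      half_window: float = DEFAULT_HALF_WINDOW):
    """peak_height(p1) / peak_height(p2); NaN where the denominator
    magnitude is <= EPS_DENOM."""
    num = np.asarray(peak_height(spectra, axis, p1, half_window), dtype=np.float64)
    den = np.asarray(peak_height(spectra, axis, p2, half_window), dtype=np.float64)
    ok = np.abs(den) > EPS_DENOM
    out = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def band_area(spectra, axis: WavenumberAxis, left: float, right: float):
    """Trapezoidal integral of absorbance above the straight line joining
    the spectrum's values at ``left`` and ``right`` (local two-point
    baseline), in AU * cm^-1.  May be negative if the band dips below its
    own chord."""
    if not left < right:
        raise ValueError("band area bounds must satisfy left < right")
    spectra = np.asarray(spectra, dtype=np.float64)
    i0 = axis.index_of(left)
    i1 = axis.index_of(right)
    if i1 <= i0:
        raise ValueError("band area interval collapses on this axis")
    v = axis.values[i0:i1 + 1]
    seg = spectra[..., i0:i1 + 1]
    frac = (v - v[0]) / (v[-1] - v[0])
    chord = seg[..., :1] + (seg[..., -1:] - seg[..., :1]) * frac
    out = np.trapezoid(seg - chord, v, axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def area_to_height_ratio(spectra, axis: WavenumberAxis, area_left: float,
                         area_right: float, peak: float,
                         half_window: float = DEFAULT_HALF_WINDOW):
    """band_area(area_left, area_right) / peak_height(peak), in cm^-1."""
    num = np.asarray(band_area(spectra, axis, area_left, area_right), dtype=np.float64)
    den = np.asarray(peak_height(spectra, axis, peak, half_window), dtype=np.float64)
    ok = np.abs(den) > EPS_DENOM
    out = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def area_to_area_ratio(spectra, axis: WavenumberAxis, l1: float, r1: float,
                       l2: float, r2: float):
    num = np.asarray(band_area(spectra, axis, l1, r1), dtype=np.float64)
    den = np.asarray(band_area(spectra, axis, l2, r2), dtype=np.float64)
    ok = np.abs(den) > EPS_DENOM
    out = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def center_of_gravity(spectra, axis: WavenumberAxis, left: float, right: float,
                      weight_left: float | None = None,
                      weight_right: float | None = None):
    """Absorbance-weighted mean wavenumber over a band, in cm^-1.

    The local baseline is the chord anchored at ``left``/``right``;
    baseline-corrected absorbance is clipped at zero before weighting so
    the weighted mean stays well-defined.  Weights are summed over
    ``[weight_left, weight_right]`` (defaulting to the anchor interval
    itself).  NaN where the total weight is <= EPS_DENOM.
    """
    if not left < right:
        raise ValueError("bounds must satisfy left < right")
    wl = left if weight_left is None else weight_left
    wr = right if weight_right is None else weight_right
    spectra = np.asarray(spectra, dtype=np.float64)
    i0 = axis.index_of(left)
    i1 = axis.index_of(right)
    v_full = axis.values[i0:i1 + 1]
    seg = spectra[..., i0:i1 + 1]
    frac = (v_full - v_full[0]) / (v_full[-1] - v_full[0])
    resid = np.clip(seg - (seg[..., :1] + (seg[..., -1:] - seg[..., :1]) * frac), 0.0, None)

    j0 = axis.index_of(wl) - i0
    j1 = axis.index_of(wr) - i0
    if j0 < 0 or j1 > i1 - i0 or j1 <= j0:
        raise ValueError("weight interval must lie within the anchor interval")
    w = resid[..., j0:j1 + 1]
    total = w.sum(axis=-1)
    num = (w * v_full[j0:j1 + 1]).sum(axis=-1)
    ok = total > EPS_DENOM
    out = np.where(ok, num / np.where(ok, total, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Metric library
# ---------------------------------------------------------------------------

#: Peak-height-ratio pairs found useful to differentiate the five classes.
PHR_PAIRS = (
    (1389, 1236), (3315, 1236), (1204, 1236),
    (1027, 1065), (1163, 1236), (1239, 1652),
    (1239, 1543), (1163, 1065), (1236, 1543),
    (1389, 1452), (1452, 1543), (1236, 3300),
    (1239, 3300), (1389, 1652), (1389, 3300),
    (1389, 1065), (1452, 1236), (1027, 1543),
    (1405, 1236), (1155, 1452), (1032, 1236),
)

#: Area-to-height definitions (area_left, area_right, peak).
AHR_TRIPLES = (
    (1482, 1594, 1652),
    (1424, 1480, 1546),
    (1184, 1300, 1652),
)

#: Center-of-gravity definitions (left, right, cg1, cg2).
COG_QUADS = (
    (1184, 1302, 1188, 1216),
    (1482, 1726, 1482, 1594),
    (984, 1144, 1016, 1048),
)


def annotated_bands() -> tuple[float, ...]:
    """Bands annotated in the mean class spectra (cm^-1), used when
    expanding the library with amide-I height ratios."""
    return (1027, 1032, 1065, 1155, 1163, 1204, 1236, 1239,
            1389, 1405, 1452, 1464, 1543, 3300, 3315)


def default_metric_library(extended: bool = False) -> list[MetricDefinition]:
    """The published 27-metric library: 21 peak-height ratios, 3
    area-to-height ratios and 3 center-of-gravity definitions.

    With ``extended=True``, height ratios of every annotated band to
    amide I not already present are appended (a step toward the larger
    metric space the approach supports).
    """
    defs = [
        MetricDefinition(f"phr_{p1}_{p2}", "peak_height_ratio", (p1, p2))
        for p1, p2 in PHR_PAIRS
    ]
    defs += [
        MetricDefinition(f"ahr_{a}_{b}_{p}", "area_to_height_ratio", (a, b, p))
        for a, b, p in AHR_TRIPLES
    ]
    defs += [
        MetricDefinition(f"cog_{a}_{b}_{c}_{d}", "center_of_gravity", (a, b, c, d))
        for a, b, c, d in COG_QUADS
    ]
    if extended:
        existing = {d.params for d in defs if d.kind == "peak_height_ratio"}
        for band in annotated_bands():
            pair = (float(band), 1652.0)
            if pair not in existing:
                defs.append(MetricDefinition(f"phr_{band}_1652", "peak_height_ratio", pair))
    names = [d.name for d in defs]
    assert len(names) == len(set(names))
    return defs


def save_metric_library(defs: list[MetricDefinition], path: str | Path) -> None:
    payload = [{"name": d.name, "kind": d.kind, "params": list(d.params)} for d in defs]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_metric_library(path: str | Path) -> list[MetricDefinition]:
    payload = json.loads(Path(path).read_text())
    return [MetricDefinition(e["name"], e["kind"], tuple(e["params"])) for e in payload]


def evaluate_metric(spectra, axis: WavenumberAxis, mdef: MetricDefinition,
                    half_window: float = DEFAULT_HALF_WINDOW,
                    cog_mode: str = "anchored"):
    """Evaluate one metric definition on spectra.

    ``cog_mode`` selects the reading of the center-of-gravity parameters:

    - ``"anchored"`` (default): weighted mean over [cg1, cg2] with the
      local baseline anchored at [left, right];
    - ``"normalized"``: weighted mean over [left, right], affinely mapped
      so cg1 -> 0 and cg2 -> 1.
    """
    p = mdef.params
    if mdef.kind == "peak_height_ratio":
        return peak_height_ratio(spectra, axis, p[0], p[1], half_window)
    if mdef.kind == "area_to_height_ratio":
        return area_to_height_ratio(spectra, axis, p[0], p[1], p[2], half_window)
    if mdef.kind == "area_to_area_ratio":
        return area_to_area_ratio(spectra, axis, p[0], p[1], p[2], p[3])
    if mdef.kind == "center_of_gravity":
        if cog_mode == "anchored":
            return center_of_gravity(spectra, axis, p[0], p[1], p[2], p[3])
        if cog_mode == "normalized":
            cg = center_of_gravity(spectra, axis, p[0], p[1])
            return (cg - p[2]) / (p[3] - p[2])
        raise ValueError(f"unknown cog_mode {cog_mode!r}")
    raise AssertionError(mdef.kind)


@dataclass
class FeatureImage:
    """Per-pixel metric values: ``values[rows, cols, n_metrics]``.

    Masked-out pixels carry NaN in every metric; kept pixels may carry NaN
    in individual metrics where those are undefined.
    """

    values: np.ndarray
    metric_names: list[str]
    mask: PixelMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.metric_names):
            raise ValueError("values must be rows x cols x n_metrics")
        if self.values.shape[:2] != self.mask.keep.shape:
            raise ValueError("mask shape does not match feature image")

    @property
    def n_metrics(self) -> int:
        return len(self.metric_names)

    def kept_matrix(self) -> np.ndarray:
        """(n_kept, n_metrics) view of kept-pixel feature vectors."""
        return self.values[self.mask.keep]

    def to_dataframe(self):
        import pandas as pd

        rows, cols = np.nonzero(self.mask.keep)
        return pd.DataFrame(
            {"row": rows, "col": cols,
             **{name: self.values[rows, cols, j]
                for j, name in enumerate(self.metric_names)}}
        )


def compute_features(cube: SpectralCube, mask: PixelMask,
                     defs: list[MetricDefinition],
                     half_window: float = DEFAULT_HALF_WINDOW,
                     cog_mode: str = "anchored") -> FeatureImage:
    """Evaluate a metric library on every kept pixel of a preprocessed cube.

    The cube is expected to be baseline-corrected and amide-I normalized.
    Masked pixels carry NaN sentinels.
    """
    if not defs:
        raise ValueError("metric library is empty")
    if mask.keep.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    rows, cols, _ = cube.data.shape
    values = np.full((rows, cols, len(defs)), np.nan, dtype=np.float64)
    kept = cube.data[mask.keep].astype(np.float64)
    for j, mdef in enumerate(defs):
        values[mask.keep, j] = evaluate_metric(kept, cube.axis, mdef, half_window, cog_mode)
    return FeatureImage(values, [d.name for d in defs], mask)
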