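"""ENVI-style hyperspectral cube I/O and spatial operations.

Mid-infrared absorbance images are held as a :class:`SpectralCube`
(rows x cols x bands, absorbance units) with an ascending
:class:`WavenumberAxis` in cm^-1.  On disk a single ENVI dialect is
supported: a plain-text ``.hdr`` companion file plus a raw
band-sequential (bsq) raster of 32-bit little-endian floats.  Files
written with a descending wavelength list (a common instrument
convention) are re-ordered to ascending on read.

Label rasters (histologic class codes 0..5) use the same header format
with ``data type = 1`` (unsigned byte).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "WavenumberAxis",
    "SpectralCube",
    "SpectralFormatError",
    "CubeIntegrityError",
    "IncompatibleCubesError",
    "read_cube",
    "write_cube",
    "read_labels",
    "write_labels",
    "read_raster",
    "write_raster",
    "stitch_tiles",
    "bin_pixels",
    "truncate_range",
]

#: Histologic class codes used throughout the package.
CLASS_NAMES = {
    0: "Unclassified",
    1: "Myocardium",
    2: "Endocardium",
    3: "Fibrosis-Endocardium",
    4: "Fibrosis-Myocardium",
    5: "Lymphocytes",
}

#: Spectral range retained for storage, cm^-1.
WAVENUMBER_MIN = 800.0
WAVENUMBER_MAX = 4000.0

_UNIFORMITY_TOL = 1e-9


class SpectralFormatError(ValueError):
    """Malformed or unsupported ENVI header."""


class CubeIntegrityError(ValueError):
    """Header metadata inconsistent with the binary raster."""


class IncompatibleCubesError(ValueError):
    """Cubes cannot be combined (axis or pixel-pitch mismatch)."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniformly spaced, strictly ascending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two wavenumbers")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("axis must be strictly ascending")
        if np.ptp(steps) > _UNIFORMITY_TOL:
            raise ValueError("axis spacing is not uniform")
        if values[0] < WAVENUMBER_MIN - _UNIFORMITY_TOL or values[-1] > WAVENUMBER_MAX + _UNIFORMITY_TOL:
            raise ValueError(
                f"axis must lie within [{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}] cm^-1"
            )

    @classmethod
    def regular(cls, lo: float = WAVENUMBER_MIN, hi: float = WAVENUMBER_MAX,
                step: float = 2.0) -> "WavenumberAxis":
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((float(self.values[0]), float(self.values[-1]), len(self)))

    def index_of(self, wavenumber: float) -> int:
        """Index of the band nearest to ``wavenumber`` (no interpolation)."""
        lo, hi = self.values[0], self.values[-1]
        if wavenumber < lo - self.step / 2 or wavenumber > hi + self.step / 2:
            raise ValueError(f"{wavenumber:g} cm^-1 outside axis range [{lo:g}, {hi:g}]")
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def slice_indices(self, lo: float, hi: float) -> tuple[int, int]:
        """Inclusive band-index bounds of the closed interval [lo, hi]."""
        if lo >= hi:
            raise ValueError("interval bounds must satisfy lo < hi")
        inside = np.nonzero((self.values >= lo - _UNIFORMITY_TOL)
                            & (self.values <= hi + _UNIFORMITY_TOL))[0]
        if inside.size == 0:
            raise ValueError(f"[{lo:g}, {hi:g}] cm^-1 does not intersect the axis")
        return int(inside[0]), int(inside[-1])


@dataclass
class SpectralCube:
    """Absorbance raster (rows x cols x bands) with wavenumber axis.

    Parameters
    ----------
    data
        Absorbance values, stored as float32.  All values must be finite.
    axis
        Ascending wavenumber axis; its length must equal the band count.
    pixel_pitch
        Pixel size in micrometres (6.25 or 25 in the imaging protocol;
        any positive value is accepted).
    provenance
        Free-text acquisition/processing note carried through operations.
    """

    data: np.ndarray
    axis: WavenumberAxis
    pixel_pitch: float = 6.25
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.axis):
            raise CubeIntegrityError(
                f"bands dimension {self.data.shape[2]} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite absorbance values")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]


# ---------------------------------------------------------------------------
# ENVI dialect
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("samples", "lines", "bands", "data type", "interleave")


def _header_path(path: str | Path) -> Path:
    path = Path(path)
    return path if path.suffix == ".hdr" else path.with_name(path.name + ".hdr")


def _data_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix("") if path.suffix == ".hdr" else path


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise SpectralFormatError("missing ENVI magic line")
    body = text.lstrip()[4:]
    # Collapse brace-delimited multi-line values onto single lines.
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    fields: dict[str, str] = {}
    for line in body.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def _header_int(fields: dict[str, str], key: str) -> int:
    try:
        return int(fields[key])
    except KeyError as exc:
        raise SpectralFormatError(f"header missing required field '{key}'") from exc
    except ValueError as exc:
        raise SpectralFormatError(f"header field '{key}' is not an integer: {fields[key]!r}") from exc


def _format_header(fields: dict[str, object]) -> str:
    lines = ["ENVI"]
    for key, value in fields.items():
        if isinstance(value, (list, tuple, np.ndarray)):
            joined = ", ".join(repr(float(v)) for v in value)
            lines.append(f"{key} = {{ {joined} }}")
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write ``cube`` as bsq float32-LE raster + text header.

    The raster goes to ``path`` and the header to ``path + '.hdr'``.
    """
    if not np.all(np.isfinite(cube.data)):  # cheap re-check before touching disk
        raise ValueError("refusing to write cube with non-finite values")
    header = {
        "description": "{ %s }" % cube.provenance.replace("}", ")"),
        "samples": cube.data.shape[1],
        "lines": cube.data.shape[0],
        "bands": cube.data.shape[2],
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": 4,
        "interleave": "bsq",
        "byte order": 0,
        "pixel size um": repr(float(cube.pixel_pitch)),
        "wavelength units": "cm-1",
        "wavelength": cube.axis.values,
    }
    data_path = _data_path(path)
    _header_path(path).write_text(_format_header(header))
    bsq = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)), dtype="<f4")
    bsq.tofile(data_path)


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (or any file in the same
    single dialect).  Descending wavelength lists are re-ordered so the
    in-memory axis is always ascending, with spectra reversed consistently.
    """
    header_path = _header_path(path)
    data_path = _data_path(path)
    if not header_path.exists():
        raise SpectralFormatError(f"header not found: {header_path}")
    fields = _parse_header(header_path.read_text())

    samples = _header_int(fields, "samples")
    lines = _header_int(fields, "lines")
    bands = _header_int(fields, "bands")
    if _header_int(fields, "data type") != 4:
        raise SpectralFormatError("only 'data type = 4' (float32) cubes are supported")
    if fields.get("interleave", "").lower() != "bsq":
        raise SpectralFormatError("only 'interleave = bsq' cubes are supported")
    if int(fields.get("byte order", "0")) != 0:
        raise SpectralFormatError("only little-endian ('byte order = 0') cubes are supported")

    wl_raw = fields.get("wavelength")
    if wl_raw is None:
        raise SpectralFormatError("header missing required field 'wavelength'")
    wavelengths = np.array(
        [float(tok) for tok in wl_raw.strip("{} \t").split(",") if tok.strip()],
        dtype=np.float64,
    )
    if wavelengths.size != bands:
        raise CubeIntegrityError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    expected = samples * lines * bands * 4
    actual = data_path.stat().st_size
    if actual != expected:
        raise CubeIntegrityError(
            f"raster size {actual} B does not match header ({expected} B expected)"
        )
    flat = np.fromfile(data_path, dtype="<f4")
    data = np.transpose(flat.reshape(bands, lines, samples), (1, 2, 0))

    descending = wavelengths.size > 1 and wavelengths[0] > wavelengths[-1]
    if descending:
        wavelengths = wavelengths[::-1]
        data = data[:, :, ::-1]

    pitch = float(fields.get("pixel size um", 6.25))
    provenance = fields.get("description", "").strip("{} ")
    return SpectralCube(np.ascontiguousarray(data), WavenumberAxis(wavelengths),
                        pixel_pitch=pitch, provenance=provenance)


def write_labels(labels: np.ndarray, path: str | Path, pixel_pitch: float = 6.25) -> None:
    """Write a class-label raster (codes 0..5) as a single-band byte ENVI file."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label raster must be 2-D")
    if labels.min() < 0 or labels.max() > 5:
        raise ValueError("label codes must lie in {0..5}")
    header = {
        "samples": labels.shape[1],
        "lines": labels.shape[0],
        "bands": 1,
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": 1,
        "interleave": "bsq",
        "byte order": 0,
        "pixel size um": repr(float(pixel_pitch)),
        "class names": "{ %s }" % ", ".join(CLASS_NAMES[c] for c in range(6)),
    }
    _header_path(path).write_text(_format_header(header))
    labels.astype(np.uint8).tofile(_data_path(path))


def read_labels(path: str | Path) -> np.ndarray:
    header_path = _header_path(path)
    if not header_path.exists():
        raise SpectralFormatError(f"header not found: {header_path}")
    fields = _parse_header(header_path.read_text())
    samples = _header_int(fields, "samples")
    lines = _header_int(fields, "lines")
    if _header_int(fields, "data type") != 1:
        raise SpectralFormatError("label rasters must use 'data type = 1' (byte)")
    raw = np.fromfile(_data_path(path), dtype=np.uint8)
    if raw.size != samples * lines:
        raise CubeIntegrityError("label raster size does not match header")
    labels = raw.reshape(lines, samples).astype(np.int64)
    if labels.max() > 5:
        raise CubeIntegrityError("label raster contains codes outside {0..5}")
    return labels


def write_raster(array: np.ndarray, path: str | Path, band_names: list[str] | None = None) -> None:
    """Write a generic float32 multi-band raster (rows x cols x bands), bsq."""
    array = np.asarray(array, dtype=np.float32)
    if array.ndim == 2:
        array = array[:, :, None]
    header = {
        "samples": array.shape[1],
        "lines": array.shape[0],
        "bands": array.shape[2],
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": 4,
        "interleave": "bsq",
        "byte order": 0,
    }
    if band_names is not None:
        header["band names"] = "{ %s }" % ", ".join(band_names)
    _header_path(path).write_text(_format_header(header))
    np.ascontiguousarray(np.transpose(array, (2, 0, 1)), dtype="<f4").tofile(_data_path(path))


def read_raster(path: str | Path) -> np.ndarray:
    fields = _parse_header(_header_path(path).read_text())
    samples = _header_int(fields, "samples")
    lines = _header_int(fields, "lines")
    bands = _header_int(fields, "bands")
    flat = np.fromfile(_data_path(path), dtype="<f4")
    if flat.size != samples * lines * bands:
        raise CubeIntegrityError("raster size does not match header")
    return np.transpose(flat.reshape(bands, lines, samples), (1, 2, 0))


# ---------------------------------------------------------------------------
# Spatial operations
# ---------------------------------------------------------------------------

def stitch_tiles(tiles: list[tuple[SpectralCube, int, int]]) -> SpectralCube:
    """Mosaic separately acquired tiles into one cube.

    Each entry is ``(cube, row_offset, col_offset)``.  The output is sized to
    the bounding box of all tiles; pixels covered by no tile are zero-filled
    (and noted in the provenance, to be removed downstream by the amide-I
    mask); where tiles overlap the last-listed tile wins.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    ref_cube, _, _ = tiles[0]
    for cube, r0, c0 in tiles:
        if cube.axis != ref_cube.axis:
            raise IncompatibleCubesError("tiles have differing wavenumber axes")
        if cube.pixel_pitch != ref_cube.pixel_pitch:
            raise IncompatibleCubesError("tiles have differing pixel pitch")
        if r0 < 0 or c0 < 0:
            raise ValueError("tile offsets must be non-negative")

    n_rows = max(cube.data.shape[0] + r0 for cube, r0, _ in tiles)
    n_cols = max(cube.data.shape[1] + c0 for cube, _, c0 in tiles)
    mosaic = np.zeros((n_rows, n_cols, len(ref_cube.axis)), dtype=np.float32)
    covered = np.zeros((n_rows, n_cols), dtype=bool)
    for cube, r0, c0 in tiles:
        r, c, _ = cube.data.shape
        mosaic[r0:r0 + r, c0:c0 + c, :] = cube.data
        covered[r0:r0 + r, c0:c0 + c] = True
    n_gap = int((~covered).sum())
    provenance = f"stitched {len(tiles)} tiles; {n_gap} uncovered pixels zero-filled"
    return SpectralCube(mosaic, ref_cube.axis, ref_cube.pixel_pitch, provenance)


def bin_pixels(cube: SpectralCube, factor: int) -> SpectralCube:
    """Average ``factor x factor`` pixel blocks (unweighted mean spectrum).

    Emulates acquisition at a coarser pixel size: the pixel pitch is
    multiplied by ``factor``.  Trailing rows/cols not filling a block are
    dropped (recorded in the provenance).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("binning factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return replace(cube, provenance=cube.provenance)
    rows, cols, bands = cube.data.shape
    out_r, out_c = rows // factor, cols // factor
    if out_r == 0 or out_c == 0:
        raise ValueError("cube smaller than one binning block")
    trimmed = cube.data[: out_r * factor, : out_c * factor, :]
    blocks = trimmed.reshape(out_r, factor, out_c, factor, bands)
    binned = blocks.mean(axis=(1, 3), dtype=np.float64).astype(np.float32)
    dropped = (rows - out_r * factor, cols - out_c * factor)
    provenance = cube.provenance + f"; binned {factor}x{factor}"
    if any(dropped):
        provenance += f" (dropped {dropped[0]} rows, {dropped[1]} cols)"
    return SpectralCube(binned, cube.axis, cube.pixel_pitch * factor, provenance)


def truncate_range(cube: SpectralCube, lo: float, hi: float) -> SpectralCube:
    """Keep only bands with wavenumber in the closed interval [lo, hi]."""
    i0, i1 = cube.axis.slice_indices(lo, hi)  # raises on empty intersection
    axis = WavenumberAxis(cube.axis.values[i0:i1 + 1])
    return SpectralCube(cube.data[:, :, i0:i1 + 1].copy(), axis,
                        cube.pixel_pitch, cube.provenance)
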