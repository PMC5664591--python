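"""Hyperspectral cube container and ENVI-style raster I/O.

Coordinate convention (used everywhere in this package):

* ``data[y, x, b]`` — ``y`` is the vertical scan-line axis (0 = top, increases
  downward), ``x`` the horizontal travel axis (0 = row start), ``b`` the band.
* Column intervals are half-open ``[start, end)``.

Cubes are stored on disk as raw BIL or BSQ binary next to a plain-text ENVI
header (``<file>.hdr``).  The header dialect is the minimal de-facto standard:
``samples``, ``lines``, ``bands``, ``interleave``, ``data type``, ``byte
order`` and a ``wavelength`` list; unknown keys are preserved on round-trip.
Binary masks travel as 8-bit PNG (0/255).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

__all__ = [
    "HyperCube",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
]

#: ENVI numeric "data type" codes for the dtypes this package supports.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_KIND_TAGS = ("raw", "dark_corrected", "reflectance")
_KIND_KEY = "cube kind"
_KNOWN_KEYS = {
    "samples",
    "lines",
    "bands",
    "interleave",
    "data type",
    "byte order",
    "header offset",
    "file type",
    "wavelength",
    _KIND_KEY,
}


@dataclass
class HyperCube:
    """An intensity cube ``data[y, x, b]`` with per-band wavelengths in nm.

    ``kind`` tags the processing state: ``raw`` digital numbers,
    ``dark_corrected`` after dark-current subtraction, or ``reflectance``
    (dimensionless ratios; may exceed 1 on specular pixels).
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "raw"
    extra_header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (y, x, band), got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ValueError(f"cube dimensions must all be >= 1, got {self.data.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths_nm.size} != band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.kind not in _KIND_TAGS:
            raise ValueError(f"unknown kind tag {self.kind!r}, expected one of {_KIND_TAGS}")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "HyperCube":
        """A copy of this cube carrying new pixel data (same wavelengths)."""
        return HyperCube(
            data=data,
            wavelengths_nm=self.wavelengths_nm.copy(),
            kind=self.kind if kind is None else kind,
            extra_header=dict(self.extra_header),
        )


def _header_path(path: Path) -> Path:
    return path.with_name(path.name + ".hdr")


def _parse_header(text: str, path: Path) -> dict:
    """Parse an ENVI text header into a {key: string-value} dict."""
    body = text.strip()
    if not body.upper().startswith("ENVI"):
        raise FormatError(f"{path}: missing ENVI magic line")
    body = body[4:]
    fields: dict[str, str] = {}
    # 'key = value' or 'key = { multi, line, list }'
    pattern = re.compile(r"^\s*([\w ][\w /:+-]*?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        value = m.group(2).strip()
        if value.startswith("{"):
            value = value[1:-1].strip()
        fields[key] = value
    return fields


def _require(fields: dict, key: str, path: Path) -> str:
    if key not in fields:
        raise FormatError(f"{path}: missing required header field '{key}'")
    return fields[key]


def read_cube(path) -> HyperCube:
    """Read an ENVI BIL/BSQ raster (+``.hdr`` text header) into a :class:`HyperCube`."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        alt = path.with_suffix(".hdr")
        if alt.exists():
            hdr = alt
        else:
            raise FormatError(f"{path}: header file {hdr} not found")
    fields = _parse_header(hdr.read_text(), hdr)

    def _int(key: str) -> int:
        raw = _require(fields, key, hdr)
        try:
            return int(raw)
        except ValueError:
            raise FormatError(f"{hdr}: field '{key}' is not an integer: {raw!r}") from None

    samples, lines, bands = _int("samples"), _int("lines"), _int("bands")
    interleave = _require(fields, "interleave", hdr).lower()
    if interleave not in ("bil", "bsq"):
        raise FormatError(f"{hdr}: unsupported interleave '{interleave}' (need bil or bsq)")
    dcode = _int("data type")
    if dcode not in _ENVI_DTYPES:
        raise FormatError(f"{hdr}: unsupported data type code {dcode}")
    dtype = np.dtype(_ENVI_DTYPES[dcode])
    if fields.get("byte order", "0").strip() == "1":
        dtype = dtype.newbyteorder(">")

    wl_raw = _require(fields, "wavelength", hdr)
    try:
        wavelengths = np.array([float(v) for v in wl_raw.replace("\n", " ").split(",") if v.strip()])
    except ValueError:
        raise FormatError(f"{hdr}: field 'wavelength' contains a non-numeric entry") from None
    if wavelengths.size != bands:
        raise FormatError(
            f"{hdr}: wavelength count {wavelengths.size} != band count {bands}"
        )

    raw = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"{path}: data size {raw.size} does not match header "
            f"samples*lines*bands = {expected}"
        )
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    kind = fields.get(_KIND_KEY, "raw").strip()
    extra = {k: v for k, v in fields.items() if k not in _KNOWN_KEYS}
    return HyperCube(np.ascontiguousarray(data), wavelengths, kind=kind, extra_header=extra)


def write_cube(cube: HyperCube, path, interleave: str = "bil") -> None:
    """Write a cube as raw binary plus an ENVI text header at ``<path>.hdr``."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"cannot store dtype {dtype} in an ENVI raster")
    if interleave == "bil":
        out = cube.data.transpose(0, 2, 1)  # lines, bands, samples
    else:
        out = cube.data.transpose(2, 0, 1)  # bands, lines, samples
    np.ascontiguousarray(out).tofile(path)

    lines = [
        "ENVI",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"{_KIND_KEY} = {cube.kind}",
        "wavelength = {",
        ", ".join(repr(float(w)) for w in cube.wavelengths_nm),
        "}",
    ]
    for key, value in cube.extra_header.items():
        lines.append(f"{key} = {value}")
    _header_path(path).write_text("\n".join(lines) + "\n")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (True -> 255)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError(f"mask must be a non-empty 2-D array, got shape {mask.shape}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    """Read a PNG mask written by :func:`write_mask` back to boolean."""
    img = iio.imread(Path(path))
    if img.ndim == 3:  # tolerate grey images saved with channels
        img = img[..., 0]
    return np.asarray(img) > 127
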