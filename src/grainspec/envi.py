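"""Minimal ENVI raster I/O for hyperspectral cubes.

Reads and writes the classic ENVI pair: a plain-text ``.hdr`` header and a
companion flat binary image in ``bil``/``bip``/``bsq`` interleave.  Only the
fields this package needs are handled (samples/lines/bands, data type,
interleave, byte order, wavelengths); everything else in a header is
preserved on read but ignored.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import DimensionError, FormatError, Hypercube, WavelengthGrid

# ENVI "data type" codes -> numpy dtypes (little-endian handled via byte order)
_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_REQUIRED = ("samples", "lines", "bands", "data type", "interleave")


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a {lowercased field: string value} dict.

    Braced values (e.g. wavelength lists) may span multiple lines.
    """
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # join continuation lines inside { ... }
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _companion_binary(header_path: Path) -> Path:
    for suffix in ("", ".img", ".dat", ".raw", ".bsq", ".bil", ".bip"):
        cand = header_path.with_suffix(suffix)
        if cand != header_path and cand.exists():
            return cand
    raise FormatError(f"no companion binary found for {header_path}")


def read_envi(header_path) -> Hypercube:
    """Read an ENVI header + binary pair into a raw Hypercube.

    The on-disk interleave (bil/bip/bsq) is normalised to
    rows x cols x bands in memory.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header not found: {header_path}")
    fields = _parse_header(header_path.read_text())
    for name in _REQUIRED:
        if name not in fields:
            raise FormatError(f"ENVI header missing required field '{name}'")
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave '{interleave}'")
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(_DTYPES[code]).newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" not in fields:
        raise FormatError("ENVI header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise FormatError("ENVI wavelength field must be a braced list")
    nm = np.array([float(v) for v in wl_text[1:-1].replace("\n", " ").split(",")
                   if v.strip()])
    if nm.size != bands:
        raise DimensionError(
            f"header declares {bands} bands but lists {nm.size} wavelengths")

    binary = _companion_binary(header_path)
    raw = np.fromfile(binary, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise DimensionError(
            f"binary holds {raw.size} values, header implies {expected} "
            f"({lines}x{samples}x{bands})")
    if interleave == "bsq":          # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":        # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                            # bip: (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    if "cube kind" in fields:        # our own provenance field, when present
        kind = fields["cube kind"]
    elif np.issubdtype(dtype, np.floating) and data.max(initial=0) <= 10:
        kind = "reflectance"
    else:                            # integer payloads are raw counts
        kind = "raw"
    return Hypercube(data=np.ascontiguousarray(data, dtype=float),
                     grid=WavelengthGrid(nm), kind=kind)


def write_envi(cube: Hypercube, header_path, interleave: str = "bsq",
               dtype="f4") -> Path:
    """Write a Hypercube as an ENVI header (.hdr) + binary (.img) pair.

    Returns the path of the binary file.
    """
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise FormatError(f"unsupported dtype {dtype}")
    rows, cols, bands = cube.shape
    if interleave == "bsq":
        ondisk = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        ondisk = cube.data.transpose(0, 2, 1)
    else:
        ondisk = cube.data
    binary_path = header_path.with_suffix(".img")
    np.ascontiguousarray(ondisk).astype(dtype.newbyteorder("<")).tofile(binary_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n")
    return binary_path
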