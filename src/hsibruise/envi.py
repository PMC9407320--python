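"""Minimal ENVI-format reader/writer for hyperspectral cubes.

Writes a text ``.hdr`` header (samples/lines/bands, interleave, data type,
wavelength list) next to a raw binary image file.  Reading supports BSQ,
BIL and BIP interleaves and the common numeric data types; writing emits
BSQ with the array's own floating dtype so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .cube import HyperspectralCube

# ENVI data-type codes <-> numpy dtypes (little-endian, byte order 0)
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _binary_path(header_path: str) -> str:
    base, ext = os.path.splitext(header_path)
    return base + ".img" if ext.lower() == ".hdr" else header_path + ".img"


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header: missing ENVI magic")
    fields: dict = {}
    # join brace-delimited multi-line values before splitting into fields
    text = text.lstrip()[4:]
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for key, value in pattern.findall(text):
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            value = value[1:-1].strip()
            fields[key] = [v.strip() for v in value.replace("\n", " ").split(",") if v.strip()]
        else:
            fields[key] = value
    return fields


def read_envi(header_path: str) -> HyperspectralCube:
    """Read an ENVI header + companion binary into a cube."""
    with open(header_path) as fh:
        fields = _parse_header(fh.read())
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required field '{req}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    interleave = str(fields["interleave"]).lower()
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required field 'wavelength'")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if len(wavelengths) != bands:
        raise ValueError(
            f"header lists {len(wavelengths)} wavelengths but declares {bands} bands"
        )

    binary = _binary_path(header_path)
    raw = np.fromfile(binary, dtype=_DTYPES[code], offset=int(fields.get("header offset", 0)))
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"binary file {binary} holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    meta = {}
    if "description" in fields:
        desc = fields["description"]
        meta["description"] = ", ".join(desc) if isinstance(desc, list) else desc
    return HyperspectralCube(np.ascontiguousarray(data), wavelengths, meta)


def write_envi(cube: HyperspectralCube, header_path: str) -> None:
    """Write a cube as BSQ binary + text header readable by :func:`read_envi`."""
    data = np.asarray(cube.data)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float32)
    code = _DTYPE_CODES[data.dtype]
    lines, samples, bands = data.shape
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    desc = str(cube.meta.get("description", "hsibruise cube"))
    header = (
        "ENVI\n"
        f"description = {{{desc}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    data.transpose(2, 0, 1).tofile(_binary_path(header_path))
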