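"""Minimal ENVI cube reader/writer (BIL/BSQ/BIP, ASCII header).

Supports the subset of the format the pipeline needs: a ``.hdr`` text
header with samples/lines/bands, data type, interleave and a wavelength
list, alongside a raw binary data file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_envi", "read_envi"]

_DTYPE_TO_ENVI = {
    np.dtype(np.uint8): 1, np.dtype(np.int16): 2, np.dtype(np.int32): 3,
    np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12,
    np.dtype(np.uint32): 13,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def write_envi(path: str | Path, cube: np.ndarray, wavelengths: np.ndarray,
               interleave: str = "bil", description: str = "sifyield scene") -> Path:
    """Write a (rows, cols, bands) cube; returns the header path."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be (rows, cols, bands)")
    rows, cols, bands = cube.shape
    if len(wavelengths) != bands:
        raise ValueError("wavelength list length != band count")
    if cube.dtype not in _DTYPE_TO_ENVI:
        cube = cube.astype(np.float32)

    if interleave == "bil":
        data = np.transpose(cube, (0, 2, 1))     # (lines, bands, samples)
    elif interleave == "bsq":
        data = np.transpose(cube, (2, 0, 1))     # (bands, lines, samples)
    else:
        data = cube                              # (lines, samples, bands)

    data_path = path.with_suffix(".bil" if interleave == "bil" else f".{interleave}")
    data_path.write_bytes(np.ascontiguousarray(data).tobytes())
    wl_str = ",\n ".join(f"{w:.6f}" for w in wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{{description}}}\n"
        f"samples = {cols}\nlines = {rows}\nbands = {bands}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[cube.dtype]}\n"
        f"interleave = {interleave}\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{\n {wl_str}}}\n"
    )
    hdr_path = data_path.with_suffix(".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for line in text.splitlines():
        if in_block:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_block, key, buf = False, None, []
            continue
        if "=" not in line:
            continue
        k, v = (part.strip() for part in line.split("=", 1))
        if "{" in v and "}" not in v:
            key, buf, in_block = k.lower(), [v], True
        else:
            fields[k.lower()] = v
    return fields


def read_envi(header_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a cube written by :func:`write_envi`; returns (cube, wavelengths)."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_TO_DTYPE[int(fields["data type"])]
    interleave = fields.get("interleave", "bil").lower()
    wl_block = fields.get("wavelength", "{}")
    wl = np.array([float(tok) for tok in
                   wl_block.strip().strip("{}").replace(",", " ").split()])

    data_path = None
    for ext in (f".{interleave}", ".img", ".dat", ""):
        cand = header_path.with_suffix(ext)
        if cand.exists() and cand != header_path:
            data_path = cand
            break
    if data_path is None:
        raise FileNotFoundError(f"no data file next to {header_path}")
    raw = np.frombuffer(data_path.read_bytes(), dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError("data file size does not match header dimensions")
    if interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return np.ascontiguousarray(cube), wl
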