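"""Minimal MRC2014 image I/O.

Reads modes 0 (int8), 1 (int16), 2 (float32) and 12 (float16); writes mode 2.
The MRC2014 layout stores the first (column) axis fastest, so a numpy array of
shape (ny, nx) maps onto an MRC file with NX = nx, NY = ny.  The pixel size is
carried in the cell dimensions: CELLA / (MX, MY, MZ).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["MrcFormatError", "read_mrc_array", "write_mrc_array"]

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 12: np.float16}


class MrcFormatError(ValueError):
    """Raised for files that are not valid/supported MRC2014."""


def read_mrc_array(path, section: int | None = None):
    """Read an MRC file.

    Returns ``(data, pixel_size)`` where ``data`` is a float32 2D array of
    shape (ny, nx) and ``pixel_size`` the x pixel size in Angstrom (0.0 when
    the header carries no cell).  3D files require ``section``.

    Raises
    ------
    MrcFormatError
        On malformed headers, unsupported modes, or anisotropic pixels.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MrcFormatError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        mx, my, mz = struct.unpack("<3i", header[28:40])
        cella = struct.unpack("<3f", header[40:52])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if min(nx, ny, nz) <= 0 or mode not in _MODE_DTYPES:
            raise MrcFormatError(f"{path}: unsupported MRC header (mode={mode})")
        pixel_sizes = [cella[i] / m if m > 0 else 0.0 for i, m in enumerate((mx, my, mz))]
        px, py = pixel_sizes[0], pixel_sizes[1]
        if px > 0 and py > 0 and not np.isclose(px, py, rtol=1e-4):
            raise MrcFormatError(
                f"{path}: anisotropic pixel size ({px:.4f} x {py:.4f} A) not supported"
            )
        fh.seek(_HEADER_SIZE + nsymbt)
        dtype = _MODE_DTYPES[mode]
        if nz > 1:
            if section is None:
                raise MrcFormatError(
                    f"{path}: {nz}-section stack; a section index is required"
                )
            if not (0 <= section < nz):
                raise MrcFormatError(f"{path}: section {section} out of range [0,{nz})")
            fh.seek(section * nx * ny * np.dtype(dtype).itemsize, 1)
        count = nx * ny
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise MrcFormatError(f"{path}: truncated data block")
    return data.reshape(ny, nx).astype(np.float32), float(px)


def write_mrc_array(path, data, pixel_size: float) -> None:
    """Write a 2D float array as a mode-2 (float32) MRC2014 file."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("only 2D arrays are written")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)          # NX NY NZ MODE
    struct.pack_into("<3i", header, 28, nx, ny, 1)            # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * pixel_size, ny * pixel_size, pixel_size)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)     # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)              # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                     # ISPG (2D image: 1 ok, 0 also used)
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"                     # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        data.astype("<f4").tofile(fh)
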