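"""XYZ geometry I/O (Angstrom on disk, bohr in memory)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from ..geometry import QMGeometry


class XYZFormatError(ValueError):
    pass


def _parse_frame(lines, start, path):
    try:
        natoms = int(lines[start].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZFormatError(
            f"{path}: line {start + 1}: expected an atom count, got {lines[start]!r}"
        ) from exc
    if start + 2 + natoms > len(lines):
        raise XYZFormatError(f"{path}: truncated frame starting at line {start + 1}")
    comment = lines[start + 1].rstrip("\n")
    symbols, coords = [], []
    for k in range(natoms):
        toks = lines[start + 2 + k].split()
        if len(toks) < 4:
            raise XYZFormatError(
                f"{path}: line {start + 3 + k}: need 'symbol x y z'"
            )
        symbols.append(toks[0].capitalize())
        coords.append([float(t) for t in toks[1:4]])
    return symbols, np.array(coords), comment, start + 2 + natoms


def read_xyz(path, total_charge: int = 0) -> QMGeometry:
    """Read the first frame of an XYZ file (coordinates in Angstrom)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    symbols, coords, _, _ = _parse_frame(lines, 0, path)
    return QMGeometry(symbols, coords * BOHR_PER_ANGSTROM, total_charge)


def read_xyz_frames(path):
    """All frames of a multi-frame XYZ as (symbols, coords_bohr, comment)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        symbols, coords, comment, pos = _parse_frame(lines, pos, path)
        frames.append((symbols, coords * BOHR_PER_ANGSTROM, comment))
    return frames


def write_xyz(path, geometry: QMGeometry, comment: str = "") -> None:
    write_trajectory(path, [(geometry.symbols, geometry.coordinates, comment)])


def write_trajectory(path, frames) -> None:
    """Write multi-frame XYZ; frames are (symbols, coords_bohr, comment)."""
    with open(path, "w") as fh:
        for symbols, coords, comment in frames:
            coords = np.asarray(coords) * ANGSTROM_PER_BOHR
            fh.write(f"{len(symbols)}\n{comment}\n")
            for s, (x, y, z) in zip(symbols, coords):
                fh.write(f"{s:2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
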