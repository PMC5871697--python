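"""Parser for Gaussian94-format basis set files.

Handles the dialect exported by the common basis repositories: element
blocks terminated by ``****``, shell headers like ``S    3   1.00``,
Fortran ``D`` exponents, and combined ``SP`` shells (split into separate
S and P shells on input).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

_SHELL_RE = re.compile(r"^\s*(S|P|D|SP|F|G)\s+(\d+)\s+(\S+)\s*$", re.IGNORECASE)
_ELEM_RE = re.compile(r"^\s*([A-Za-z]{1,2})\s+0\s*$")

_L_OF = {"S": 0, "P": 1, "D": 2}


class BasisParseError(ValueError):
    pass


def _tofloat(tok: str) -> float:
    return float(tok.replace("D", "E").replace("d", "e"))


def parse_gaussian94(text: str) -> dict:
    """Parse basis text into {element: [(l, exponents, coefficients), ...]}."""
    library: dict[str, list] = {}
    lines = text.splitlines()
    i = 0
    n = len(lines)
    current: str | None = None
    while i < n:
        line = lines[i]
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            i += 1
            continue
        if stripped == "****":
            current = None
            i += 1
            continue
        m = _ELEM_RE.match(line)
        if m and current is None:
            current = m.group(1).capitalize()
            library[current] = []
            i += 1
            continue
        m = _SHELL_RE.match(line)
        if m:
            if current is None:
                raise BasisParseError(
                    f"line {i + 1}: shell block outside an element section"
                )
            label = m.group(1).upper()
            nprim = int(m.group(2))
            if label in ("F", "G"):
                raise BasisParseError(
                    f"line {i + 1}: angular momentum {label} not supported (s, p, d only)"
                )
            rows = []
            for k in range(nprim):
                i += 1
                if i >= n:
                    raise BasisParseError(f"line {i + 1}: truncated shell block")
                toks = lines[i].split()
                try:
                    rows.append([_tofloat(t) for t in toks])
                except ValueError as exc:
                    raise BasisParseError(
                        f"line {i + 1}: cannot parse primitive row: {lines[i]!r}"
                    ) from exc
            rows = np.array(rows)
            exps = rows[:, 0]
            if label == "SP":
                if rows.shape[1] < 3:
                    raise BasisParseError(
                        f"line {i + 1}: SP shell needs two coefficient columns"
                    )
                library[current].append((0, exps, rows[:, 1]))
                library[current].append((1, exps, rows[:, 2]))
            else:
                library[current].append((_L_OF[label], exps, rows[:, 1]))
            i += 1
            continue
        raise BasisParseError(f"line {i + 1}: unrecognized content: {stripped!r}")
    return library


def load_basis(path, elements=None) -> dict:
    """Load a Gaussian94 basis file, optionally restricted to ``elements``.

    Raises ``KeyError`` naming any requested element absent from the file.
    """
    text = Path(path).read_text()
    library = parse_gaussian94(text)
    if elements is None:
        return library
    missing = sorted(set(elements) - set(library))
    if missing:
        raise KeyError(
            f"element(s) {', '.join(missing)} not found in basis file {path}"
        )
    return {el: library[el] for el in elements}
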